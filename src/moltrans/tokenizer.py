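"""Tokenization of SMILES and InChI strings and one-hot encoding.

Sequences are tokenized on the character level except for a small set of
multi-character units matched greedily: ``Cl`` and ``Br`` in SMILES, and the
constant prefix ``InChI=1S/`` plus ``Cl``/``Br`` in InChI. Each notation has
its own ordered lookup table with three special tokens (start, end, pad)
prepended.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

START, END, PAD = "<s>", "</s>", "<pad>"
_SPECIALS = (START, END, PAD)

_MULTI = {
    "smiles": ("Cl", "Br"),
    "inchi": ("InChI=1S/", "Cl", "Br"),
}


class TokenizationError(ValueError):
    """A sequence contains a character outside the vocabulary's alphabet."""

    def __init__(self, text: str, offset: int, message: str):
        super().__init__(f"{message} at offset {offset} in {text!r}")
        self.text = text
        self.offset = offset


def split_tokens(text: str, notation: str) -> list[str]:
    """Greedy longest-match split of ``text`` into token strings."""
    multi = _MULTI[notation]
    out: list[str] = []
    i = 0
    while i < len(text):
        for m in multi:
            if text.startswith(m, i):
                out.append(m)
                i += len(m)
                break
        else:
            out.append(text[i])
            i += 1
    return out


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token lookup table for one notation.

    Specials occupy indices 0..2 (start, end, pad); observed tokens follow in
    lexicographic order, so a vocabulary is a deterministic function of the
    corpus it was built from.
    """

    notation: str
    tokens: tuple[str, ...]
    index: dict = field(repr=False, hash=False, compare=False)

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def start(self) -> int:
        return self.index[START]

    @property
    def end(self) -> int:
        return self.index[END]

    @property
    def pad(self) -> int:
        return self.index[PAD]

    def to_json(self) -> str:
        return json.dumps({"notation": self.notation, "tokens": list(self.tokens)})

    @classmethod
    def from_json(cls, payload: str) -> "TokenVocabulary":
        d = json.loads(payload)
        return cls(
            notation=d["notation"],
            tokens=tuple(d["tokens"]),
            index={t: i for i, t in enumerate(d["tokens"])},
        )


def build_vocabulary(notation: str, corpus: Iterable[str]) -> TokenVocabulary:
    """Build a vocabulary from every token observed in ``corpus``.

    Ordering is deterministic: the three specials first, then observed tokens
    sorted lexicographically.
    """
    if notation not in _MULTI:
        raise ValueError(f"unknown notation {notation!r}")
    seen: set[str] = set()
    n_seqs = 0
    for text in corpus:
        n_seqs += 1
        seen.update(split_tokens(text, notation))
    if n_seqs == 0:
        raise ValueError("corpus is empty")
    tokens = _SPECIALS + tuple(sorted(seen))
    return TokenVocabulary(
        notation=notation, tokens=tokens,
        index={t: i for i, t in enumerate(tokens)},
    )


@dataclass(frozen=True)
class TokenSequence:
    """Token indices of one sequence: content tokens, then end, then pads."""

    vocab: TokenVocabulary
    indices: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return int(self.indices.shape[0])

    @property
    def content_length(self) -> int:
        """Number of tokens before (and excluding) the end token."""
        where = np.nonzero(self.indices == self.vocab.end)[0]
        return int(where[0]) if where.size else len(self)

    def mask(self) -> np.ndarray:
        """True for content tokens and the end token, False for pads."""
        m = np.zeros(len(self), dtype=bool)
        m[: self.content_length + 1] = True
        return m[: len(self)]


def tokenize(text: str, vocab: TokenVocabulary, max_len: int | None = None) -> TokenSequence:
    """Encode ``text`` as indices, append the end token and pad to ``max_len``.

    ``max_len`` counts the end token; None pads to exactly content+1.
    """
    parts = split_tokens(text, vocab.notation)
    idx = []
    offset = 0
    for p in parts:
        if p not in vocab.index:
            raise TokenizationError(text, offset, f"unknown token {p!r}")
        idx.append(vocab.index[p])
        offset += len(p)
    if max_len is None:
        max_len = len(idx) + 1
    if len(idx) + 1 > max_len:
        raise TokenizationError(text, 0, f"sequence longer than max length {max_len}")
    arr = np.full(max_len, vocab.pad, dtype=np.int64)
    arr[: len(idx)] = idx
    arr[len(idx)] = vocab.end
    return TokenSequence(vocab=vocab, indices=arr)


def detokenize(seq: TokenSequence) -> str:
    """Inverse of :func:`tokenize`: concatenate content tokens."""
    return "".join(seq.vocab.tokens[i] for i in seq.indices[: seq.content_length])


def reverse_content(seq: TokenSequence) -> TokenSequence:
    """Reverse the content tokens, keeping the end token and pads in place."""
    n = seq.content_length
    rev = seq.indices.copy()
    rev[:n] = rev[:n][::-1]
    return TokenSequence(vocab=seq.vocab, indices=rev)


def one_hot(seq: TokenSequence) -> np.ndarray:
    """(length x N) one-hot matrix; row r has a single 1 at column indices[r]."""
    n = seq.vocab.size
    out = np.zeros((len(seq), n), dtype=np.float64)
    out[np.arange(len(seq)), seq.indices] = 1.0
    return out


def pad_batch(seqs: Sequence[TokenSequence]) -> np.ndarray:
    """Stack variable-length sequences into a (B x T) index array, T = max length."""
    vocab = seqs[0].vocab
    t = max(s.content_length + 1 for s in seqs)
    out = np.full((len(seqs), t), vocab.pad, dtype=np.int64)
    for i, s in enumerate(seqs):
        k = min(len(s), t)
        out[i, :k] = s.indices[:k]
    return out
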