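"""Descriptor extraction and sequence generation from latent vectors.

Decoding is a left-to-right beam search over the decoder's step
distributions, keeping the B highest cumulative log-probability hypotheses
per step with no length normalization; ties are broken by hypothesis
creation order so results are bit-reproducible. ``decode_latent`` adds the
validity fallback: among the top-k beams, the highest-ranked one whose text
parses as a molecule is returned together with the rank used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem

from . import chem_prep, seq2seq, tokenizer
from .seq2seq import Checkpoint, ModelConfig


@dataclass
class BeamHypothesis:
    """A (partial or finished) decoded sequence with its log-probability."""

    indices: tuple[int, ...]
    logp: float
    finished: bool
    forced: bool = False   # finished by hitting max_len, not the end token


def beam_search(params: dict, cfg: ModelConfig, latent: np.ndarray,
                width: int, max_len: int, start_index: int, end_index: int,
                length_penalty: Optional[Callable[[int], float]] = None
                ) -> list[BeamHypothesis]:
    """Beam search from one latent; returns up to ``width`` finished
    hypotheses sorted by descending cumulative log-probability.

    ``length_penalty`` is an optional hook mapping hypothesis length to a
    score divisor; by default scores are raw log-probabilities.
    """
    if width < 1 or max_len < 1:
        raise ValueError("width and max_len must be >= 1")
    latent = np.asarray(latent, dtype=params["dec0_Wx"].dtype).reshape(1, -1)
    hs0, cs0 = seq2seq.decoder_initial_states(params, cfg, latent)
    # each entry: (hypothesis, state slot or None when finished)
    beams: list[BeamHypothesis] = [BeamHypothesis((), 0.0, False)]
    slots: list[Optional[int]] = [0]
    states = ([h.copy() for h in hs0], [c.copy() for c in cs0])
    for _ in range(max_len):
        live = [(i, s) for i, s in enumerate(slots) if s is not None]
        if not live:
            break
        live_idx = [i for i, _ in live]
        sel = np.array([s for _, s in live])
        last = np.array([beams[i].indices[-1] if beams[i].indices
                         else start_index for i in live_idx], dtype=np.int64)
        hs_b = [h[sel] for h in states[0]]
        cs_b = [c[sel] for c in states[1]]
        probs, new_hs, new_cs = seq2seq.decoder_step(params, cfg, hs_b, cs_b,
                                                     last)
        logp = np.log(np.clip(probs, 1e-30, None))
        # candidates: finished beams carry over; live beams spawn every
        # one-token extension. Ordering index encodes "earlier-generated"
        # so ties in score are broken reproducibly.
        cand: list[tuple[float, int, BeamHypothesis, Optional[int]]] = []
        order = 0
        for i, b in enumerate(beams):
            if slots[i] is None:
                cand.append((b.logp, order, b, None))
                order += 1
        for row, i in enumerate(live_idx):
            b = beams[i]
            for tok in range(cfg.vocab_out_size):
                hyp = BeamHypothesis(b.indices + (tok,),
                                     b.logp + float(logp[row, tok]),
                                     tok == end_index)
                cand.append((hyp.logp, order, hyp, row))
                order += 1
        cand.sort(key=lambda x: (-x[0], x[1]))
        kept = cand[:width]
        beams, slots, keep_rows = [], [], []
        for _, _, hyp, row in kept:
            beams.append(hyp)
            if hyp.finished or row is None:
                slots.append(None)
            else:
                slots.append(len(keep_rows))
                keep_rows.append(row)
        if keep_rows:
            r = np.array(keep_rows)
            states = ([h[r] for h in new_hs], [c[r] for c in new_cs])
        if all(s is None for s in slots):
            break
    out = [b if b.finished else BeamHypothesis(b.indices, b.logp, True, True)
           for b in beams]
    key = ((lambda h: -h.logp) if length_penalty is None
           else (lambda h: -h.logp / length_penalty(max(1, len(h.indices)))))
    out.sort(key=key)
    return out[:width]


def hypothesis_text(hyp: BeamHypothesis, vocab) -> str:
    idx = [i for i in hyp.indices if i != vocab.end]
    return "".join(vocab.tokens[i] for i in idx)


def decode_latent(latent: np.ndarray, checkpoint: Checkpoint, k: int = 3,
                  width: int = 10, max_len: int = 120
                  ) -> tuple[Optional[str], Optional[int]]:
    """Best valid SMILES among the top-k beams, plus the rank used (1-based).

    Scans hypotheses in rank order 1..k and returns the first whose text
    parses as a molecule; (None, None) when no rank yields a valid SMILES.
    """
    if k < 1 or k > width:
        raise ValueError("need 1 <= k <= width")
    vocab = checkpoint.vocab_out
    hyps = beam_search(checkpoint.params, checkpoint.config, latent, width,
                       max_len, vocab.start, vocab.end)
    for rank, hyp in enumerate(hyps[:k], start=1):
        text = hypothesis_text(hyp, vocab)
        if text and Chem.MolFromSmiles(text) is not None:
            return text, rank
    return None, None


def encode_records(records, checkpoint: Checkpoint,
                   batch_size: int = 256) -> np.ndarray:
    """Latent matrix (n x D) for standardized records.

    The descriptor of a molecule is the latent of its canonical SMILES (or
    its InChI for an InChI-input model), not an average over enumerations.
    """
    vin = checkpoint.vocab_in
    texts = [r.inchi if vin.notation == "inchi" else r.canonical_smiles
             for r in records]
    seqs = [tokenizer.tokenize(t, vin) for t in texts]
    if checkpoint.config.input_reversed:
        seqs = [tokenizer.reverse_content(s) for s in seqs]
    out = []
    for i in range(0, len(seqs), batch_size):
        chunk = seqs[i:i + batch_size]
        toks = tokenizer.pad_batch(chunk)
        mask = (toks != vin.pad).astype(np.float64)
        out.append(seq2seq.encode(checkpoint.params, checkpoint.config,
                                  toks, mask))
    return np.concatenate(out, axis=0)


def extract_descriptors(smiles_list: Sequence[str], checkpoint: Checkpoint,
                        standardize: bool = False
                        ) -> tuple[np.ndarray, list[str], list]:
    """Descriptors for raw SMILES; returns (matrix, kept ids, rejections).

    With ``standardize`` the columns are scaled to zero mean, unit variance
    over this input set (the per-task convention of the QSAR protocol).
    """
    records, rejections = chem_prep.preprocess(
        smiles_list, policy=chem_prep.FilterPolicy(),
        ids=[str(i) for i in range(len(smiles_list))])
    X = (encode_records(records, checkpoint) if records
         else np.zeros((0, checkpoint.config.latent_dim)))
    if standardize:
        if X.shape[0] < 2:
            raise ValueError("degenerate_standardization: need >= 2 molecules")
        X = standardize_columns(X)
    return X, [r.id for r in records], rejections


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance scaling per column over the given set."""
    if X.shape[0] < 2:
        raise ValueError("degenerate_standardization: need >= 2 rows")
    X = np.asarray(X, dtype=np.float64)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-12] = 1.0
    return (X - mean) / std
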