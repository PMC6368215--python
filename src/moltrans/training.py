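"""Training loop for the translation tasks.

Three tasks are supported: ``sml2can`` (enumerated SMILES -> canonical SMILES,
with the canonical string itself used as input half of the time), ``inchi2can``
(InChI -> canonical SMILES) and ``can2can`` (plain autoencoding). Training
uses teacher forcing at every step, Adam with gradient clipping, and monitors
translation quality as single-character accuracy on a held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem_prep, nn, seq2seq, tokenizer
from .chem_prep import MoleculeRecord
from .seq2seq import Checkpoint, ModelConfig
from .tokenizer import TokenSequence, TokenVocabulary

TASKS = ("sml2can", "inchi2can", "can2can")


@dataclass
class TrainConfig:
    """Optimization settings (desk-scale defaults)."""

    steps: int = 20000
    batch_size: int = 64
    lr: float = 1e-3
    lr_decay: float = 0.5          # multiplied in every lr_decay_every steps
    lr_decay_every: int = 10000
    clip_norm: float = 5.0
    latent_noise: float = 0.0      # sd of training-time latent jitter
    dropout: float = 0.0           # inverted dropout on top decoder states
    word_dropout: float = 0.0      # rate of corrupted teacher-forcing inputs
    weight_decay: float = 0.0      # decoupled (AdamW-style)
    holdout_frac: float = 0.05
    eval_every: int = 200
    eval_max: int = 256
    max_len_smiles: int = 120
    max_len_inchi: int = 200
    seed: int = 0


@dataclass
class TrainingPair:
    """One training example: tokenized input, tokenized canonical target and
    the standardized 9-property target."""

    input_tokens: TokenSequence
    target_tokens: TokenSequence
    property_targets: np.ndarray


class PairFactory:
    """Builds training pairs for a task from standardized molecule records.

    Holds the two vocabularies and the property-standardization constants so
    a pair is a pure function of (record, task, rng draw). With
    ``reverse_input`` the encoder consumes the input tokens in reverse order
    (a standard seq2seq device that shortens the path between the decoder's
    first outputs and the encoder tokens that determine them).
    """

    def __init__(self, vocab_in: TokenVocabulary, vocab_out: TokenVocabulary,
                 prop_mean: np.ndarray, prop_std: np.ndarray,
                 reverse_input: bool = False):
        self.vocab_in = vocab_in
        self.vocab_out = vocab_out
        self.prop_mean = prop_mean
        self.prop_std = prop_std
        self.reverse_input = reverse_input
        self._mol_cache: dict[str, object] = {}

    def _mol(self, record: MoleculeRecord):
        mol = self._mol_cache.get(record.canonical_smiles)
        if mol is None:
            mol = record.mol()
            self._mol_cache[record.canonical_smiles] = mol
        return mol

    def standardize_properties(self, props: np.ndarray) -> np.ndarray:
        return (props - self.prop_mean) / self.prop_std

    def make_pair(self, record: MoleculeRecord, task: str,
                  rng: np.random.Generator) -> TrainingPair:
        """Input selection per task; the target is always the canonical SMILES.

        For ``sml2can`` the input is an enumerated random SMILES with
        probability 0.5 and the canonical SMILES otherwise; an enumerated
        variant containing a token unseen at vocabulary-build time falls back
        to the canonical input.
        """
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}")
        can = record.canonical_smiles
        if task == "inchi2can":
            input_text = record.inchi
        elif task == "sml2can" and rng.random() < 0.5:
            input_text = chem_prep.enumerate_smiles(self._mol(record), rng)
        else:
            input_text = can
        try:
            inp = tokenizer.tokenize(input_text, self.vocab_in)
        except tokenizer.TokenizationError:
            if task == "sml2can" and input_text != can:
                inp = tokenizer.tokenize(can, self.vocab_in)
            else:
                raise ValueError(
                    f"record {record.id!r}: untokenizable input") from None
        if self.reverse_input:
            inp = tokenizer.reverse_content(inp)
        tgt = tokenizer.tokenize(can, self.vocab_out)
        return TrainingPair(
            input_tokens=inp, target_tokens=tgt,
            property_targets=self.standardize_properties(record.properties))


def char_accuracy(step_distributions: np.ndarray, targets: np.ndarray,
                  mask: np.ndarray) -> float:
    """Fraction of unmasked positions whose argmax matches the target token."""
    m = mask.astype(bool)
    if not m.any():
        raise ValueError("no unmasked positions")
    pred = step_distributions.argmax(axis=-1)
    return float((pred == targets)[m].mean())


def build_factory(corpus: Sequence[MoleculeRecord], task: str,
                  rng: np.random.Generator,
                  n_enum_per_mol: int = 5,
                  reverse_input: bool = False) -> PairFactory:
    """Derive vocabularies and property standardization from the corpus.

    For SMILES input vocabularies the canonical strings are augmented with a
    few enumerated variants per molecule so tokens that only ever appear in
    non-canonical spellings are covered.
    """
    canonicals = [r.canonical_smiles for r in corpus]
    vocab_out = tokenizer.build_vocabulary("smiles", canonicals)
    if task == "inchi2can":
        vocab_in = tokenizer.build_vocabulary("inchi", [r.inchi for r in corpus])
    elif task == "sml2can":
        aug = list(canonicals)
        for r in corpus:
            mol = r.mol()
            aug.extend(chem_prep.enumerate_smiles(mol, rng)
                       for _ in range(n_enum_per_mol))
        vocab_in = tokenizer.build_vocabulary("smiles", aug)
    else:
        vocab_in = vocab_out
    props = np.stack([r.properties for r in corpus])
    mean = props.mean(axis=0)
    std = props.std(axis=0)
    std[std < 1e-12] = 1.0
    return PairFactory(vocab_in, vocab_out, mean, std,
                       reverse_input=reverse_input)


def _batch_arrays(pairs: list[TrainingPair]):
    enc = tokenizer.pad_batch([p.input_tokens for p in pairs])
    tgt = tokenizer.pad_batch([p.target_tokens for p in pairs])
    vin, vout = pairs[0].input_tokens.vocab, pairs[0].target_tokens.vocab
    enc_mask = (enc != vin.pad).astype(np.float64)
    tgt_mask = (tgt != vout.pad).astype(np.float64)
    props = np.stack([p.property_targets for p in pairs])
    return enc, enc_mask, tgt, tgt_mask, props


def evaluate_char_accuracy(params: dict, cfg: ModelConfig,
                           factory: PairFactory, records, task: str,
                           rng: np.random.Generator,
                           batch_size: int = 128) -> float:
    """Teacher-forced single-character accuracy over a record set."""
    total, correct = 0, 0
    for i in range(0, len(records), batch_size):
        chunk = records[i:i + batch_size]
        pairs = [factory.make_pair(r, task, rng) for r in chunk]
        enc, enc_mask, tgt, tgt_mask, _ = _batch_arrays(pairs)
        z = seq2seq.encode(params, cfg, enc, enc_mask)
        probs = seq2seq.decode_teacher_forced(params, cfg, z, tgt,
                                              factory.vocab_out.start)
        m = tgt_mask.astype(bool)
        correct += int((probs.argmax(-1) == tgt)[m].sum())
        total += int(m.sum())
    return correct / total


def train(corpus: Sequence[MoleculeRecord], task: str,
          model_config: dict | ModelConfig | None = None,
          train_config: TrainConfig | None = None,
          seed: int = 0) -> tuple[Checkpoint, pd.DataFrame]:
    """Train a translation model on a standardized corpus.

    Returns the final checkpoint and a metric log with one row per eval
    interval: (step, loss, ce, mse, char_acc). All randomness — holdout
    split, initialization, shuffling, augmentation — derives from ``seed``,
    so the metric trajectory is reproducible on a fixed platform.
    """
    tc = train_config or TrainConfig()
    rng = np.random.default_rng(seed)
    if isinstance(model_config, ModelConfig):
        reversed_in = model_config.input_reversed
    else:
        reversed_in = bool(dict(model_config or {}).get("input_reversed",
                                                        False))
    factory = build_factory(corpus, task, rng, reverse_input=reversed_in)

    if isinstance(model_config, ModelConfig):
        cfg = replace(model_config,
                      vocab_in_size=factory.vocab_in.size,
                      vocab_out_size=factory.vocab_out.size)
    else:
        kw = dict(model_config or {})
        cfg = ModelConfig(vocab_in_size=factory.vocab_in.size,
                          vocab_out_size=factory.vocab_out.size, **kw)
    params = seq2seq.init_params(cfg, rng)
    opt = nn.Adam(params, lr=tc.lr, clip_norm=tc.clip_norm)

    n = len(corpus)
    perm = rng.permutation(n)
    n_hold = max(1, int(round(tc.holdout_frac * n)))
    hold_idx = perm[:n_hold]
    train_idx = perm[n_hold:]
    holdout = [corpus[i] for i in hold_idx[: tc.eval_max]]
    train_set = [corpus[i] for i in train_idx]
    eval_seed = int(rng.integers(2**31))

    log_rows = []
    last_good = None

    def log_point(step):
        acc = evaluate_char_accuracy(
            params, cfg, factory, holdout, task,
            np.random.default_rng(eval_seed))
        return {"step": step, "loss": np.nan, "ce": np.nan, "mse": np.nan,
                "char_acc": acc}

    # step-0 point: untrained model
    row0 = log_point(0)
    log_rows.append(row0)

    for step in range(1, tc.steps + 1):
        idx = rng.integers(0, len(train_set), size=tc.batch_size)
        pairs = [factory.make_pair(train_set[i], task, rng) for i in idx]
        enc, enc_mask, tgt, tgt_mask, props = _batch_arrays(pairs)
        noise = (rng.normal(scale=tc.latent_noise,
                            size=(len(pairs), cfg.latent_dim))
                 if tc.latent_noise > 0 else None)
        drop = None
        if tc.dropout > 0:
            keep = 1.0 - tc.dropout
            drop = (rng.random((tgt.shape[0], tgt.shape[1],
                                cfg.decoder_layers[-1])) < keep) / keep
        dec_in = None
        if tc.word_dropout > 0:
            B, T = tgt.shape
            dec_in = np.concatenate(
                [np.full((B, 1), factory.vocab_out.start, dtype=np.int64),
                 tgt[:, :-1]], axis=1)
            hit = rng.random((B, T)) < tc.word_dropout
            repl = rng.integers(3, factory.vocab_out.size, size=(B, T))
            dec_in = np.where(hit, repl, dec_in)
        loss, metrics, grads, _ = seq2seq.loss_and_grads(
            params, cfg, enc, enc_mask, tgt, tgt_mask, props,
            factory.vocab_out.start, latent_noise=noise, dropout_mask=drop,
            dec_in=dec_in)
        if not np.isfinite(loss):
            if last_good is None:
                raise RuntimeError("training diverged before first checkpoint")
            params = last_good
            break
        lr = tc.lr * (tc.lr_decay ** (step // tc.lr_decay_every))
        opt.step(params, grads, lr=lr, weight_decay=tc.weight_decay)
        if step % tc.eval_every == 0 or step == tc.steps:
            row = log_point(step)
            row.update({k: metrics[k] for k in ("loss", "ce", "mse")})
            log_rows.append(row)
            last_good = {k: v.copy() for k, v in params.items()}

    checkpoint = Checkpoint(
        params=params, config=cfg,
        vocab_in=factory.vocab_in, vocab_out=factory.vocab_out,
        prop_mean=factory.prop_mean, prop_std=factory.prop_std)
    log = pd.DataFrame(log_rows)
    log.attrs["holdout_ids"] = [corpus[i].id for i in hold_idx]
    return checkpoint, log
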