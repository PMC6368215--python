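"""The translation network: encoder -> latent bottleneck -> decoder + classifier.

A recurrent (LSTM) encoder reads the tokenized input notation; the final cell
states of all encoder layers are concatenated and mapped by a fully connected
layer through a bounded (tanh) bottleneck to the latent vector — the molecular
descriptor. The decoder is an LSTM whose initial cell state in each layer is
produced by that layer's own fully connected map from the latent; it is
trained with teacher forcing to emit the canonical SMILES. A 3-layer fully
connected classifier predicts the nine standardized molecular properties from
the latent, and the joint loss is masked cross-entropy plus ``loss_mix`` times
the property mean squared error.

All forward passes are pure NumPy; ``loss_and_grads`` implements the exact
analytic backward pass (verified against finite differences in the tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .tokenizer import TokenVocabulary


@dataclass
class ModelConfig:
    """Architecture hyperparameters; sizes are free, property_dim is fixed at 9."""

    vocab_in_size: int
    vocab_out_size: int
    encoder_layers: tuple = (256, 256)
    latent_dim: int = 64
    decoder_layers: tuple = (256, 256)
    classifier_hidden: tuple = (64, 32)
    property_dim: int = 9
    loss_mix: float = 1.0
    bottleneck_activation: str = "tanh"
    encoder_kind: str = "recurrent"
    input_reversed: bool = False   # encoder consumes tokens right-to-left
    bidirectional_encoder: bool = False
    decoder_hidden_init: bool = False  # own affine map for h0 (else tanh(c0))

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.property_dim != 9:
            raise ValueError("property_dim is fixed at 9")
        self.encoder_layers = tuple(self.encoder_layers)
        self.decoder_layers = tuple(self.decoder_layers)
        self.classifier_hidden = tuple(self.classifier_hidden)
        if len(self.classifier_hidden) != 2:
            raise ValueError("classifier has exactly two hidden layers")


def init_params(cfg: ModelConfig, rng: np.random.Generator,
                dtype=np.float32) -> dict:
    """Glorot-uniform initialization of every weight matrix, zero biases.

    float32 is the training default; float64 is available for numerical
    verification (the finite-difference gradient checks).
    """
    p: dict[str, np.ndarray] = {}
    size_in = cfg.vocab_in_size
    for l, h in enumerate(cfg.encoder_layers):
        p[f"enc{l}_Wx"] = nn.glorot(rng, size_in, 4 * h, dtype)
        p[f"enc{l}_Wh"] = nn.glorot(rng, h, 4 * h, dtype)
        p[f"enc{l}_b"] = np.zeros(4 * h, dtype)
        # forget-gate bias 1: standard trick for stable early training
        p[f"enc{l}_b"][h:2 * h] = 1.0
        size_in = h
    if cfg.bidirectional_encoder:
        size_in = cfg.vocab_in_size
        for l, h in enumerate(cfg.encoder_layers):
            p[f"encb{l}_Wx"] = nn.glorot(rng, size_in, 4 * h, dtype)
            p[f"encb{l}_Wh"] = nn.glorot(rng, h, 4 * h, dtype)
            p[f"encb{l}_b"] = np.zeros(4 * h, dtype)
            p[f"encb{l}_b"][h:2 * h] = 1.0
            size_in = h
    concat = sum(cfg.encoder_layers) * (2 if cfg.bidirectional_encoder else 1)
    p["bott_W"] = nn.glorot(rng, concat, cfg.latent_dim, dtype)
    p["bott_b"] = np.zeros(cfg.latent_dim, dtype)
    size_in = cfg.vocab_out_size
    for l, h in enumerate(cfg.decoder_layers):
        p[f"dini{l}_W"] = nn.glorot(rng, cfg.latent_dim, h, dtype)
        p[f"dini{l}_b"] = np.zeros(h, dtype)
        if cfg.decoder_hidden_init:
            p[f"dinh{l}_W"] = nn.glorot(rng, cfg.latent_dim, h, dtype)
            p[f"dinh{l}_b"] = np.zeros(h, dtype)
        p[f"dec{l}_Wx"] = nn.glorot(rng, size_in, 4 * h, dtype)
        p[f"dec{l}_Wh"] = nn.glorot(rng, h, 4 * h, dtype)
        p[f"dec{l}_b"] = np.zeros(4 * h, dtype)
        p[f"dec{l}_b"][h:2 * h] = 1.0
        size_in = h
    p["out_W"] = nn.glorot(rng, cfg.decoder_layers[-1], cfg.vocab_out_size,
                           dtype)
    p["out_b"] = np.zeros(cfg.vocab_out_size, dtype)
    h1, h2 = cfg.classifier_hidden
    p["cls_W1"] = nn.glorot(rng, cfg.latent_dim, h1, dtype)
    p["cls_b1"] = np.zeros(h1, dtype)
    p["cls_W2"] = nn.glorot(rng, h1, h2, dtype)
    p["cls_b2"] = np.zeros(h2, dtype)
    p["cls_W3"] = nn.glorot(rng, h2, cfg.property_dim, dtype)
    p["cls_b3"] = np.zeros(cfg.property_dim, dtype)
    return p


def _token_gates(Wx: np.ndarray, tokens: np.ndarray) -> np.ndarray:
    # one-hot input @ Wx is a row lookup
    return Wx[tokens]


def _scatter_dWx(n_vocab: int, tokens: np.ndarray, dgates: np.ndarray) -> np.ndarray:
    B, T, H4 = dgates.shape
    onehot = np.zeros((B * T, n_vocab), dtype=dgates.dtype)
    onehot[np.arange(B * T), tokens.reshape(-1)] = 1.0
    return onehot.T @ dgates.reshape(B * T, H4)


def _reverse_rows(tokens: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-row reversal of the unmasked prefix of a (B, T) token array."""
    B, T = tokens.shape
    lens = mask.astype(np.int64).sum(axis=1)
    ar = np.arange(T)[None, :]
    idx = np.where(ar < lens[:, None], lens[:, None] - 1 - ar, ar)
    return tokens[np.arange(B)[:, None], idx]


def _encode_stack(params, cfg, prefix, tokens, m, dtype):
    B = tokens.shape[0]
    x_gates = _token_gates(params[f"{prefix}0_Wx"], tokens)
    caches, c_finals, layer_inputs = [], [], []
    inp = None
    for l, h in enumerate(cfg.encoder_layers):
        if l > 0:
            layer_inputs.append(inp)
            x_gates = inp @ params[f"{prefix}{l}_Wx"]
        H_seq, hT, cT, cache = nn.lstm_forward(
            x_gates, params[f"{prefix}{l}_Wh"], params[f"{prefix}{l}_b"],
            np.zeros((B, h), dtype), np.zeros((B, h), dtype), mask=m)
        caches.append(cache)
        c_finals.append(cT)
        inp = H_seq
    return c_finals, caches, layer_inputs


def encode(params: dict, cfg: ModelConfig, tokens: np.ndarray,
           mask: np.ndarray, return_cache: bool = False):
    """Map a (B, T) token batch to (B, D) latents.

    ``mask`` (B, T) marks real positions; padded steps freeze the recurrent
    state so the concatenated final cell states are taken at each sequence's
    true length before the bottleneck projection. With a bidirectional
    encoder a second LSTM stack reads each sequence reversed and its final
    cell states join the concatenation.
    """
    dtype = params["enc0_Wx"].dtype
    m = mask.astype(dtype)
    c_finals, caches, layer_inputs = _encode_stack(
        params, cfg, "enc", tokens, m, dtype)
    cache = {"caches": caches, "tokens": tokens, "mask": m,
             "layer_inputs": layer_inputs}
    if cfg.bidirectional_encoder:
        rev = _reverse_rows(tokens, m)
        cb, cachesb, layer_inputsb = _encode_stack(
            params, cfg, "encb", rev, m, dtype)
        c_finals = c_finals + cb
        cache.update({"cachesb": cachesb, "tokensb": rev,
                      "layer_inputsb": layer_inputsb})
    concat = np.concatenate(c_finals, axis=1)
    u = concat @ params["bott_W"] + params["bott_b"]
    z = np.tanh(u) if cfg.bottleneck_activation == "tanh" else u
    if return_cache:
        cache.update({"concat": concat, "z": z})
        return z, cache
    return z


def _encode_stack_backward(params, cfg, prefix, dcTs, caches, layer_inputs,
                           tokens, dtype, grads):
    B, T = tokens.shape
    dH_upper = None
    for l in range(len(cfg.encoder_layers) - 1, -1, -1):
        h = cfg.encoder_layers[l]
        dH_seq = (np.zeros((B, T, h), dtype) if dH_upper is None
                  else dH_upper)
        dgx, dWh, db, _, _ = nn.lstm_backward(
            dH_seq, np.zeros((B, h), dtype), dcTs[l], caches[l])
        grads[f"{prefix}{l}_Wh"] += dWh
        grads[f"{prefix}{l}_b"] += db
        if l > 0:
            grads[f"{prefix}{l}_Wx"] += np.einsum(
                "bti,btj->ij", layer_inputs[l - 1], dgx)
            dH_upper = dgx @ params[f"{prefix}{l}_Wx"].T
        else:
            grads[f"{prefix}0_Wx"] += _scatter_dWx(
                cfg.vocab_in_size, tokens, dgx)


def _encode_backward(params, cfg, dz, cache, grads):
    z, concat = cache["z"], cache["concat"]
    du = dz * (1.0 - z * z) if cfg.bottleneck_activation == "tanh" else dz
    grads["bott_W"] += concat.T @ du
    grads["bott_b"] += du.sum(axis=0)
    dconcat = du @ params["bott_W"].T
    dtype = dz.dtype
    # split back into per-layer final-cell gradients
    dcTs, off = [], 0
    sizes = list(cfg.encoder_layers)
    if cfg.bidirectional_encoder:
        sizes = sizes + sizes
    for h in sizes:
        dcTs.append(dconcat[:, off:off + h])
        off += h
    n = len(cfg.encoder_layers)
    _encode_stack_backward(params, cfg, "enc", dcTs[:n], cache["caches"],
                           cache["layer_inputs"], cache["tokens"], dtype,
                           grads)
    if cfg.bidirectional_encoder:
        _encode_stack_backward(params, cfg, "encb", dcTs[n:],
                               cache["cachesb"], cache["layer_inputsb"],
                               cache["tokensb"], dtype, grads)


def decoder_initial_states(params: dict, cfg: ModelConfig, latent: np.ndarray,
                           return_cache: bool = False):
    """Per-layer initial states from the latent.

    c0 = tanh(affine_c(latent)); h0 is tanh(c0) by default, or its own
    tanh(affine_h(latent)) when the config enables a separate hidden-state
    initialization map.
    """
    hs, cs, cache = [], [], []
    for l in range(len(cfg.decoder_layers)):
        a = latent @ params[f"dini{l}_W"] + params[f"dini{l}_b"]
        c0 = np.tanh(a)
        if cfg.decoder_hidden_init:
            h0 = np.tanh(latent @ params[f"dinh{l}_W"] + params[f"dinh{l}_b"])
        else:
            h0 = np.tanh(c0)
        hs.append(h0)
        cs.append(c0)
        cache.append((c0, h0))
    if return_cache:
        return hs, cs, cache
    return hs, cs


def decode_teacher_forced(params: dict, cfg: ModelConfig, latent: np.ndarray,
                          targets: np.ndarray, start_index: int,
                          return_cache: bool = False,
                          dropout_mask: np.ndarray | None = None,
                          dec_in: np.ndarray | None = None):
    """Teacher-forced step distributions (B, T, N_out).

    The decoder input at step t is the true target token t-1 (start token at
    t = 0), so distribution t is conditioned only on target tokens < t.
    """
    B, T = targets.shape
    if dec_in is None:
        dec_in = np.concatenate(
            [np.full((B, 1), start_index, dtype=np.int64), targets[:, :-1]],
            axis=1)
    hs, cs, init_cache = decoder_initial_states(params, cfg, latent, True)
    x_gates = _token_gates(params["dec0_Wx"], dec_in)
    caches, inp = [], None
    inputs = []
    for l in range(len(cfg.decoder_layers)):
        if l > 0:
            inputs.append(inp)
            x_gates = inp @ params[f"dec{l}_Wx"]
        H_seq, _, _, cache = nn.lstm_forward(
            x_gates, params[f"dec{l}_Wh"], params[f"dec{l}_b"], hs[l], cs[l])
        caches.append(cache)
        inp = H_seq
    if dropout_mask is not None:
        inp = inp * dropout_mask.astype(inp.dtype)
    logits = inp @ params["out_W"] + params["out_b"]
    probs = nn.softmax(logits)
    if return_cache:
        return probs, {"logits": logits, "H_top": inp, "caches": caches,
                       "dec_in": dec_in, "init": init_cache, "inputs": inputs,
                       "latent": latent}
    return probs


def classify_properties(params: dict, cfg: ModelConfig, latent: np.ndarray,
                        return_cache: bool = False):
    """3-layer fully connected map latent -> 9 properties (ReLU hiddens)."""
    a1 = latent @ params["cls_W1"] + params["cls_b1"]
    r1 = np.maximum(a1, 0.0)
    a2 = r1 @ params["cls_W2"] + params["cls_b2"]
    r2 = np.maximum(a2, 0.0)
    pred = r2 @ params["cls_W3"] + params["cls_b3"]
    if return_cache:
        return pred, {"r1": r1, "r2": r2, "latent": latent}
    return pred


def joint_loss(step_distributions: np.ndarray, targets: np.ndarray,
               prop_pred: np.ndarray, prop_true: np.ndarray,
               mask: np.ndarray, loss_mix: float = 1.0) -> float:
    """Reference joint objective (no gradients).

    Mean over unmasked positions of -log p(correct token), plus ``loss_mix``
    times the mean squared error over the standardized properties.
    """
    m = mask.astype(np.float64)
    n = m.sum()
    if n == 0:
        raise ValueError("no unmasked positions")
    B, T = targets.shape
    picked = step_distributions[np.arange(B)[:, None], np.arange(T)[None, :], targets]
    ce = -(np.log(np.clip(picked, 1e-300, None)) * m).sum() / n
    mse = float(np.mean((prop_pred - prop_true) ** 2))
    return float(ce + loss_mix * mse)


def loss_and_grads(params: dict, cfg: ModelConfig, enc_tokens, enc_mask,
                   targets, target_mask, prop_true, start_index: int,
                   latent_noise: np.ndarray | None = None,
                   dropout_mask: np.ndarray | None = None,
                   dec_in: np.ndarray | None = None):
    """Joint loss, metrics and analytic gradients for one batch.

    ``latent_noise`` (B, D), when given, is added to the latent before the
    decoder and classifier — a denoising regularizer active only during
    training; the gradient passes through the additive noise unchanged.
    ``dropout_mask`` (B, T, H_top), when given, multiplies the top decoder
    hidden states before the output projection (inverted dropout, drawn by
    the caller so training stays seed-reproducible).
    """
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dtype = params["enc0_Wx"].dtype
    prop_true = np.asarray(prop_true, dtype=dtype)
    z, enc_cache = encode(params, cfg, enc_tokens, enc_mask, return_cache=True)
    z_dec = z if latent_noise is None else (z + latent_noise.astype(dtype))
    probs, dec_cache = decode_teacher_forced(
        params, cfg, z_dec, targets, start_index, return_cache=True,
        dropout_mask=dropout_mask, dec_in=dec_in)
    pred, cls_cache = classify_properties(params, cfg, z_dec, return_cache=True)

    ce, dlogits, _ = nn.masked_softmax_ce(dec_cache["logits"], targets, target_mask)
    mse = float(np.mean((pred - prop_true) ** 2))
    loss = ce + cfg.loss_mix * mse

    # ---- decoder/output backward
    B, T = targets.shape
    H_top = dec_cache["H_top"]
    grads["out_W"] += np.einsum("bti,btj->ij", H_top, dlogits)
    grads["out_b"] += dlogits.sum(axis=(0, 1))
    dH = dlogits @ params["out_W"].T
    if dropout_mask is not None:
        dH = dH * dropout_mask.astype(dH.dtype)
    dlatent = np.zeros_like(z)
    for l in range(len(cfg.decoder_layers) - 1, -1, -1):
        h = cfg.decoder_layers[l]
        dgx, dWh, db, dh0, dc0 = nn.lstm_backward(
            dH, np.zeros((B, h), dH.dtype), np.zeros((B, h), dH.dtype),
            dec_cache["caches"][l])
        # note: dh0/dc0 returned above already include recurrent paths
        grads[f"dec{l}_Wh"] += dWh
        grads[f"dec{l}_b"] += db
        if l > 0:
            lower_in = dec_cache["inputs"][l - 1]
            grads[f"dec{l}_Wx"] += np.einsum("bti,btj->ij", lower_in, dgx)
            dH = dgx @ params[f"dec{l}_Wx"].T
        else:
            grads["dec0_Wx"] += _scatter_dWx(cfg.vocab_out_size,
                                             dec_cache["dec_in"], dgx)
        # initial-state maps
        c0, h0 = dec_cache["init"][l]
        if cfg.decoder_hidden_init:
            dah = dh0 * (1.0 - h0 * h0)
            grads[f"dinh{l}_W"] += z_dec.T @ dah
            grads[f"dinh{l}_b"] += dah.sum(axis=0)
            dlatent += dah @ params[f"dinh{l}_W"].T
            dc0_total = dc0
        else:
            dc0_total = dc0 + dh0 * (1.0 - h0 * h0)
        da = dc0_total * (1.0 - c0 * c0)
        grads[f"dini{l}_W"] += z_dec.T @ da
        grads[f"dini{l}_b"] += da.sum(axis=0)
        dlatent += da @ params[f"dini{l}_W"].T

    # ---- classifier backward
    dpred = cfg.loss_mix * 2.0 * (pred - prop_true) / prop_true.size
    r1, r2 = cls_cache["r1"], cls_cache["r2"]
    grads["cls_W3"] += r2.T @ dpred
    grads["cls_b3"] += dpred.sum(axis=0)
    dr2 = (dpred @ params["cls_W3"].T) * (r2 > 0)
    grads["cls_W2"] += r1.T @ dr2
    grads["cls_b2"] += dr2.sum(axis=0)
    dr1 = (dr2 @ params["cls_W2"].T) * (r1 > 0)
    grads["cls_W1"] += z_dec.T @ dr1
    grads["cls_b1"] += dr1.sum(axis=0)
    dlatent += dr1 @ params["cls_W1"].T

    _encode_backward(params, cfg, dlatent, enc_cache, grads)

    metrics = {"loss": float(loss), "ce": float(ce), "mse": mse}
    return float(loss), metrics, grads, probs


def decoder_step(params: dict, cfg: ModelConfig, hs, cs, tokens: np.ndarray):
    """One decoding step: advance all layers for tokens (B,), return probs."""
    x_gates = _token_gates(params["dec0_Wx"], tokens[:, None])
    new_hs, new_cs, inp = [], [], None
    for l in range(len(cfg.decoder_layers)):
        if l > 0:
            x_gates = inp[:, None, :] @ params[f"dec{l}_Wx"]
        _, h, c, _ = nn.lstm_forward(
            x_gates, params[f"dec{l}_Wh"], params[f"dec{l}_b"], hs[l], cs[l])
        new_hs.append(h)
        new_cs.append(c)
        inp = h
    logits = inp @ params["out_W"] + params["out_b"]
    return nn.softmax(logits), new_hs, new_cs


@dataclass
class Checkpoint:
    """Self-describing model archive: parameters, config, vocabularies and
    the property-standardization constants fitted on the training corpus."""

    params: dict
    config: ModelConfig
    vocab_in: TokenVocabulary
    vocab_out: TokenVocabulary
    prop_mean: np.ndarray
    prop_std: np.ndarray

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        meta = {"config": cfg,
                "prop_mean": self.prop_mean.tolist(),
                "prop_std": self.prop_std.tolist()}
        (path / "model.json").write_text(json.dumps(meta, indent=1))
        (path / "vocab_in.json").write_text(self.vocab_in.to_json())
        (path / "vocab_out.json").write_text(self.vocab_out.to_json())
        np.savez(path / "params.npz", **self.params)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        cfg = ModelConfig(**meta["config"])
        with np.load(path / "params.npz") as npz:
            params = {k: npz[k].copy() for k in npz.files}
        return cls(
            params=params, config=cfg,
            vocab_in=TokenVocabulary.from_json((path / "vocab_in.json").read_text()),
            vocab_out=TokenVocabulary.from_json((path / "vocab_out.json").read_text()),
            prop_mean=np.asarray(meta["prop_mean"]),
            prop_std=np.asarray(meta["prop_std"]),
        )
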