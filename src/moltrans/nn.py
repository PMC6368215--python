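"""Minimal NumPy neural-network primitives for the translation model.

Implements exactly what the seq2seq model needs — batched LSTM layers with
explicit backward passes, dense layers, masked softmax cross-entropy and an
Adam optimizer over flat parameter dicts. Gate order throughout is
(input, forget, output, cell) — the three sigmoid gates contiguous so one
call covers them; forward passes return a cache consumed by the matching
backward pass.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    # clipping keeps exp() in range; exact for |x| < 30 at both precisions
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           dtype=np.float64) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


def lstm_forward(gates_x, Wh, b, h0, c0, mask=None):
    """Run an LSTM layer over a precomputed input projection.

    gates_x : (B, T, 4H) — input contribution ``x_t @ Wx`` for every step.
    mask    : (B, T) floats; where 0 the state is frozen (padding), so the
              final state is the state at each sequence's true length.

    Returns (H_seq (B,T,H), h_T, c_T, cache).
    """
    B, T, H4 = gates_x.shape
    H = H4 // 4
    h, c = h0, c0
    H_seq = np.empty((B, T, H), dtype=gates_x.dtype)
    cache_steps = []
    for t in range(T):
        g = gates_x[:, t] + h @ Wh + b
        ifo = sigmoid(g[:, : 3 * H])
        i = ifo[:, :H]
        f = ifo[:, H:2 * H]
        o = ifo[:, 2 * H:]
        gg = np.tanh(g[:, 3 * H:])
        c_new = f * c + i * gg
        ch = np.tanh(c_new)
        h_new = o * ch
        if mask is not None:
            m = mask[:, t:t + 1]
            h_new = m * h_new + (1.0 - m) * h
            c_new = m * c_new + (1.0 - m) * c
        cache_steps.append((h, c, i, f, gg, o, c_new, ch))
        h, c = h_new, c_new
        H_seq[:, t] = h
    cache = {"steps": cache_steps, "Wh": Wh, "mask": mask, "H": H}
    return H_seq, h, c, cache


def lstm_backward(dH_seq, dh_T, dc_T, cache):
    """Backward pass of :func:`lstm_forward`.

    dH_seq : (B, T, H) gradient w.r.t. every per-step output (may be zeros).
    Returns (dgates_x (B,T,4H), dWh, db, dh0, dc0).
    """
    steps = cache["steps"]
    Wh, mask, H = cache["Wh"], cache["mask"], cache["H"]
    B, T, _ = dH_seq.shape
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H, dtype=Wh.dtype)
    dgates_x = np.empty((B, T, 4 * H), dtype=Wh.dtype)
    dh = dh_T.copy()
    dc = dc_T.copy()
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, i, f, gg, o, c_new, ch = steps[t]
        dh += dH_seq[:, t]
        if mask is not None:
            m = mask[:, t:t + 1]
            dh_skip = (1.0 - m) * dh
            dc_skip = (1.0 - m) * dc
            dh = m * dh
            dc = m * dc
        else:
            dh_skip = dc_skip = 0.0
        do = dh * ch
        dc = dc + dh * o * (1.0 - ch * ch)
        di = dc * gg
        df = dc * c_prev
        dgg = dc * i
        dc_prev = dc * f
        dG = dgates_x[:, t]
        dG[:, :H] = di * i * (1.0 - i)
        dG[:, H:2 * H] = df * f * (1.0 - f)
        dG[:, 2 * H:3 * H] = do * o * (1.0 - o)
        dG[:, 3 * H:] = dgg * (1.0 - gg * gg)
        dWh += h_prev.T @ dG
        db += dG.sum(axis=0)
        dh = dG @ Wh.T + dh_skip
        dc = dc_prev + dc_skip
    return dgates_x, dWh, db, dh, dc


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def masked_softmax_ce(logits, targets, mask):
    """Mean cross-entropy over unmasked positions.

    logits (B,T,N); targets (B,T) int; mask (B,T) bool/float.
    Returns (loss, dlogits, probs); dlogits already divided by the number of
    unmasked positions.
    """
    p = softmax(logits)
    B, T, N = logits.shape
    m = mask.astype(logits.dtype)
    n_pos = float(m.sum())
    if n_pos == 0:
        raise ValueError("no unmasked positions")
    rows = np.arange(B)[:, None], np.arange(T)[None, :]
    picked = p[rows[0], rows[1], targets]
    loss = -(np.log(np.clip(picked, 1e-30, None)) * m).sum() / n_pos
    dlogits = p.copy()
    dlogits[rows[0], rows[1], targets] -= 1.0
    dlogits *= (m / n_pos)[:, :, None]
    return loss, dlogits, p


class Adam:
    """Adam over a dict of parameter arrays, with global gradient-norm clipping."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8, clip_norm=5.0):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float | None = None,
             weight_decay: float = 0.0):
        if self.clip_norm is not None:
            norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        lr = self.lr if lr is None else lr
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if weight_decay:
                params[k] -= lr * weight_decay * params[k]
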