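"""Low-level sequence-model primitives (NumPy).

Forward functions return ``(out, cache)``; backward functions take the
upstream gradient and the cache and return input/parameter gradients.  All
primitives are exact (no stochastic kernels), so finite-difference gradient
checks apply; the only stochastic operation is inverted dropout, whose mask
is supplied explicitly.

Shapes follow the (batch, time, channels) convention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv1d_forward",
    "conv1d_backward",
    "relu_forward",
    "relu_backward",
    "maxpool1d_forward",
    "maxpool1d_backward",
    "lstm_forward",
    "lstm_backward",
    "dense_forward",
    "dense_backward",
    "dropout_mask",
    "softmax",
    "softmax_cross_entropy",
    "glorot_uniform",
    "AdamOptimizer",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


# ---------------------------------------------------------------------------
# convolution (1-D, 'same' padding, stride 1)

def conv1d_forward(x, w, b):
    """x: (B, T, C); w: (K, C, F); b: (F,) -> out (B, T, F)."""
    B, T, C = x.shape
    K, _, F = w.shape
    pad = K // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    # (B, T, C, K) -> (B, T, K, C) -> (B, T, K*C)
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B, T, K * C)
    w2 = w.reshape(K * C, F)
    out = cols @ w2 + b
    return out, (cols, w, x.shape)


def conv1d_backward(dout, cache):
    cols, w, x_shape = cache
    B, T, C = x_shape
    K, _, F = w.shape
    pad = K // 2
    w2 = w.reshape(K * C, F)
    db = dout.sum(axis=(0, 1))
    dw = (cols.reshape(-1, K * C).T @ dout.reshape(-1, F)).reshape(K, C, F)
    dcols = (dout @ w2.T).reshape(B, T, K, C)
    dxp = np.zeros((B, T + 2 * pad, C), dtype=dout.dtype)
    for k in range(K):
        dxp[:, k : k + T, :] += dcols[:, :, k, :]
    dx = dxp[:, pad : pad + T, :]
    return dx, dw, db


# ---------------------------------------------------------------------------
# pointwise / pooling

def relu_forward(x):
    out = np.maximum(x, 0)
    return out, (x > 0)


def relu_backward(dout, cache):
    return dout * cache


def maxpool1d_forward(x, size: int):
    """Non-overlapping max pooling (stride == size); T must divide by size."""
    B, T, C = x.shape
    if T % size:
        raise ValueError(f"time length {T} not divisible by pool size {size}")
    xr = x.reshape(B, T // size, size, C)
    idx = xr.argmax(axis=2)
    out = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (idx, x.shape, size)


def maxpool1d_backward(dout, cache):
    idx, x_shape, size = cache
    B, T, C = x_shape
    dxr = np.zeros((B, T // size, size, C), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[:, :, None, :], dout[:, :, None, :], axis=2)
    return dxr.reshape(B, T, C)


# ---------------------------------------------------------------------------
# LSTM (returns the final hidden state; zero initial state)

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def lstm_forward(x, wx, wh, b):
    """x: (B, T, D); wx: (D, 4H); wh: (H, 4H); b: (4H,) -> h_T (B, H).

    Gate layout along the 4H axis: input, forget, cell-candidate, output.
    """
    B, T, D = x.shape
    H = wh.shape[0]
    h = np.zeros((B, H), dtype=x.dtype)
    c = np.zeros((B, H), dtype=x.dtype)
    gates_seq = np.empty((T, B, 4 * H), dtype=x.dtype)
    c_seq = np.empty((T, B, H), dtype=x.dtype)
    h_prev_seq = np.empty((T, B, H), dtype=x.dtype)
    for t in range(T):
        z = x[:, t, :] @ wx + h @ wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        h_prev_seq[t] = h
        c = f * c + i * g
        h = o * np.tanh(c)
        gates_seq[t] = np.concatenate([i, f, g, o], axis=1)
        c_seq[t] = c
    cache = (x, wx, wh, gates_seq, c_seq, h_prev_seq)
    return h, cache


def lstm_backward(dh_last, cache):
    x, wx, wh, gates_seq, c_seq, h_prev_seq = cache
    B, T, D = x.shape
    H = wh.shape[0]
    dwx = np.zeros_like(wx)
    dwh = np.zeros_like(wh)
    db = np.zeros(4 * H, dtype=x.dtype)
    dx = np.zeros_like(x)
    dh = dh_last.copy()
    dc = np.zeros((B, H), dtype=x.dtype)
    for t in range(T - 1, -1, -1):
        i = gates_seq[t][:, :H]
        f = gates_seq[t][:, H : 2 * H]
        g = gates_seq[t][:, 2 * H : 3 * H]
        o = gates_seq[t][:, 3 * H :]
        c = c_seq[t]
        c_prev = c_seq[t - 1] if t > 0 else np.zeros_like(c)
        tanh_c = np.tanh(c)
        do = dh * tanh_c
        dc = dc + dh * o * (1 - tanh_c**2)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dz = np.concatenate(
            [
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g**2),
                do * o * (1 - o),
            ],
            axis=1,
        )
        dwx += x[:, t, :].T @ dz
        dwh += h_prev_seq[t].T @ dz
        db += dz.sum(axis=0)
        dx[:, t, :] = dz @ wx.T
        dh = dz @ wh.T
        dc = dc * f
    return dx, dwx, dwh, db


# ---------------------------------------------------------------------------
# dense head, dropout, softmax loss

def dense_forward(x, w, b):
    return x @ w + b, (x, w)


def dense_backward(dout, cache):
    x, w = cache
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)


def dropout_mask(rng: np.random.Generator, shape, rate: float, dtype):
    """Inverted-dropout mask: zeros with probability ``rate``, else 1/(1-rate)."""
    if rate == 0.0:
        return np.ones(shape, dtype=dtype)
    keep = (rng.random(shape) >= rate).astype(dtype)
    return keep / dtype(1.0 - rate)


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, y_index):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(logits.dtype).tiny
    loss = -np.log(p[np.arange(n), y_index] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y_index] -= 1.0
    dlogits /= n
    return float(loss), dlogits


class AdamOptimizer:
    """Adaptive-moment gradient descent over a flat dict of parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )
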