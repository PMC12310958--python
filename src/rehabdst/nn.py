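"""Minimal recurrent-network engine (NumPy).

Implements exactly what the two decision-support models need and nothing
more: stacked LSTM layers (full-sequence or last-step output), inverted
dropout, a shared dense head applied per time-step, masked mean-squared
error for the per-step regression task, softmax cross-entropy for the
classification task, and RMSprop/Adam updates with global-norm gradient
clipping. Everything is seeded through ``numpy.random.Generator`` and runs
deterministically on a single thread.

Gate order inside a layer is (input, forget, cell, output); the forget gate
bias starts at 1 so early training does not wash out the cell state. The
input-to-hidden kernel uses Glorot-uniform init, the recurrent kernel
per-gate orthogonal init.

Padding is a suffix of each series and the loss masks it out; because the
recurrence is causal, values stored in padded rows can never influence the
loss or any valid-step prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class DivergenceError(RuntimeError):
    """Training produced a non-finite or non-decreasing loss; a lower
    learning rate is likely needed."""


def _maybe_njit(fn):
    """JIT-compile the sequential step loops when numba is available; the
    kernels are plain NumPy and run unchanged (just slower) without it."""
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional speedup
        return fn
    return njit(cache=False)(fn)


@_maybe_njit
def _lstm_forward_kernel(zx, Wh):
    """zx: (B, T, 4H) precomputed input contribution; returns h, c, gates."""
    B, T, H4 = zx.shape
    H = H4 // 4
    h_all = np.zeros((B, T, H))
    c_all = np.zeros((B, T, H))
    gates = np.zeros((B, T, H4))
    h_prev = np.zeros((B, H))
    c_prev = np.zeros((B, H))
    for t in range(T):
        z = zx[:, t] + np.dot(h_prev, Wh)
        i = 1.0 / (1.0 + np.exp(-z[:, :H]))
        f = 1.0 / (1.0 + np.exp(-z[:, H : 2 * H]))
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = 1.0 / (1.0 + np.exp(-z[:, 3 * H :]))
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        gates[:, t, :H] = i
        gates[:, t, H : 2 * H] = f
        gates[:, t, 2 * H : 3 * H] = g
        gates[:, t, 3 * H :] = o
        c_all[:, t] = c
        h_all[:, t] = h
        h_prev = h
        c_prev = c
    return h_all, c_all, gates


@_maybe_njit
def _lstm_backward_kernel(dh_out, c_all, gates, WhT):
    """Reverse-time gate-gradient recursion; returns dz over all steps."""
    B, T, H = dh_out.shape
    dz_all = np.zeros((B, T, 4 * H))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :H]
        f = gates[:, t, H : 2 * H]
        g = gates[:, t, 2 * H : 3 * H]
        o = gates[:, t, 3 * H :]
        c = c_all[:, t]
        if t > 0:
            c_prev = c_all[:, t - 1]
        else:
            c_prev = np.zeros((B, H))
        tc = np.tanh(c)
        dh = dh_out[:, t] + dh_next
        do = dh * tc * o * (1.0 - o)
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g * i * (1.0 - i)
        df = dc * c_prev * f * (1.0 - f)
        dg = dc * i * (1.0 - g * g)
        dz_all[:, t, :H] = di
        dz_all[:, t, H : 2 * H] = df
        dz_all[:, t, 2 * H : 3 * H] = dg
        dz_all[:, t, 3 * H :] = do
        dh_next = np.dot(np.ascontiguousarray(dz_all[:, t]), WhT)
        dc_next = dc * f
    return dz_all


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class LSTMLayer:
    """One LSTM layer over full sequences, with BPTT."""

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.units = units
        h = units
        self.Wx = _glorot(rng, input_dim, 4 * h)
        self.Wh = np.concatenate([_orthogonal(rng, h) for _ in range(4)], axis=1)
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget gate bias
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cache = None

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (B, T, D) -> h: (B, T, H)."""
        zx = np.ascontiguousarray(x @ self.Wx + self.b)  # (B, T, 4H)
        h_all, c_all, gates = _lstm_forward_kernel(zx, self.Wh)
        self._cache = (x, h_all, c_all, gates)
        return h_all

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        """dh_out: (B, T, H) upstream gradient -> dx: (B, T, D)."""
        x, h_all, c_all, gates = self._cache
        B, T, D = x.shape
        H = self.units
        dz_all = _lstm_backward_kernel(
            np.ascontiguousarray(dh_out), c_all, gates,
            np.ascontiguousarray(self.Wh.T),
        )
        h_prev_all = np.zeros_like(h_all)
        h_prev_all[:, 1:] = h_all[:, :-1]
        self.grads[0][...] = x.reshape(B * T, D).T @ dz_all.reshape(B * T, 4 * H)
        self.grads[1][...] = h_prev_all.reshape(B * T, H).T @ dz_all.reshape(B * T, 4 * H)
        self.grads[2][...] = dz_all.sum(axis=(0, 1))
        return dz_all @ self.Wx.T


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Dense:
    """Affine layer shared across time-steps (TimeDistributed when the
    input is 3-D)."""

    def __init__(self, input_dim: int, output_dim: int, rng: np.random.Generator):
        self.W = _glorot(rng, input_dim, output_dim)
        self.b = np.zeros(output_dim)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._x = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads[0][...] = x2.T @ dy2
        self.grads[1][...] = dy2.sum(axis=0)
        return dy @ self.W.T


class _Optimizer:
    def __init__(self, lr: float, clipnorm: float | None = 1.0):
        self.lr = lr
        self.clipnorm = clipnorm

    def _clip(self, grads: list[np.ndarray]) -> list[np.ndarray]:
        if self.clipnorm is None:
            return grads
        total = math.sqrt(sum(float(np.sum(g * g)) for g in grads))
        if total > self.clipnorm and total > 0:
            scale = self.clipnorm / total
            return [g * scale for g in grads]
        return grads

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        raise NotImplementedError


class RMSprop(_Optimizer):
    def __init__(self, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-7,
                 clipnorm: float | None = 1.0):
        super().__init__(lr, clipnorm)
        self.rho = rho
        self.eps = eps
        self._acc: list[np.ndarray] | None = None

    def step(self, params, grads):
        grads = self._clip(grads)
        if self._acc is None:
            self._acc = [np.zeros_like(p) for p in params]
        for p, g, a in zip(params, grads, self._acc):
            a *= self.rho
            a += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(a) + self.eps)


class Adam(_Optimizer):
    def __init__(self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7, clipnorm: float | None = 1.0):
        super().__init__(lr, clipnorm)
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None
        self._t = 0

    def step(self, params, grads):
        grads = self._clip(grads)
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def masked_mse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over valid steps only.

    pred: (B, T, K); target: (B, K) broadcast over time or (B, T, K);
    mask: (B, T) with 1 = valid. Returns (loss, dpred).
    """
    if target.ndim == 2:
        target = target[:, None, :]
    m = mask[..., None].astype(float)
    diff = (pred - target) * m
    denom = float(m.sum()) * pred.shape[-1]
    if denom == 0:
        return 0.0, np.zeros_like(pred)
    loss = float(np.sum(diff * diff) / denom)
    return loss, 2.0 * diff / denom


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """logits: (B, K); labels: (B,) int class ids. Returns (loss, dlogits)."""
    p = softmax(logits)
    B = logits.shape[0]
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(B), labels] + eps)))
    d = p.copy()
    d[np.arange(B), labels] -= 1.0
    return loss, d / B


class LSTMStack:
    """Stacked LSTM layers with dropout after each, plus a dense head.

    ``return_sequences=True`` applies the head per time-step (outcome
    regression); ``False`` applies it to the last step's hidden state
    (next-session classification; windows are fixed-length and unmasked).
    """

    def __init__(
        self,
        input_dim: int,
        n_layers: int,
        units: int,
        output_dim: int,
        dropout: float,
        seed: int,
        return_sequences: bool,
    ):
        rng = np.random.default_rng(seed)
        self.return_sequences = return_sequences
        self.layers: list = []
        d = input_dim
        for _ in range(n_layers):
            self.layers.append(LSTMLayer(d, units, rng))
            self.layers.append(Dropout(dropout, rng))
            d = units
        self.head = Dense(d, output_dim, rng)
        self._modules = [*self.layers, self.head]

    @property
    def params(self) -> list[np.ndarray]:
        return [p for m in self._modules for p in m.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for m in self._modules for g in m.grads]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h, training=training)
        if self.return_sequences:
            return self.head.forward(h, training=training)
        self._last_T = h.shape[1]
        return self.head.forward(h[:, -1], training=training)

    def backward(self, dout: np.ndarray) -> None:
        dh = self.head.backward(dout)
        if not self.return_sequences:
            full = np.zeros((dh.shape[0], self._last_T, dh.shape[-1]))
            full[:, -1] = dh
            dh = full
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
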