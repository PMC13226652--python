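"""Minimal NumPy neural-network engine with explicit backward passes.

Implements exactly the pieces the encoder and probing heads need: 1-D
convolution over time (channels as feature maps), ReLU, global average
pooling, linear layers, dropout, and Adam/AdamW optimizers.  All arithmetic
is float32; every layer caches what its backward pass needs and accumulates
parameter gradients into ``Param.g``.

Convolutions use "same"-style padding (output length ``ceil(L / stride)``)
and are evaluated as im2col + GEMM; the backward input pass folds the
column gradient back with per-tap strided slice adds, which keeps the whole
engine vectorised.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.ascontiguousarray(value, dtype=DTYPE)
        self.g = np.zeros_like(self.v)

    def zero_grad(self) -> None:
        self.g[...] = 0.0


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv1d:
    """1-D convolution over the last axis; input shape (B, C_in, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be positive")
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        self.W = Param(he_init(rng, (c_out, c_in * kernel), c_in * kernel))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def out_len(self, L: int) -> int:
        return -(-L // self.stride)

    def _pad(self, L: int) -> tuple[int, int]:
        L_out = self.out_len(L)
        total = max(0, (L_out - 1) * self.stride + self.k - L)
        left = total // 2
        return left, total - left

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, L = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        left, right = self._pad(L)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        # (B, C, L_valid, k) view -> strided pick -> (B, L_out, C*k)
        sw = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = np.ascontiguousarray(
            sw[:, :, ::self.stride, :].transpose(0, 2, 1, 3)
        ).reshape(B, -1, self.c_in * self.k)
        y = cols @ self.W.v.T + self.b.v
        if train:
            self._cache = (cols, L, left, xp.shape[2])
        return np.ascontiguousarray(y.transpose(0, 2, 1))  # (B, C_out, L_out)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        cols, L, left, Lp = self._cache
        B, _, L_out = dy.shape
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1))  # (B, L_out, C_out)
        flat_dy = dyt.reshape(-1, self.c_out)
        self.W.g += flat_dy.T @ cols.reshape(-1, self.c_in * self.k)
        self.b.g += flat_dy.sum(axis=0)
        self._cache = None
        if not need_dx:
            return None
        dcols = (dyt @ self.W.v).reshape(B, L_out, self.c_in, self.k)
        dcols = dcols.transpose(0, 2, 1, 3)  # (B, C_in, L_out, k)
        dxp = np.zeros((B, self.c_in, Lp), dtype=DTYPE)
        for j in range(self.k):
            dxp[:, :, j:j + self.stride * L_out:self.stride] += dcols[:, :, :, j]
        return dxp[:, :, left:left + L]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class GlobalAvgPool:
    """(B, C, L) -> (B, C)."""

    def __init__(self):
        self._L = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        L = self._L
        return np.repeat(dy[:, :, None] / L, L, axis=2).astype(DTYPE)


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(he_init(rng, (d_out, d_in), d_in))
        self.b = Param(np.zeros(d_out, dtype=DTYPE))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.v.T + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.g += dy.T @ self._x
        self.b.g += dy.sum(axis=0)
        dx = dy @ self.W.v
        self._x = None
        return dx


class Dropout:
    """Inverted dropout; identity when ``train`` is False or rng is None."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or rng is None or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        mask = (rng.random(x.shape) < keep).astype(DTYPE) / keep
        self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam with optional L2-coupled weight decay (``decoupled=False``) or
    AdamW-style decoupled decay (``decoupled=True``)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0, decoupled: bool = False):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.u = [np.zeros_like(p.v) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, u in zip(self.params, self.m, self.u):
            g = p.g
            if self.wd and not self.decoupled:
                g = g + self.wd * p.v
            m *= self.b1
            m += (1.0 - self.b1) * g
            u *= self.b2
            u += (1.0 - self.b2) * g * g
            upd = (m / bc1) / (np.sqrt(u / bc2) + self.eps)
            if self.wd and self.decoupled:
                upd = upd + self.wd * p.v
            p.v -= (lr * upd).astype(DTYPE)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def AdamW(params: list[Param], lr: float = 1e-3, weight_decay: float = 1e-4,
          **kw) -> Adam:
    return Adam(params, lr=lr, weight_decay=weight_decay, decoupled=True, **kw)
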