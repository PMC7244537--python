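"""Minimal CNN layer zoo with explicit forward/backward passes.

Everything operates on float64 NCHW batches.  Each layer caches what its
backward pass needs; gradients accumulate into ``Param.grad`` and are
cleared by the optimizer step.  This is deliberately a small, auditable
substrate sized for the two smear-analysis U-nets, not a general
framework.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .losses import LEAKY_SLOPE


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name


def truncated_normal(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    """Normal(0, sd) draws re-sampled (by clipping) to +-2 sd."""
    return np.clip(rng.standard_normal(shape), -2.0, 2.0) * sd


class Conv2d:
    """3x3 (or kxk) convolution, zero padded, stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, name: str = "conv"):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        sd = np.sqrt(2.0 / fan_in)
        self.W = Param(truncated_normal(rng, (c_out, c_in, kernel, kernel), sd),
                       f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._cols = None
        self._x_shape = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (n, c, k, k, h, w) view -> (n, c*k*k, h*w)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * self.k * self.k, h * w)
        self._cols = cols
        self._x_shape = x.shape
        wmat = self.W.value.reshape(self.c_out, -1)
        out = np.einsum("oi,nip->nop", wmat, cols, optimize=True)
        out += self.b.value[None, :, None]
        return out.reshape(n, self.c_out, h, w)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        g = gout.reshape(n, self.c_out, h * w)
        self.W.grad += np.einsum("nop,nip->oi", g, self._cols,
                                 optimize=True).reshape(self.W.value.shape)
        self.b.grad += g.sum(axis=(0, 2))
        wmat = self.W.value.reshape(self.c_out, -1)
        dcols = np.einsum("oi,nop->nip", wmat, g, optimize=True)
        dcols = dcols.reshape(n, c, self.k, self.k, h, w)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, ki, kj]
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w]


class LeakyReLU:
    def __init__(self, slope: float = LEAKY_SLOPE):
        self.slope = slope
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, gout, self.slope * gout)
        self._mask = None
        return g


class AvgPool2:
    """2x2 average pooling, stride 2."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial size must be even for 2x2 pooling")
        self._in_shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        g = np.repeat(np.repeat(gout, 2, axis=2), 2, axis=3) / 4.0
        return g


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix, half-pixel-centers mapping."""
    a = np.zeros((n_out, n_in))
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = src - i0
    a[np.arange(n_out), i0] += 1 - t
    a[np.arange(n_out), i1] += t
    return a


class BilinearUp2:
    """Bilinear x2 upsampling (half-pixel-centers / align-corners-false)."""

    params: list = []
    _cache: dict = {}

    def _mats(self, h, w):
        key = (h, w)
        if key not in BilinearUp2._cache:
            BilinearUp2._cache[key] = (_resize_matrix(h, 2 * h),
                                       _resize_matrix(w, 2 * w))
        return BilinearUp2._cache[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ar, ac = self._mats(h, w)
        self._in_hw = (h, w)
        return np.einsum("oh,nchw,pw->ncop", ar, x, ac, optimize=True)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        h, w = self._in_hw
        ar, ac = self._mats(h, w)
        return np.einsum("oh,ncop,pw->nchw", ar, gout, ac, optimize=True)


class Adam:
    """Adaptive moment estimation optimizer."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.grad[:] = 0.0

    def zero_grad(self):
        for p in self.params:
            p.grad[:] = 0.0
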