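"""Minimal 3D conv-net building blocks with explicit forward/backward passes.

A deliberately small, dependency-free neural engine: each layer caches what
its backward pass needs and exposes ``forward`` / ``backward``.  Convolutions
are implemented as 27 shifted matrix products (channels-last layout), which
keeps memory flat and lets BLAS do the work.  float32 throughout.
"""

from __future__ import annotations

import numpy as np

_OFFSETS = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Conv3d:
    """3x3x3 same-padding convolution, channels-last (D, H, W, C)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, zero_init: bool = False):
        fan_in = 27 * cin
        if zero_init:
            w = np.zeros((27, cin, cout), dtype=np.float32)
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (27, cin, cout)).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))
        self._xp: np.ndarray | None = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        d, h, w, cin = x.shape
        xp = np.pad(x, ((1, 1), (1, 1), (1, 1), (0, 0)))
        self._xp = xp
        out = np.empty((d * h * w, self.bias.value.shape[0]), dtype=np.float32)
        out[:] = self.bias.value
        for k, (dz, dy, dx) in enumerate(_OFFSETS):
            view = xp[dz:dz + d, dy:dy + h, dx:dx + w, :].reshape(-1, cin)
            out += view @ self.weight.value[k]
        return out.reshape(d, h, w, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d, h, w, cout = dout.shape
        xp = self._xp
        cin = xp.shape[-1]
        dflat = dout.reshape(-1, cout)
        self.bias.grad += dflat.sum(axis=0)
        dxp = np.zeros_like(xp)
        for k, (dz, dy, dx) in enumerate(_OFFSETS):
            view = xp[dz:dz + d, dy:dy + h, dx:dx + w, :].reshape(-1, cin)
            self.weight.grad[k] += view.T @ dflat
            dview = (dflat @ self.weight.value[k].T).reshape(d, h, w, cin)
            dxp[dz:dz + d, dy:dy + h, dx:dx + w, :] += dview
        self._xp = None
        return dxp[1:-1, 1:-1, 1:-1, :]


class LeakyReLU:
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha
        self._neg: np.ndarray | None = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        neg = x < 0
        self._neg = neg
        out = x.copy()
        out[neg] *= self.alpha
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout.copy()
        dx[self._neg] *= self.alpha
        self._neg = None
        return dx


class AvgPool2:
    """2x2x2 average pooling (requires even spatial dims)."""

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        d, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c).mean(axis=(1, 3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d, h, w, c = self._shape
        up = np.repeat(np.repeat(np.repeat(dout, 2, axis=0), 2, axis=1), 2, axis=2)
        return (up / 8.0).astype(np.float32)


class UpsampleNearest2:
    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(np.repeat(x, 2, axis=0), 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d, h, w, c = dout.shape
        return dout.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(1, 3, 5))


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
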