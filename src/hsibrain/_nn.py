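"""Minimal seeded forward/backward neural-network engine (NumPy).

Implements exactly the layer set the classifiers in this package need:
dense, 3x3 convolution (channels-last, 'same' padding), average pooling
(3x3 'valid', stride 1), 2x2 max pooling, nearest-neighbor upsampling,
ReLU/sigmoid activations, inverted dropout, softmax cross-entropy and
sigmoid binary cross-entropy losses, and SGD / AdaDelta optimizers.

All randomness (initialization, dropout, batching) flows through
``numpy.random.Generator`` instances supplied by the caller, so training
is bit-reproducible on one platform.  Arrays are float32 NHWC.
"""

from __future__ import annotations

import hashlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Conv2D(Layer):
    """3x3 'same' convolution on NHWC tensors."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.k = k
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.W = Param(rng.normal(0.0, scale, size=(k * k * c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))  # n,h,w,c,k,k
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, self.k * self.k * c)
        self._cols = np.ascontiguousarray(cols, dtype=F)
        self._xshape = x.shape
        y = self._cols @ self.W.value + self.b.value
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy):
        n, h, w, _ = self._xshape
        dy_flat = dy.reshape(n * h * w, self.c_out)
        self.W.grad += self._cols.T @ dy_flat
        self.b.grad += dy_flat.sum(axis=0)
        p = self.k // 2
        dx_pad = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in), dtype=F)
        Wk = self.W.value.reshape(self.k, self.k, self.c_in, self.c_out)
        dy4 = dy.reshape(n, h, w, self.c_out)
        for di in range(self.k):
            for dj in range(self.k):
                dx_pad[:, di : di + h, dj : dj + w, :] += dy4 @ Wk[di, dj].T
        return dx_pad[:, p : p + h, p : p + w, :]


class AvgPool3x3Valid(Layer):
    """3x3 average pooling, stride 1, 'valid' (H,W shrink by 2)."""

    def forward(self, x, train):
        self._xshape = x.shape
        win = sliding_window_view(x, (3, 3), axis=(1, 2))
        return win.mean(axis=(-2, -1), dtype=F)

    def backward(self, dy):
        n, h, w, c = self._xshape
        dx = np.zeros((n, h, w, c), dtype=F)
        g = dy / F(9.0)
        ho, wo = h - 2, w - 2
        for di in range(3):
            for dj in range(3):
                dx[:, di : di + ho, dj : dj + wo, :] += g
        return dx


class MaxPool2x2(Layer):
    def forward(self, x, train):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        self._mask = xr == y[:, :, None, :, None, :]
        self._shape = x.shape
        return y

    def backward(self, dy):
        n, h, w, c = self._shape
        g = self._mask * dy[:, :, None, :, None, :]
        return g.reshape(n, h, w, c).astype(F)


class Upsample2x(Layer):
    def forward(self, x, train):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(F)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-x.astype(F)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F) / F(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x.astype(F), train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean()
    d = p.copy()
    d[np.arange(n), targets] -= 1.0
    return float(loss), (d / n).astype(F)


def sigmoid_bce(logits: np.ndarray, targets: np.ndarray):
    """Elementwise binary cross-entropy on logits; returns (loss, dlogits)."""
    p = 1.0 / (1.0 + np.exp(-logits))
    eps = 1e-7
    loss = -(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps)).mean()
    d = (p - targets) / targets.size
    return float(loss), d.astype(F)


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------


class SGD:
    def __init__(self, params: list[Param], lr: float):
        self.params = params
        self.lr = lr

    def step(self):
        for p in self.params:
            p.value -= F(self.lr) * p.grad
            p.grad[...] = 0.0


class AdaDelta:
    """Zeiler's AdaDelta; ``lr`` scales the update (1.0 in the original)."""

    def __init__(self, params: list[Param], lr: float = 1.0, rho: float = 0.95, eps: float = 1e-6):
        self.params = params
        self.lr, self.rho, self.eps = lr, rho, eps
        self._eg = [np.zeros_like(p.value) for p in params]
        self._ex = [np.zeros_like(p.value) for p in params]

    def step(self):
        rho, eps = self.rho, self.eps
        for p, eg, ex in zip(self.params, self._eg, self._ex):
            eg *= rho
            eg += (1 - rho) * p.grad**2
            update = -np.sqrt((ex + eps) / (eg + eps)) * p.grad
            ex *= rho
            ex += (1 - rho) * update**2
            p.value += F(self.lr) * update
            p.grad[...] = 0.0


def weights_hash(params: list[Param]) -> str:
    """Stable digest of all parameter values (reproducibility checks)."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()
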