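"""Minimal CNN building blocks with hand-written backpropagation.

Just enough machinery for the dual-view localizer: 3x3 convolutions
via im2col, ReLU, 2x2 max pooling, block average pooling, dense layers,
and Adam.  Layers cache what their backward pass needs; parameters and
gradients live on the layer objects.  Everything is float32 and fully
deterministic given the init generator.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class AvgPool(Layer):
    """Non-overlapping block mean; H and W must be divisible by k."""

    def __init__(self, k: int):
        self.k = k
        self.params, self.grads = [], []

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        k = self.k
        self._in_shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._in_shape
        k = self.k
        g = np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)
        return g.astype(np.float32)


class Conv3x3(Layer):
    """3x3 same-padding convolution via im2col."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        fan_in = cin * 9
        self.w = (rng.standard_normal((cout, cin, 3, 3)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.params = [self.w, self.b]
        self.grads = [self.gw, self.gb]

    @staticmethod
    def _im2col(xp: np.ndarray, h: int, w: int) -> np.ndarray:
        n, c = xp.shape[:2]
        cols = np.empty((n, c, 9, h, w), dtype=np.float32)
        idx = 0
        for di in range(3):
            for dj in range(3):
                cols[:, :, idx] = xp[:, :, di : di + h, dj : dj + w]
                idx += 1
        return cols

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = self._im2col(xp, h, w).reshape(n, c * 9, h * w)
        if train:
            self._cols = cols
            self._in_shape = x.shape
        wmat = self.w.reshape(self.w.shape[0], -1)
        y = np.einsum("oc,ncp->nop", wmat, cols, optimize=True)
        return y.reshape(n, -1, h, w) + self.b[None, :, None, None]

    def backward(self, grad):
        n, c, h, w = self._in_shape
        cout = self.w.shape[0]
        g = grad.reshape(n, cout, h * w)
        self.gb[...] = g.sum(axis=(0, 2))
        self.gw[...] = np.einsum("nop,ncp->oc", g, self._cols, optimize=True).reshape(
            self.w.shape
        )
        wmat = self.w.reshape(cout, -1)
        gcols = np.einsum("oc,nop->ncp", wmat, g, optimize=True).reshape(n, c, 9, h, w)
        gx = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        idx = 0
        for di in range(3):
            for dj in range(3):
                gx[:, :, di : di + h, dj : dj + w] += gcols[:, :, idx]
                idx += 1
        self._cols = None
        return gx[:, :, 1:-1, 1:-1]


class ReLU(Layer):
    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            self._mask = xr == y[:, :, :, None, :, None]
            self._in_shape = x.shape
        return y

    def backward(self, grad):
        n, c, h, w = self._in_shape
        g = self._mask * grad[:, :, :, None, :, None]
        return g.reshape(n, c, h, w).astype(np.float32)


class Flatten(Layer):
    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((nin, nout)) * np.sqrt(2.0 / nin)).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.params = [self.w, self.b]
        self.grads = [self.gw, self.gb]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        gx = grad @ self.w.T
        self._x = None
        return gx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)
        self.params = [p for l in self.layers for p in l.params]
        self.grads = [g for l in self.layers for g in l.grads]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
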