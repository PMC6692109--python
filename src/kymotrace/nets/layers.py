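"""Minimal CNN layer library (numpy, explicit backprop).

Implements exactly the building blocks the tracing networks need: padded
3x3 (and 1x1) convolutions, batch normalisation, the leaky ramp
activation leakyReLU(x) = max(x, 0) - 0.1 max(-x, 0), 2x2 max pooling,
nearest-neighbour upsampling, dropout, and the Adam optimiser.  All
tensors are (N, C, H, W) float32 arrays.  Every layer caches what its
backward pass needs; ``backward`` must be called with the same
batch that was last pushed through ``forward``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2D", "BatchNorm2D", "LeakyReLU", "MaxPool2", "Upsample2",
    "Dropout", "Dense", "Sequential", "Adam", "leaky_relu", "cross_entropy",
    "EPS",
]

EPS = 1e-7
LEAK = 0.1
DTYPE = np.float32


def leaky_relu(x):
    """leakyReLU(x) = max(x, 0) - 0.1 * max(-x, 0)."""
    x = np.asarray(x, float)
    out = np.maximum(x, 0.0) - LEAK * np.maximum(-x, 0.0)
    return out if out.ndim else float(out)


def cross_entropy(t, o):
    """Per-entry cross entropy -(t ln o + (1-t) ln(1-o)), averaged over all
    entries; ``o`` is clipped away from {0, 1} before the logs."""
    t = np.asarray(t, float)
    o = np.clip(np.asarray(o, float), EPS, 1.0 - EPS)
    ce = -(t * np.log(o) + (1.0 - t) * np.log(1.0 - o))
    return float(np.mean(ce))


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded convolution with kernel size 1 or 3 (im2col + matmul)."""

    def __init__(self, cin: int, cout: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        assert k in (1, 3)
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialisation
        self.W = rng.normal(0.0, scale, (cout, cin, k, k)).astype(DTYPE)
        self.b = np.zeros(cout, DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k

    def params(self): return [self.W, self.b]

    def grads(self): return [self.dW, self.db]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, DTYPE)
        N, C, H, Wd = x.shape
        O = self.W.shape[0]
        if self.k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(-1, C)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            win = np.lib.stride_tricks.sliding_window_view(
                xp, (3, 3), axis=(2, 3))            # (N,C,H,W,3,3)
            cols = np.ascontiguousarray(
                win.transpose(0, 2, 3, 1, 4, 5)).reshape(-1, C * 9)
        self._cols, self._shape = cols, (N, C, H, Wd)
        wmat = self.W.reshape(O, -1)
        y = cols @ wmat.T + self.b
        return y.reshape(N, H, Wd, O).transpose(0, 3, 1, 2)

    def backward(self, dy):
        N, C, H, Wd = self._shape
        O = self.W.shape[0]
        dy_mat = np.ascontiguousarray(
            dy.transpose(0, 2, 3, 1), DTYPE).reshape(-1, O)
        self.dW[...] = (dy_mat.T @ self._cols).reshape(self.W.shape)
        self.db[...] = dy_mat.sum(axis=0)
        dcols = dy_mat @ self.W.reshape(O, -1)
        if self.k == 1:
            return dcols.reshape(N, H, Wd, C).transpose(0, 3, 1, 2)
        # one contiguous permute, then nine contiguous-source adds
        dcols = np.ascontiguousarray(
            dcols.reshape(N, H, Wd, C, 3, 3).transpose(4, 5, 0, 3, 1, 2))
        dxp = np.zeros((N, C, H + 2, Wd + 2), DTYPE)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i:i + H, j:j + Wd] += dcols[i, j]
        return dxp[:, :, 1:-1, 1:-1]


class BatchNorm2D(Layer):
    """Per-channel normalisation to zero mean / unit variance over the
    batch and spatial axes, with learned rescaling, applied before the
    activation.  Running statistics are used at inference."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, DTYPE)
        self.beta = np.zeros(c, DTYPE)
        self.dgamma = np.zeros(c, DTYPE)
        self.dbeta = np.zeros(c, DTYPE)
        self.running_mean = np.zeros(c, DTYPE)
        self.running_var = np.ones(c, DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self): return [self.gamma, self.beta]

    def grads(self): return [self.dgamma, self.dbeta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._train = xhat, inv, train
        return (self.gamma[None, :, None, None] * xhat
                + self.beta[None, :, None, None])

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        if not self._train:
            return dy * g * inv[None, :, None, None]
        N = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx * inv[None, :, None, None]


class LeakyReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x >= 0
        return np.where(self._mask, x, LEAK * x)

    def backward(self, dy):
        return np.where(self._mask, dy, LEAK * dy)


class MaxPool2(Layer):
    """2x2 max pooling; spatial dims must be even."""

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        N, C, H, W = self._shape
        dxr = np.zeros((N, C, H // 2, W // 2, 4), DTYPE)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5)
        return dxr.reshape(N, C, H, W)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        N, C, H, W = dy.shape
        return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p)
                      .astype(DTYPE) / DTYPE(1.0 - self.p))
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    def __init__(self, nin: int, nout: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin), (nin, nout)).astype(DTYPE)
        self.b = np.zeros(nout, DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self): return [self.W, self.b]

    def grads(self): return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adaptive-moment stochastic gradient descent."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads_ = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, lr_scale: float = 1.0):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        lr = self.lr * lr_scale
        for p, g, m, v in zip(self.params, self.grads_, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
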