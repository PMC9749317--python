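"""Layer implementations with explicit forward/backward passes.

Conventions: 1-D activations are (N, L, C); 2-D activations are
(N, H, W, C).  Convolutions and pools use valid (no) padding.  Each layer
exposes ``params`` / ``grads`` (parallel lists of arrays) so an optimizer
can update weights in place.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x, train: bool = False):
        raise NotImplementedError

    def backward(self, g):
        raise NotImplementedError


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class Conv1D(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        self.k, self.stride = kernel, stride
        self.W = he_normal(rng, (kernel, in_ch, out_ch), kernel * in_ch)
        self.b = np.zeros(out_ch)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        if x.shape[1] < self.k:
            raise ValueError(f"input length {x.shape[1]} < kernel {self.k}")
        # (N, Lout, C, k)
        win = sliding_window_view(x, self.k, axis=1)[:, ::self.stride]
        self._win, self._in_shape = win, x.shape
        return np.einsum("nlck,kco->nlo", win, self.W, optimize=True) + self.b

    def backward(self, g):
        self.grads[0][...] = np.einsum("nlck,nlo->kco", self._win, g, optimize=True)
        self.grads[1][...] = g.sum(axis=(0, 1))
        dx = np.zeros(self._in_shape)
        L_out = g.shape[1]
        for j in range(self.k):
            contrib = np.einsum("nlo,co->nlc", g, self.W[j], optimize=True)
            dx[:, j:j + self.stride * L_out:self.stride] += contrib
        return dx


class Conv2D(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.k, self.stride = kernel, stride
        self.W = he_normal(rng, (kernel, kernel, in_ch, out_ch), kernel * kernel * in_ch)
        self.b = np.zeros(out_ch)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        s = self.stride
        win = sliding_window_view(x, (self.k, self.k), axis=(1, 2))[:, ::s, ::s]
        self._win, self._in_shape = win, x.shape  # (N, Ho, Wo, C, k, k)
        return np.einsum("nhwcij,ijco->nhwo", win, self.W, optimize=True) + self.b

    def backward(self, g):
        self.grads[0][...] = np.einsum("nhwcij,nhwo->ijco", self._win, g, optimize=True)
        self.grads[1][...] = g.sum(axis=(0, 1, 2))
        dx = np.zeros(self._in_shape)
        s = self.stride
        Ho, Wo = g.shape[1], g.shape[2]
        for i in range(self.k):
            for j in range(self.k):
                contrib = np.einsum("nhwo,co->nhwc", g, self.W[i, j], optimize=True)
                dx[:, i:i + s * Ho:s, j:j + s * Wo:s] += contrib
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        self._axes = axes
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        axes, m = self._axes, self._m
        self.grads[0][...] = (g * self._xhat).sum(axis=axes)
        self.grads[1][...] = g.sum(axis=axes)
        dxhat = g * self.gamma
        # standard batchnorm backward (training statistics)
        dx = (self._inv_std / m) * (
            m * dxhat
            - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool1D(Layer):
    def __init__(self, size: int, stride: int):
        self.size, self.stride = size, stride

    def forward(self, x, train=False):
        if x.shape[1] < self.size:
            raise ValueError(f"input length {x.shape[1]} < pool size {self.size}")
        win = sliding_window_view(x, self.size, axis=1)[:, ::self.stride]
        self._argmax = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, g):
        dx = np.zeros(self._in_shape)
        L_out = g.shape[1]
        for p in range(self.size):
            mask = self._argmax == p
            dx[:, p:p + self.stride * L_out:self.stride] += g * mask
        return dx


class MaxPool2D(Layer):
    def __init__(self, size: int, stride: int | None = None):
        self.size = size
        self.stride = stride or size

    def forward(self, x, train=False):
        s = self.stride
        win = sliding_window_view(x, (self.size, self.size), axis=(1, 2))[:, ::s, ::s]
        flat = win.reshape(win.shape[:4] + (self.size * self.size,))
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, g):
        dx = np.zeros(self._in_shape)
        s = self.stride
        Ho, Wo = g.shape[1], g.shape[2]
        for p in range(self.size * self.size):
            i, j = divmod(p, self.size)
            mask = self._argmax == p
            dx[:, i:i + s * Ho:s, j:j + s * Wo:s] += g * mask
        return dx


class AvgPool2D(Layer):
    """Non-overlapping average pooling (stride = size); trims remainders."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train=False):
        k = self.size
        N, H, W, C = x.shape
        Ho, Wo = H // k, W // k
        self._in_shape, self._trim = x.shape, (Ho * k, Wo * k)
        v = x[:, :Ho * k, :Wo * k].reshape(N, Ho, k, Wo, k, C)
        return v.mean(axis=(2, 4))

    def backward(self, g):
        k = self.size
        dx = np.zeros(self._in_shape)
        Ht, Wt = self._trim
        spread = np.repeat(np.repeat(g, k, axis=1), k, axis=2) / (k * k)
        dx[:, :Ht, :Wt] = spread
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, g):
        N, L, C = self._shape
        return np.broadcast_to(g[:, None, :], self._shape) / L


class GlobalAvgPool2D(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        N, H, W, C = self._shape
        return np.broadcast_to(g[:, None, None, :], self._shape) / (H * W)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = he_normal(rng, (in_dim, out_dim), in_dim)
        self.b = np.zeros(out_dim)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class ResidualConv1D(Layer):
    """Strided conv-BN path plus a 1x1 strided linear projection skip.

    The projection output is cropped to the conv path's (shorter, valid-
    padding) length before the sum; ReLU is applied after the addition.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.conv = Conv1D(in_ch, out_ch, kernel, stride, rng)
        self.bn = BatchNorm(out_ch)
        self.proj = Conv1D(in_ch, out_ch, 1, stride, rng)
        self.relu = ReLU()
        self.params = self.conv.params + self.bn.params + self.proj.params
        self.grads = self.conv.grads + self.bn.grads + self.proj.grads

    def forward(self, x, train=False):
        main = self.bn.forward(self.conv.forward(x, train), train)
        skip = self.proj.forward(x, train)
        self._skip_len = skip.shape[1]
        self._main_len = main.shape[1]
        return self.relu.forward(main + skip[:, :main.shape[1]], train)

    def backward(self, g):
        g = self.relu.backward(g)
        g_skip = np.zeros(g.shape[:1] + (self._skip_len,) + g.shape[2:])
        g_skip[:, :self._main_len] = g
        dx = self.conv.backward(self.bn.backward(g))
        dx += self.proj.backward(g_skip)
        return dx
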