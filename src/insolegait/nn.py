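"""A compact numpy neural-network engine for 1-D convolutional classifiers.

Implements exactly the layer vocabulary the gait classifier needs: valid
(unpadded) 1-D convolution over the time axis, ReLU, batch normalization,
dense layers, inverted dropout, and softmax cross-entropy, trained with
Adam.  Forward/backward passes are vectorized with im2col-style windowing;
everything is deterministic given the seeds supplied by the caller.

Shapes: convolutional activations are ``(N, T, C)`` (batch, time, channels);
dense activations are ``(N, D)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1d",
    "BatchNorm",
    "Dense",
    "ReLU",
    "Dropout",
    "Flatten",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
    "xavier_uniform",
]


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization: U(-a, a), a = sqrt(6/(fi+fo))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of row-stochastic ``probs``."""
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))


class Layer:
    trainable = True

    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Valid 1-D convolution over time: (N, T, C_in) -> (N, T', C_out).

    ``T' = (T - kernel) // stride + 1``; the first layer of the gait network
    uses kernel height 20 with the filter spanning the full sensor width,
    which in this layout is simply ``C_in`` = W input channels.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int, stride: int, rng):
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel
        fan_out = out_channels * kernel
        self.W = xavier_uniform(rng, (kernel * in_channels, out_channels), fan_in, fan_out)
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train: bool):
        N, T, C = x.shape
        if T < self.kernel:
            raise ValueError(f"input length {T} shorter than filter height {self.kernel}")
        # (N, T', kernel, C): window j covers frames j*s .. j*s+kernel-1
        windows = sliding_window_view(x, self.kernel, axis=1)[:, :: self.stride]
        windows = np.ascontiguousarray(np.swapaxes(windows, 2, 3))
        self._cols = windows.reshape(N, windows.shape[1], -1)
        self._in_shape = x.shape
        return self._cols @ self.W + self.b

    def backward(self, dy):
        N, To, F = dy.shape
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        self.dW[...] = cols2.T @ dy.reshape(-1, F)
        self.db[...] = dy.sum(axis=(0, 1))
        dcols = (dy @ self.W.T).reshape(N, To, self.kernel, -1)
        dx = np.zeros(self._in_shape)
        idx = self.stride * np.arange(To)
        for j in range(self.kernel):
            dx[:, idx + j, :] += dcols[:, :, j, :]
        return dx


class ReLU(Layer):
    trainable = False

    def forward(self, x, train: bool):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics.

    For (N, T, C) inputs the statistics pool over batch and time; for
    (N, D) inputs over the batch.  At evaluation time the exponential
    running moments are used.
    """

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.dgamma = np.zeros(n_channels)
        self.dbeta = np.zeros(n_channels)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train: bool):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._n = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        axes, n = self._axes, self._n
        self.dgamma[...] = (dy * self._xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        return (
            dxhat
            - dxhat.mean(axis=axes)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng):
        self.W = xavier_uniform(rng, (in_features, out_features), in_features, out_features)
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train: bool):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    trainable = False

    def __init__(self, rate: float, rng):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    trainable = False

    def forward(self, x, train: bool):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list):
        self.layers = list(layers)
        self.frozen = False

    def params(self):
        if self.frozen:
            return []
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        if self.frozen:
            return []
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x, train: bool):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam optimizer over a flat parameter/gradient list (in-place updates)."""

    def __init__(self, params: list, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
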