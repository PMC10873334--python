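"""Minimal 1D convolutional network engine on NumPy.

Implements exactly the layer vocabulary the imputation model needs —
1D convolution (stride 1, zero 'same' padding), ReLU, max-pooling (window
2, stride 2), batch normalisation, inverted dropout, dense — together with
reverse-mode gradients, the Adam optimiser, and a masked mean-squared-error
loss in which target slots equal to a sentinel (−1) contribute neither to
the loss nor to the gradient.

Weights default to float32; a dtype argument exists so finite-difference
gradient checks can run in float64.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

try:  # fused single-pass Adam kernel; pure-NumPy fallback below
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _adam_kernel(p, g, m, v, lr, b1, b2, eps, b1t, b2t):  # pragma: no cover
        for i in range(p.size):
            gi = g[i]
            m[i] = b1 * m[i] + (1.0 - b1) * gi
            v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
            p[i] -= lr * (m[i] / b1t) / (np.sqrt(v[i] / b2t) + eps)

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

SENTINEL = -1.0


class Layer:
    """Base layer: forward/backward plus optional (param, grad) pairs."""

    def forward(self, x, training, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def params(self):
        return []


class Conv1D(Layer):
    """Cross-correlation with kernel 3 (any odd size), stride 1, same padding.

    Input (B, C, L) -> output (B, F, L).
    """

    def __init__(self, in_channels, filters, kernel_size, rng, dtype=np.float32):
        fan_in = in_channels * kernel_size
        self.W = (rng.standard_normal((filters, in_channels, kernel_size))
                  * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.k = kernel_size
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training, rng):
        B, C, L = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.k, axis=2)  # (B, C, L, k)
        cols = win.transpose(0, 2, 1, 3).reshape(B, L, C * self.k)
        self._cols, self._shape = cols, (B, C, L)
        Wm = self.W.reshape(self.W.shape[0], -1).T  # (C*k, F)
        y = cols @ Wm + self.b
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, grad):
        B, C, L = self._shape
        F = self.W.shape[0]
        g = grad.transpose(0, 2, 1).reshape(B * L, F)  # (B*L, F)
        cols = self._cols.reshape(B * L, C * self.k)
        self.dW[...] = (cols.T @ g).T.reshape(self.W.shape)
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W.reshape(F, -1)).reshape(B, L, C, self.k)
        p = self.k // 2
        dxp = np.zeros((B, C, L + 2 * p), dtype=grad.dtype)
        for j in range(self.k):
            dxp[:, :, j:j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, p:p + L]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Window 2, stride 2; input length must be even."""

    def forward(self, x, training, rng):
        B, C, L = x.shape
        a, b = x[:, :, 0::2], x[:, :, 1::2]
        self._right = b > a  # ties go left, matching argmax
        self._shape = x.shape
        return np.where(self._right, b, a)

    def backward(self, grad):
        B, C, L = self._shape
        out = np.zeros((B, C, L), dtype=grad.dtype)
        right = self._right
        out[:, :, 0::2] = np.where(right, 0, grad)
        out[:, :, 1::2] = np.where(right, grad, 0)
        return out


class BatchNorm1D(Layer):
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, channels, momentum=0.9, eps=1e-5, dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(channels, dtype=np.float64)
        self.run_var = np.ones(channels, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training, rng):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean = self.run_mean.astype(x.dtype)
            var = self.run_var.astype(x.dtype)
        std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / std[None, :, None]
        self._std = std
        self._training = training
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad):
        xhat, std = self._xhat, self._std
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 2))
        self.dbeta[...] = grad.sum(axis=(0, 2))
        g = grad * self.gamma[None, :, None]
        if not self._training:
            return g / std[None, :, None]
        n = grad.shape[0] * grad.shape[2]
        return (g - g.mean(axis=(0, 2), keepdims=True)
                - xhat * (g * xhat).sum(axis=(0, 2), keepdims=True) / n
                ) / std[None, :, None]

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class Dropout(Layer):
    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, scale=2.0, dtype=np.float32):
        self.W = (rng.standard_normal((n_in, n_out))
                  * np.sqrt(scale / n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        np.matmul(self._x.T, grad, out=self.dW)
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Network:
    """A plain feed-forward stack of layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.params(), weights):
            p[...] = w


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self._buf = [np.empty_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        if _HAVE_NUMBA:
            for (p, g), m, v in zip(self.params, self.m, self.v):
                _adam_kernel(p.ravel(), g.ravel(), m.ravel(), v.ravel(),
                             self.lr, self.b1, self.b2, self.eps, b1t, b2t)
            return
        for (p, g), m, v, buf in zip(self.params, self.m, self.v, self._buf):
            # in-place update; buf avoids temporaries on large layers
            m *= self.b1
            np.multiply(g, 1 - self.b1, out=buf)
            m += buf
            v *= self.b2
            np.multiply(g, g, out=buf)
            buf *= 1 - self.b2
            v += buf
            np.sqrt(v, out=buf)
            buf /= np.sqrt(b2t)
            buf += self.eps
            buf *= b1t / self.lr
            np.divide(m, buf, out=buf)
            p -= buf


def masked_mse_loss(
    pred: np.ndarray, truth: np.ndarray, sentinel: float = SENTINEL
) -> tuple[float, np.ndarray]:
    """MSE over slots where ``truth != sentinel``; returns (loss, dloss/dpred).

    Slots carrying the sentinel are excluded from both the mean and the
    gradient, so padded or masked targets cannot influence training.
    """
    mask = truth != sentinel
    count = int(mask.sum())
    if count == 0:
        warnings.warn("all target slots masked; loss is 0")
        return 0.0, np.zeros_like(pred)
    diff = np.where(mask, pred - truth, 0.0)
    loss = float((diff ** 2).sum() / count)
    return loss, (2.0 / count) * diff.astype(pred.dtype)
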