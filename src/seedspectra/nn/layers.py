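"""Differentiable 1-D layers with explicit numpy forward/backward passes.

Convolution activations use the layout (batch, channels, length); dense
activations are (batch, features).  Convolutions are evaluated as a single
BLAS matmul over an im2col view, which is where essentially all training
time goes.  Every layer exposes ``params()`` -> list of (value, grad) array
pairs updated in place by the optimizer, and ``state_arrays()`` -> every
array that must be snapshotted to checkpoint the layer (parameters plus
batch-norm running statistics).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def softmax(z: np.ndarray) -> np.ndarray:
    """Shift-stable softmax along the last axis:
    sigma(z)_i = exp(z_i) / sum_k exp(z_k)."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    def params(self):
        return []

    def state_arrays(self):
        return [p for p, _ in self.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int]:
    out = -(-length // stride)  # ceil
    total = max((out - 1) * stride + kernel - length, 0)
    return total // 2, total - total // 2


class Conv1d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: str = "same", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding = kernel, stride, padding
        scale = np.sqrt(2.0 / (c_in * kernel))  # He initialization
        self.W = (rng.normal(0.0, scale, size=(c_out, c_in, kernel))
                  .astype(DTYPE))
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def out_length(self, length: int) -> int:
        if self.padding == "same":
            return -(-length // self.stride)
        return (length - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, length = x.shape
        pl, pr = (_same_pad(length, self.kernel, self.stride)
                  if self.padding == "same" else (0, 0))
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
        windows = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        lo = windows.shape[2]
        col = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(
            n * lo, c * self.kernel)
        out = col @ self.W.reshape(self.c_out, -1).T + self.b
        if train:
            self._col = col
            self._shape = (n, c, length, pl, pr, lo)
        return np.ascontiguousarray(out.reshape(n, lo, self.c_out).transpose(0, 2, 1))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, length, pl, pr, lo = self._shape
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(n * lo, self.c_out)
        self.dW[...] = (dflat.T @ self._col).reshape(self.W.shape)
        self.db[...] = dflat.sum(axis=0)
        dcol = (dflat @ self.W.reshape(self.c_out, -1)).reshape(
            n, lo, c, self.kernel).transpose(0, 2, 1, 3)
        dxp = np.zeros((n, c, length + pl + pr), dtype=DTYPE)
        s = self.stride
        for j in range(self.kernel):
            dxp[:, :, j:j + s * lo:s] += dcol[:, :, :, j]
        self._col = None
        return dxp[:, :, pl:pl + length]


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling; a trailing remainder shorter than the
    window is dropped."""

    def __init__(self, pool: int = 2, stride: int | None = None):
        self.pool = pool
        self.stride = stride or pool
        if self.stride != self.pool:
            raise ValueError("only non-overlapping pooling is supported")

    def out_length(self, length: int) -> int:
        return length // self.pool

    def forward(self, x, train=False):
        n, c, length = x.shape
        lo = length // self.pool
        view = x[:, :, :lo * self.pool].reshape(n, c, lo, self.pool)
        if train:
            self._argmax = view.argmax(axis=3)
            self._shape = (n, c, length, lo)
        return view.max(axis=3)

    def backward(self, dout):
        n, c, length, lo = self._shape
        dview = np.zeros((n, c, lo, self.pool), dtype=DTYPE)
        np.put_along_axis(dview, self._argmax[..., None], dout[..., None], axis=3)
        dx = np.zeros((n, c, length), dtype=DTYPE)
        dx[:, :, :lo * self.pool] = dview.reshape(n, c, lo * self.pool)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, scale, size=(d_in, d_out)).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length) for conv
    activations."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def state_arrays(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mean)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None]) * inv[None, :, None]
            self._cache = (xhat, inv, x.shape[0] * x.shape[2])
            return (self.gamma[None, :, None] * xhat
                    + self.beta[None, :, None]).astype(DTYPE)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None]) * inv[None, :, None]
        return (self.gamma[None, :, None] * xhat + self.beta[None, :, None]
                ).astype(DTYPE)

    def backward(self, dout):
        xhat, inv, m = self._cache
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 2))
        self.dbeta[...] = dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        dx = (inv[None, :, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True))
        self._cache = None
        return dx.astype(DTYPE)


class GlobalAvgPool1d(Layer):
    def forward(self, x, train=False):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return (np.repeat(dout[:, :, None], self._length, axis=2)
                / self._length).astype(DTYPE)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def state_arrays(self):
        return [a for layer in self.layers for a in layer.state_arrays()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class ResidualBlock(Layer):
    """Two k-size convolutions with equal channel counts, a shortcut
    (identity, or a strided 1x1 projection when shape changes), and a final
    ReLU on the sum."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 batchnorm: bool = True, rng: np.random.Generator | None = None):
        main: list[Layer] = [Conv1d(c_in, c_out, kernel, stride=stride, rng=rng)]
        if batchnorm:
            main.append(BatchNorm1d(c_out))
        main.append(ReLU())
        main.append(Conv1d(c_out, c_out, kernel, stride=1, rng=rng))
        if batchnorm:
            main.append(BatchNorm1d(c_out))
        self.main = Sequential(main)
        if c_in != c_out or stride != 1:
            short: list[Layer] = [Conv1d(c_in, c_out, 1, stride=stride, rng=rng)]
            if batchnorm:
                short.append(BatchNorm1d(c_out))
            self.shortcut: Layer | None = Sequential(short)
        else:
            self.shortcut = None
        self.relu = ReLU()
        self.c_out = c_out
        self.stride = stride

    def params(self):
        out = self.main.params()
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out

    def state_arrays(self):
        out = self.main.state_arrays()
        if self.shortcut is not None:
            out += self.shortcut.state_arrays()
        return out

    def forward(self, x, train=False):
        main = self.main.forward(x, train=train)
        short = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        return self.relu.forward(main + short, train=train)

    def backward(self, dout):
        dsum = self.relu.backward(dout)
        dx = self.main.backward(dsum)
        if self.shortcut is None:
            dx = dx + dsum
        else:
            dx = dx + self.shortcut.backward(dsum)
        return dx


class SoftmaxCrossEntropy:
    """Mean softmax cross-entropy over a batch of logits."""

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> float:
        self._probs = softmax(logits.astype(np.float64))
        self._labels = labels
        eps = 1e-12
        return float(-np.mean(np.log(self._probs[np.arange(labels.size), labels] + eps)))

    def backward(self) -> np.ndarray:
        n = self._labels.size
        grad = self._probs.copy()
        grad[np.arange(n), self._labels] -= 1.0
        return (grad / n).astype(DTYPE)


class SGD:
    """Stochastic gradient descent with classical momentum:
    v <- momentum * v + grad;  w <- w - lr * v."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9):
        if lr < 0:
            raise ValueError("learning rate must be nonnegative")
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.velocity = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        for (value, grad), v in zip(self.params, self.velocity):
            v *= self.momentum
            v += grad
            value -= (self.lr * v).astype(value.dtype)
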