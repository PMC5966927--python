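"""Minimal CPU layer set: forward/backward passes on float32 numpy arrays.

Image tensors are channels-last ``(N, H, W, C)``; dense activations are
``(N, D)``.  Convolutions use im2col + one matmul, which is the fastest
pure-numpy route at the channel widths used here (<= 16).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "sigmoid":
        # stable logistic
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    return z


def _activate_grad(out: np.ndarray, kind: str) -> np.ndarray:
    """d activation / d pre-activation, expressed through the output."""
    if kind == "relu":
        return (out > 0).astype(out.dtype)
    if kind == "sigmoid":
        return out * (1.0 - out)
    return np.ones_like(out)


class Layer:
    trainable = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """3x3 same-padded convolution, stride 1, fused activation."""

    trainable = True

    def __init__(self, c_in: int, c_out: int, activation: str, rng: np.random.Generator,
                 kernel: int = 3):
        self.k = kernel
        self.activation = activation
        fan_in = kernel * kernel * c_in
        limit = np.sqrt(6.0 / (fan_in + c_out))
        self.W = rng.uniform(-limit, limit, (fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, k, k, C) -> (N*H*W, k*k*C)
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # win shape: (N, H, W, C, k, k) -> reorder so flattening matches W layout
        col = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, -1)
        z = col @ self.W + self.b
        out = _activate(z, self.activation).reshape(n, h, w, -1)
        if train:
            self._cache = (col, (n, h, w, c), out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        col, (n, h, w, c), out = self._cache
        dz = (dout * _activate_grad(out, self.activation)).reshape(n * h * w, -1)
        self.dW[...] = col.T @ dz
        self.db[...] = dz.sum(axis=0)
        dcol = dz @ self.W.T  # (N*H*W, k*k*C)
        dcol = dcol.reshape(n, h, w, self.k, self.k, c)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dout.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + h, j:j + w, :] += dcol[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class MaxPool2D(Layer):
    """2x2 max pool; ties route the gradient to the first maximum."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        flat = win.reshape(n, h // 2, w // 2, 4, c)
        idx = flat.argmax(axis=3)
        out = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        dflat = np.zeros((n, h // 2, w // 2, 4, c), dtype=dout.dtype)
        np.put_along_axis(dflat, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        return dflat.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, c)


class Upsample2D(Layer):
    """2x2 nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Dense(Layer):
    trainable = True

    def __init__(self, d_in: int, d_out: int, activation: str, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = rng.uniform(-limit, limit, (d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.activation = activation

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = _activate(x @ self.W + self.b, self.activation)
        if train:
            self._x, self._out = x, out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * _activate_grad(self._out, self.activation)
        self.dW[...] = self._x.T @ dz
        self.db[...] = dz.sum(axis=0)
        return dz @ self.W.T

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class BatchNorm(Layer):
    """1-D batch normalisation with running statistics for evaluation."""

    trainable = True

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(dim, dtype=np.float32)
        self.beta = np.zeros(dim, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(dim, dtype=np.float32)
        self.running_var = np.ones(dim, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mu) / self._std
            return self.gamma * self._xhat + self.beta
        return self.gamma * (x - self.running_mean) / np.sqrt(self.running_var + self.eps) + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        xhat, std = self._xhat, self._std
        self.dgamma[...] = (dout * xhat).sum(axis=0)
        self.dbeta[...] = dout.sum(axis=0)
        dxhat = dout * self.gamma
        return (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std

    @property
    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dgamma, self.dbeta]


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return dout
        return dout * self._mask.astype(dout.dtype)
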