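"""Minimal NumPy layers with manual backprop for the seizure classifier.

Tensors flow as float32 arrays of shape (batch, rows, time, features), where
``rows`` are EEG channels.  Convolutions are 1 x k (time only, shared across
rows) with TensorFlow-style "same" padding, so the temporal length after a
stride-s convolution is ceil(T / s) regardless of k.  Max pooling is "valid"
with stride equal to the pool size (remainder samples dropped).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D", "BatchNorm", "ReLU", "MaxPool1D", "GlobalAvgPool", "Dense",
    "RMSProp", "softmax", "same_out_len", "pool_out_len",
]


def same_out_len(t: int, stride: int) -> int:
    return -(-t // stride)  # ceil


def pool_out_len(t: int, pool: int) -> int:
    return t // pool


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base: subclasses fill ``params``/``grads`` dicts keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1 x k convolution along time with stride and "same" padding."""

    def __init__(self, k: int, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k, self.c_in, self.c_out, self.stride = k, c_in, c_out, stride
        limit = np.sqrt(6.0 / (k * c_in + k * c_out))  # Glorot uniform
        self.params["W"] = rng.uniform(-limit, limit, (k, c_in, c_out)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def _pad(self, t: int) -> tuple[int, int, int]:
        out = same_out_len(t, self.stride)
        total = max((out - 1) * self.stride + self.k - t, 0)
        return out, total // 2, total - total // 2

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        m, r, t, c = x.shape
        out, pl, pr = self._pad(t)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = cols[:, :, ::self.stride]          # (M, R, out, C_in, k)
        y = np.tensordot(cols, self.params["W"], axes=([4, 3], [0, 1]))
        y += self.params["b"]
        if train:
            self._cols, self._tshape = cols, (t, pl, pr)
        return y.astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols = self._cols
        t, pl, pr = self._tshape
        gW = np.tensordot(cols, gy, axes=([0, 1, 2], [0, 1, 2]))  # (C_in, k, C_out)
        self.grads["W"] = gW.transpose(1, 0, 2).astype(np.float32)
        self.grads["b"] = gy.sum(axis=(0, 1, 2)).astype(np.float32)
        gcols = np.tensordot(gy, self.params["W"], axes=([3], [2]))  # (M,R,out,k,C_in)
        m, r, out = gy.shape[:3]
        gxp = np.zeros((m, r, t + pl + pr, self.c_in), dtype=np.float32)
        pos = np.arange(out) * self.stride
        for j in range(self.k):
            gxp[:, :, pos + j, :] += gcols[:, :, :, j, :]
        return gxp[:, :, pl:pl + t, :]


class BatchNorm(Layer):
    """Batch normalization per feature over (batch, rows, time)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._xhat, self._inv = xhat, inv
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        n = gy.shape[0] * gy.shape[1] * gy.shape[2]
        self.grads["gamma"] = (gy * xhat).sum(axis=(0, 1, 2)).astype(np.float32)
        self.grads["beta"] = gy.sum(axis=(0, 1, 2)).astype(np.float32)
        g = gy * self.params["gamma"]
        gx = (g - g.mean(axis=(0, 1, 2))
              - xhat * (g * xhat).mean(axis=(0, 1, 2))) * inv
        return gx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool1D(Layer):
    """Max pooling along time, stride = pool size, no padding."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        m, r, t, c = x.shape
        out = pool_out_len(t, self.pool)
        xr = x[:, :, :out * self.pool].reshape(m, r, out, self.pool, c)
        y = xr.max(axis=3)
        if train:
            self._argmax = xr.argmax(axis=3)
            self._in_t = t
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        m, r, out, c = gy.shape
        gxr = np.zeros((m, r, out, self.pool, c), dtype=np.float32)
        np.put_along_axis(gxr, self._argmax[:, :, :, None, :], gy[:, :, :, None, :], axis=3)
        gx = np.zeros((m, r, self._in_t, c), dtype=np.float32)
        gx[:, :, :out * self.pool] = gxr.reshape(m, r, out * self.pool, c)
        return gx


class GlobalAvgPool(Layer):
    """Average over rows and time: (M, R, T, C) -> (M, C)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        m, r, t, c = self._shape
        return np.broadcast_to(gy[:, None, None, :] / (r * t), self._shape).astype(np.float32)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (c_in + c_out))
        self.params["W"] = rng.uniform(-limit, limit, (c_in, c_out)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads["W"] = (self._x.T @ gy).astype(np.float32)
        self.grads["b"] = gy.sum(axis=0).astype(np.float32)
        return gy @ self.params["W"].T


class RMSProp:
    """Root-mean-square propagation with Keras-style defaults."""

    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-7) -> None:
        self.lr, self.rho, self.eps = lr, rho, eps
        self._cache: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: list[Layer]) -> None:
        for li, layer in enumerate(layers):
            if not layer.params:
                continue
            cache = self._cache.setdefault(li, {})
            for name, p in layer.params.items():
                g = layer.grads[name]
                c = cache.get(name)
                if c is None:
                    c = np.zeros_like(p)
                c[...] = self.rho * c + (1 - self.rho) * g * g
                cache[name] = c
                p -= self.lr * g / (np.sqrt(c) + self.eps)
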