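"""Minimal CPU neural-network layers with explicit backpropagation.

The analysis-stage network is small (a 4-block CNN at test scale), so the
layers are implemented directly on numpy: im2col convolutions via
``sliding_window_view``, 2x2 max pooling, fully connected layers, global
average pooling, ReLU, and the AdamW optimizer. Each layer caches its
forward inputs and implements ``backward(dout) -> dx``, accumulating
parameter gradients in ``Parameter.grad``. Analytic gradients are verified
against numerical differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Conv2d",
    "Linear",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "AdamW",
    "softplus",
    "sigmoid",
]


#: compute dtype; float32 roughly halves CPU time at ample precision for SGD
DTYPE = np.float32


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), overflow-safe
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


class Layer:
    def parameters(self) -> list[Parameter]:
        return []


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with symmetric zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(rng.normal(
            0.0, scale, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels))
        self.stride = stride
        self.padding = padding
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        kh = kw = self.weight.data.shape[2]
        s, p = self.stride, self.padding
        if p:
            x_pad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            x_pad = x
        win = sliding_window_view(x_pad, (kh, kw), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        out = np.tensordot(win, self.weight.data, axes=([1, 4, 5], [1, 2, 3]))
        out = out.transpose(0, 3, 1, 2) + self.bias.data[None, :, None, None]
        self._cache = (x_pad.shape, win, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        pad_shape, win, x_shape = self._cache
        kh = kw = self.weight.data.shape[2]
        s, p = self.stride, self.padding
        n, _, ho, wo = dout.shape
        self.weight.grad += np.tensordot(dout, win, axes=([0, 2, 3],
                                                          [0, 2, 3]))
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        dxp = np.zeros(pad_shape, dtype=DTYPE)
        for i in range(kh):
            for j in range(kw):
                # gradient routed to input positions (i + s*ho, j + s*wo)
                contrib = np.einsum("nfhw,fc->nchw",
                                    np.asarray(dout, dtype=DTYPE),
                                    self.weight.data[:, :, i, j])
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += contrib
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale,
                                           (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))
        self._x = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = np.asarray(x, dtype=DTYPE)
        return self._x @ self.weight.data.T + self.bias.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.asarray(dout, dtype=DTYPE)
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2; spatial dims must be even."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class GlobalMaxPool(Layer):
    """Global spatial max per channel; suits small localized signals."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        idx = flat.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dflat = np.zeros((n, c, h * w), dtype=DTYPE)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        return dflat.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               (n, c, h, w)).copy()


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.data -= self.lr * ((m / bc1) / (np.sqrt(v / bc2) + self.eps)
                                 + self.weight_decay * p.data)
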