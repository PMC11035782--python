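"""Layers: conv, batch norm, pooling, linear, and containers.

Shapes follow the NCHW convention.  ``forward`` caches whatever ``backward``
needs; ``backward`` accumulates parameter gradients into ``Param.grad`` and
returns the gradient with respect to its input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
]


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N*OH*OW, C*kh*kw) patches, stride applied."""
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, oh, ow = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), (oh, ow)


class Conv2d(Module):
    """2-D cross-correlation: out[i,j] = sum_{m,n} X[i*s+m, j*s+n] * theta[m,n],
    summed over input channels, one kernel per output channel."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k * k
        # Kaiming-normal init for ReLU networks.
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, k, k))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding
        self.kernel_size = k
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        p, s, k = self.padding, self.stride, self.kernel_size
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols, (oh, ow) = _im2col(xp, k, k, s)
        wmat = self.weight.value.reshape(self.out_channels, -1).T  # (C*k*k, F)
        out = cols @ wmat
        if self.bias is not None:
            out += self.bias.value
        n = x.shape[0]
        out = out.reshape(n, oh, ow, self.out_channels).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, xp.shape, x.shape, oh, ow)
        return np.ascontiguousarray(out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cols, xp_shape, x_shape, oh, ow = self._cache
        n = x_shape[0]
        p, s, k = self.padding, self.stride, self.kernel_size
        g = grad_out.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_channels)
        g = np.ascontiguousarray(g, dtype=np.float32)

        self.weight.grad += (cols.T @ g).T.reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=0)

        dcols = g @ self.weight.value.reshape(self.out_channels, -1)  # (N*OH*OW, C*k*k)
        dcols = dcols.reshape(n, oh, ow, self.in_channels, k, k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        # Scatter each kernel tap back; k^2 vectorized adds handle overlaps.
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return out.astype(np.float32)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = grad_out.shape[0] * grad_out.shape[2] * grad_out.shape[3]
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad_out.sum(axis=(0, 2, 3))
        g = grad_out * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gx_sum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (g - gsum / m - xhat * gx_sum / m) * inv_std[None, :, None, None]
        return dx.astype(np.float32)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        self.k = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p, s, k = self.padding, self.stride, self.k
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
            if p
            else x
        )
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, oh, ow = win.shape[:4]
        flat = win.reshape(n, c, oh, ow, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, xp.shape, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        arg, xp_shape, x_shape = self._cache
        p, s, k = self.padding, self.stride, self.k
        n, c, oh, ow = grad_out.shape
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                mask = arg == (i * k + j)
                if not mask.any():
                    continue
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += grad_out * mask
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) by spatial averaging."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            grad_out[:, :, None, None] / (h * w), self._shape
        ).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_features))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if train:
            self._cache = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += x.T @ grad_out
        self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.value.T


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out
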