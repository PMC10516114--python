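"""Minimal NumPy neural-network layers with manual backpropagation.

All layers follow the same contract: ``forward(x, train)`` caches whatever
the backward pass needs on the instance, ``backward(dy)`` accumulates
parameter gradients and returns the gradient w.r.t. the input. Tensors are
NCHW ``float64`` for convolutional layers and ``(N, D)`` for dense layers.

The implementation is deliberately small: it exists because the modelling
stack must run on CPU-only NumPy, and it is exercised by gradient-check
tests rather than trusted blindly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Linear",
    "ReLU",
    "Conv2d",
    "BatchNorm1d",
    "BatchNorm2d",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Flatten",
    "Identity",
    "Sequential",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "frozen")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.frozen = False

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class; subclasses override forward/backward."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> dict[str, Param]:
        return {}

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. BatchNorm running stats)."""
        return {}

    def load_buffers(self, buffers: dict[str, np.ndarray]) -> None:
        for k, v in buffers.items():
            getattr(self, k)[...] = v


class Identity(Layer):
    def forward(self, x, train=False):
        return x

    def backward(self, dy):
        return dy


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def parameters(self):
        return {"W": self.W, "b": self.b}


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Conv2d(Layer):
    """2-D convolution via im2col + matmul. Input/output are NCHW."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = False,
    ):
        self.kernel = kernel
        self.stride = stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = c_in * kernel * kernel
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)))
        self.b = Param(np.zeros(c_out)) if bias else None
        self.c_in = c_in
        self.c_out = c_out

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # win: (N, C, Ho, Wo, k, k) -> cols (N, Ho, Wo, C*k*k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * k * k)
        return np.ascontiguousarray(cols), (n, c, h, w, ho, wo)

    def forward(self, x, train=False):
        cols, shape = self._im2col(x)
        self._cols, self._shape = cols, shape
        n, c, h, w, ho, wo = shape
        y = cols @ self.W.value.T  # (N, Ho, Wo, c_out)
        if self.b is not None:
            y += self.b.value
        return y.transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, c, h, w, ho, wo = self._shape
        k, s, p = self.kernel, self.stride, self.pad
        dyt = dy.transpose(0, 2, 3, 1)  # (N, Ho, Wo, c_out)
        self.W.grad += np.tensordot(dyt, self._cols, axes=([0, 1, 2], [0, 1, 2]))
        if self.b is not None:
            self.b.grad += dyt.sum(axis=(0, 1, 2))
        dcols = dyt @ self.W.value  # (N, Ho, Wo, C*k*k)
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]

    def parameters(self):
        out = {"W": self.W}
        if self.b is not None:
            out["b"] = self.b
        return out


class _BatchNormBase(Layer):
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self._axes: tuple[int, ...] = (0,)

    def _reshape(self, v: np.ndarray) -> np.ndarray:
        return v

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._reshape(mean)) * self._reshape(inv_std)
        self._xhat, self._inv_std, self._train = xhat, inv_std, train
        return self._reshape(self.gamma.value) * xhat + self._reshape(self.beta.value)

    def backward(self, dy):
        xhat, inv_std = self._xhat, self._inv_std
        self.gamma.grad += (dy * xhat).sum(axis=self._axes)
        self.beta.grad += dy.sum(axis=self._axes)
        dxhat = dy * self._reshape(self.gamma.value)
        if not self._train:
            return dxhat * self._reshape(inv_std)
        m = dy.size / dy.shape[1] if dy.ndim == 4 else dy.shape[0]
        mean_dxhat = dxhat.mean(axis=self._axes)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=self._axes)
        return (
            dxhat - self._reshape(mean_dxhat) - xhat * self._reshape(mean_dxhat_xhat)
        ) * self._reshape(inv_std)

    def parameters(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class BatchNorm1d(_BatchNormBase):
    pass


class BatchNorm2d(_BatchNormBase):
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__(dim, momentum, eps)
        self._axes = (0, 2, 3)

    def _reshape(self, v):
        return v.reshape(1, -1, 1, 1)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class GlobalAvgPool2d(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._shape).copy()


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    """Ordered composition of named layers."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers

    def forward(self, x, train=False):
        for _, layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for _, layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        out: dict[str, Param] = {}
        for name, layer in self.layers:
            for k, p in layer.parameters().items():
                out[f"{name}.{k}"] = p
        return out

    def buffers(self):
        out: dict[str, np.ndarray] = {}
        for name, layer in self.layers:
            for k, v in layer.buffers().items():
                out[f"{name}.{k}"] = v
        return out

    def load_buffers(self, buffers):
        for name, layer in self.layers:
            prefix = f"{name}."
            sub = {
                k[len(prefix) :]: v for k, v in buffers.items() if k.startswith(prefix)
            }
            if sub:
                layer.load_buffers(sub)

    def __getitem__(self, name: str) -> Layer:
        for n, layer in self.layers:
            if n == name:
                return layer
        raise KeyError(name)
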