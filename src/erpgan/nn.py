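"""Minimal 1-D convolutional network core with manual backpropagation.

The translation networks here are small (kernel-2, stride-2 convolutions on
256-sample signals), and one independent model is trained per EEG channel.
To make that cheap on a single CPU, every layer carries a leading *bank*
axis: a bank of M per-channel models is evaluated and updated as one batched
einsum/matmul, with identical per-model arithmetic to running the M models
separately.

Shapes are ``(M, C, L)`` — bank, feature channels, temporal length. With
kernel 2 and stride 2 a convolution is exactly a reshape followed by a
matrix product, which keeps both the forward and the backward pass in BLAS.

Batch normalization runs with batch size 1, so it normalizes each feature
map over its temporal axis (instance-norm behavior); the same batch
statistics are used at inference, which keeps generation deterministic
per input.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class Adam:
    """Adaptive-moment optimizer (the pix2pix-style defaults live upstream)."""

    def __init__(self, params: list[Param], lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p in self.params:
            p.m *= self.b1
            p.m += (1 - self.b1) * p.grad
            p.v *= self.b2
            p.v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ConvDown(Layer):
    """Kernel-2 stride-2 convolution: (M, c_in, L) -> (M, c_out, L/2)."""

    def __init__(self, bank: int, c_in: int, c_out: int, rng: np.random.Generator,
                 init_sd: float = 0.02, dtype=np.float64):
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, init_sd, size=(bank, c_in * 2, c_out)).astype(dtype))
        self.b = Param(np.zeros((bank, 1, c_out), dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        m, c, n = x.shape
        if n % 2:
            raise ValueError(f"length {n} not divisible by 2")
        # (M, c, n) -> (M, n/2, 2*c) with the kernel taps adjacent per channel
        xr = x.reshape(m, c, n // 2, 2).transpose(0, 2, 1, 3).reshape(m, n // 2, c * 2)
        self._x = xr
        y = xr @ self.w.value + self.b.value
        return y.transpose(0, 2, 1)

    def backward(self, dy):
        dyt = dy.transpose(0, 2, 1)  # (M, n/2, c_out)
        self.w.grad += self._x.transpose(0, 2, 1) @ dyt
        self.b.grad += dyt.sum(axis=1, keepdims=True)
        dxr = dyt @ self.w.value.transpose(0, 2, 1)  # (M, n/2, 2*c_in)
        m, half, _ = dxr.shape
        return dxr.reshape(m, half, self.c_in, 2).transpose(0, 2, 1, 3).reshape(m, self.c_in, 2 * half)


class ConvUp(Layer):
    """Kernel-2 stride-2 transposed convolution: (M, c_in, L) -> (M, c_out, 2L)."""

    def __init__(self, bank: int, c_in: int, c_out: int, rng: np.random.Generator,
                 init_sd: float = 0.02, dtype=np.float64):
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(rng.normal(0.0, init_sd, size=(bank, c_in, 2 * c_out)).astype(dtype))
        self.b = Param(np.zeros((bank, 1, c_out), dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        m, c, n = x.shape
        xt = x.transpose(0, 2, 1)  # (M, n, c_in)
        self._x = xt
        y = xt @ self.w.value  # (M, n, 2*c_out)
        y = y.reshape(m, n, 2, self.c_out) + self.b.value[:, :, None, :]
        return y.transpose(0, 3, 1, 2).reshape(m, self.c_out, 2 * n)

    def backward(self, dy):
        m, c, n2 = dy.shape
        dyt = dy.reshape(m, c, n2 // 2, 2).transpose(0, 2, 3, 1).reshape(m, n2 // 2, 2 * c)
        self.w.grad += self._x.transpose(0, 2, 1) @ dyt
        self.b.grad += dy.sum(axis=-1)[:, None, :]
        return (dyt @ self.w.value.transpose(0, 2, 1)).transpose(0, 2, 1)


class ConvOne(Layer):
    """Kernel-1 stride-1 convolution (channel mixing only)."""

    def __init__(self, bank: int, c_in: int, c_out: int, rng: np.random.Generator,
                 init_sd: float = 0.02, dtype=np.float64):
        self.w = Param(rng.normal(0.0, init_sd, size=(bank, c_in, c_out)).astype(dtype))
        self.b = Param(np.zeros((bank, 1, c_out), dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x.transpose(0, 2, 1)
        return (self._x @ self.w.value + self.b.value).transpose(0, 2, 1)

    def backward(self, dy):
        dyt = dy.transpose(0, 2, 1)
        self.w.grad += self._x.transpose(0, 2, 1) @ dyt
        self.b.grad += dyt.sum(axis=1, keepdims=True)
        return (dyt @ self.w.value.transpose(0, 2, 1)).transpose(0, 2, 1)


class BatchNorm(Layer):
    """Per-feature normalization over the temporal axis (batch size 1)."""

    def __init__(self, bank: int, channels: int, rng: np.random.Generator,
                 eps: float = 1e-5, init_sd: float = 0.02, dtype=np.float64):
        self.gamma = Param(rng.normal(1.0, init_sd, size=(bank, channels, 1)).astype(dtype))
        self.beta = Param(np.zeros((bank, channels, 1), dtype=dtype))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        n = dy.shape[-1]
        self.gamma.grad += (dy * self._xhat).sum(axis=-1, keepdims=True)
        self.beta.grad += dy.sum(axis=-1, keepdims=True)
        dxhat = dy * self.gamma.value
        return self._istd / n * (
            n * dxhat - dxhat.sum(axis=-1, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=-1, keepdims=True)
        )


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(0.0)


class Tanh(Layer):
    def forward(self, x, train):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(x.dtype) / x.dtype.type(1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x, train):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy
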