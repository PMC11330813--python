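"""Minimal NumPy neural-network core: layers with explicit forward/backward passes.

All feature maps are NHWC ``float`` arrays (batch, height, width, channels).
Every layer caches what its backward pass needs during ``forward``; gradients
are *accumulated* into ``Parameter.grad`` so a parameter used twice in one
graph traversal (e.g. a shared MLP) receives the sum of both contributions.
Call ``zero_grads`` (or ``Adam.zero_grad``) before each backward sweep.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2x2",
    "Upsample2xNearest",
    "Sequential",
    "Adam",
    "he_normal",
    "zero_grads",
]


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return int(self.value.size)


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return (rng.standard_normal(shape) * std).astype(dtype)


class Layer:
    """Base class; children discovered by attribute walk for parameter listing."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for name in vars(self):
            attr = getattr(self, name)
            if isinstance(attr, Parameter):
                out.append(attr)
            elif isinstance(attr, Layer):
                out.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Layer):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def modules(self):
        """Yield self and every sub-layer, in deterministic attribute order."""
        yield self
        for name in vars(self):
            attr = getattr(self, name)
            if isinstance(attr, Layer):
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Layer):
                        yield from item.modules()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


def zero_grads(params: list[Parameter]) -> None:
    for p in params:
        p.grad[...] = 0.0


class Conv2d(Layer):
    """2-D convolution ('same' padding, stride 1) with optional dilation.

    Implemented as a sum of per-tap GEMMs: for each kernel offset the shifted
    input slab is multiplied by that tap's (Cin, Cout) weight matrix.  This
    keeps memory flat (no full im2col buffer) and supports dilation directly.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 bias: bool = True, *, rng: np.random.Generator, dtype=np.float32):
        if cout < 1:
            raise ValueError(f"out_channels must be positive, got {cout}")
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.cin, self.cout, self.k, self.dilation = cin, cout, k, dilation
        self.w = Parameter(he_normal(rng, (k, k, cin, cout), k * k * cin, dtype))
        self.b = Parameter(np.zeros(cout, dtype=dtype)) if bias else None
        self._cache = None

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        p = self.dilation * (self.k // 2)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.zeros((n * h * w, self.cout), dtype=x.dtype)
        for ki in range(self.k):
            for kj in range(self.k):
                oi, oj = ki * self.dilation, kj * self.dilation
                patch = xp[:, oi:oi + h, oj:oj + w, :].reshape(n * h * w, c)
                out += patch @ self.w.value[ki, kj]
        if self.b is not None:
            out += self.b.value
        self._cache = (xp, (n, h, w, c), p)
        return out.reshape(n, h, w, self.cout)

    def backward(self, dy):
        xp, (n, h, w, c), p = self._cache
        dy2 = dy.reshape(n * h * w, self.cout)
        dxp = np.zeros_like(xp)
        for ki in range(self.k):
            for kj in range(self.k):
                oi, oj = ki * self.dilation, kj * self.dilation
                patch = xp[:, oi:oi + h, oj:oj + w, :].reshape(n * h * w, c)
                self.w.grad[ki, kj] += patch.T @ dy2
                dxp[:, oi:oi + h, oj:oj + w, :] += (dy2 @ self.w.value[ki, kj].T
                                                    ).reshape(n, h, w, c)
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        if p == 0:
            return dxp
        return dxp[:, p:p + h, p:p + w, :]


class ConvTranspose2x2(Layer):
    """2×2 transposed convolution with stride 2 (exact ×2 upsampling).

    Kernel 2 / stride 2 tiles the output without overlap, so each of the four
    output phase grids is an independent (Cin, Cout) projection of the input.
    """

    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator, dtype=np.float32):
        self.cin, self.cout = cin, cout
        self.w = Parameter(he_normal(rng, (2, 2, cin, cout), 4 * cin, dtype))
        self.b = Parameter(np.zeros(cout, dtype=dtype))
        self._cache = None

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        x2 = x.reshape(n * h * w, c)
        y = np.empty((n, 2 * h, 2 * w, self.cout), dtype=x.dtype)
        for di in range(2):
            for dj in range(2):
                y[:, di::2, dj::2, :] = (x2 @ self.w.value[di, dj]).reshape(
                    n, h, w, self.cout)
        y += self.b.value
        self._cache = (x2, (n, h, w, c))
        return y

    def backward(self, dy):
        x2, (n, h, w, c) = self._cache
        dx2 = np.zeros_like(x2)
        for di in range(2):
            for dj in range(2):
                dys = dy[:, di::2, dj::2, :].reshape(n * h * w, self.cout)
                self.w.grad[di, dj] += x2.T @ dys
                dx2 += dys @ self.w.value[di, dj].T
        self.b.grad += dy.sum(axis=(0, 1, 2))
        return dx2.reshape(n, h, w, c)


class BatchNorm2d(Layer):
    """Per-channel batch normalisation over (N, H, W) with affine transform."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5, *, dtype=np.float32):
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(
                self.running_mean.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(x.dtype)
        xhat = (x - mean.astype(x.dtype)) / std
        self._cache = (xhat, std, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, std, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        if not train:
            return dxhat / std
        # batch statistics were part of the graph
        mu1 = dxhat.mean(axis=(0, 1, 2))
        mu2 = (dxhat * xhat).mean(axis=(0, 1, 2))
        return (dxhat - mu1 - xhat * mu2) / std


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = expit(x)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool2x2(Layer):
    """2×2 max pooling, stride 2. Ties resolve to the first occurrence."""

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size ({h}, {w}) not divisible by 2")
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = r.reshape(n, h // 2, w // 2, c, 4)
        idx = r.argmax(axis=-1)
        self._onehot = (idx[..., None] == np.arange(4)).astype(x.dtype)
        self._shape = (n, h, w, c)
        return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._shape
        dr = dy[..., None] * self._onehot  # (n, h/2, w/2, c, 4)
        dr = dr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dr.reshape(n, h, w, c)


class Upsample2xNearest(Layer):
    """Parameter-free ×2 nearest-neighbour upsampling."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        n, h, w, c = self._shape
        return dy.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam optimiser (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        zero_grads(self.params)

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr * (m / bc1) /
                        (np.sqrt(v / bc2) + self.eps)).astype(p.value.dtype)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(a) for a in state["m"]]
        self.v = [np.asarray(a) for a in state["v"]]
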