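"""Attention primitives: squeeze-excitation, channel/spatial attention (CBAM)
and the additive attention gate used on the decoder skip connections.

All gains come out of a sigmoid, so every attention map lies strictly in
(0, 1) and gated features never exceed the input in magnitude element-wise.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .nn import BatchNorm2d, Conv2d, Layer, Parameter, he_normal

ATTENTION_VARIANTS = ("none", "cam", "sam", "cbam")


def _sigmoid(x):
    return expit(x)


class Identity(Layer):
    def forward(self, x, train=True):
        return x

    def backward(self, dy):
        return dy


def _hidden_width(channels: int, reduction: int, floor: int = 4) -> int:
    """Bottleneck width of the two-layer excitation MLP (C/r, floored)."""
    return max(channels // reduction, min(floor, channels))


class SEBlock(Layer):
    """Squeeze-and-excitation: global average pool -> C/r bottleneck MLP ->
    sigmoid channel gains -> rescale the input map."""

    def __init__(self, c: int, reduction: int = 16, *, rng: np.random.Generator,
                 dtype=np.float32):
        hidden = _hidden_width(c, reduction)
        self.c, self.hidden = c, hidden
        self.w1 = Parameter(he_normal(rng, (c, hidden), c, dtype))
        self.b1 = Parameter(np.zeros(hidden, dtype=dtype))
        self.w2 = Parameter(he_normal(rng, (hidden, c), hidden, dtype))
        self.b2 = Parameter(np.zeros(c, dtype=dtype))
        self._cache = None

    def channel_gains(self, x: np.ndarray) -> np.ndarray:
        """The (N, C) sigmoid gains for input ``x`` (no caching)."""
        z = x.mean(axis=(1, 2))
        h = np.maximum(z @ self.w1.value + self.b1.value, 0.0)
        return _sigmoid(h @ self.w2.value + self.b2.value)

    def forward(self, x, train=True):
        n, hh, ww, c = x.shape
        z = x.mean(axis=(1, 2))
        pre = z @ self.w1.value + self.b1.value
        h = np.maximum(pre, 0.0)
        s = _sigmoid(h @ self.w2.value + self.b2.value)
        self._cache = (x, z, pre, h, s)
        return x * s[:, None, None, :]

    def backward(self, dy):
        x, z, pre, h, s = self._cache
        n, hh, ww, c = x.shape
        dx = dy * s[:, None, None, :]
        ds = (dy * x).sum(axis=(1, 2))
        dlogit = ds * s * (1.0 - s)
        self.w2.grad += h.T @ dlogit
        self.b2.grad += dlogit.sum(axis=0)
        dh = (dlogit @ self.w2.value.T) * (pre > 0)
        self.w1.grad += z.T @ dh
        self.b1.grad += dh.sum(axis=0)
        dz = dh @ self.w1.value.T
        dx += dz[:, None, None, :] / (hh * ww)
        return dx


class ChannelAttention(Layer):
    """CBAM channel attention.

    Global max- and average-pooled channel descriptors go through one shared
    two-layer MLP; the two outputs are summed element-wise and squashed by a
    single sigmoid (the standard CBAM form).  ``printed_form=True`` instead
    applies a sigmoid to each branch before summing — an alternative reading
    kept only for comparison; its gains lie in (0, 2).
    """

    def __init__(self, c: int, reduction: int = 16, printed_form: bool = False,
                 *, rng: np.random.Generator, dtype=np.float32):
        hidden = _hidden_width(c, reduction)
        self.c, self.hidden = c, hidden
        self.printed_form = printed_form
        self.w1 = Parameter(he_normal(rng, (c, hidden), c, dtype))
        self.b1 = Parameter(np.zeros(hidden, dtype=dtype))
        self.w2 = Parameter(he_normal(rng, (hidden, c), hidden, dtype))
        self.b2 = Parameter(np.zeros(c, dtype=dtype))
        self._cache = None

    def _mlp(self, v):
        pre = v @ self.w1.value + self.b1.value
        h = np.maximum(pre, 0.0)
        return pre, h, h @ self.w2.value + self.b2.value

    def forward(self, x, train=True):
        n, hh, ww, c = x.shape
        flat = x.reshape(n, hh * ww, c)
        avg = flat.mean(axis=1)
        amax = flat.argmax(axis=1)            # (n, c) winning pixel per channel
        mx = np.take_along_axis(flat, amax[:, None, :], axis=1)[:, 0, :]
        pre_a, h_a, out_a = self._mlp(avg)
        pre_m, h_m, out_m = self._mlp(mx)
        if self.printed_form:
            s = _sigmoid(out_a) + _sigmoid(out_m)
            sig = (_sigmoid(out_a), _sigmoid(out_m))
        else:
            s = _sigmoid(out_a + out_m)
            sig = (s,)
        self._cache = (x.shape, avg, amax, mx, pre_a, h_a, pre_m, h_m, sig)
        return s

    def backward(self, ds):
        shape, avg, amax, mx, pre_a, h_a, pre_m, h_m, sig = self._cache
        n, hh, ww, c = shape
        if self.printed_form:
            sa, sm = sig
            dout_a = ds * sa * (1.0 - sa)
            dout_m = ds * sm * (1.0 - sm)
        else:
            (s,) = sig
            dcommon = ds * s * (1.0 - s)
            dout_a = dout_m = dcommon

        def back_mlp(dout, pre, h, v):
            self.w2.grad += h.T @ dout
            self.b2.grad += dout.sum(axis=0)
            dh = (dout @ self.w2.value.T) * (pre > 0)
            self.w1.grad += v.T @ dh
            self.b1.grad += dh.sum(axis=0)
            return dh @ self.w1.value.T

        davg = back_mlp(dout_a, pre_a, h_a, avg)
        dmx = back_mlp(dout_m, pre_m, h_m, mx)
        dflat = np.zeros((n, hh * ww, c), dtype=davg.dtype)
        dflat += davg[:, None, :] / (hh * ww)
        np.put_along_axis(
            dflat, amax[:, None, :],
            np.take_along_axis(dflat, amax[:, None, :], axis=1) + dmx[:, None, :],
            axis=1)
        return dflat.reshape(n, hh, ww, c)


class SpatialAttention(Layer):
    """CBAM spatial attention: channel-wise max and mean maps, concatenated,
    reduced to one channel by a 7x7 convolution and squashed by a sigmoid."""

    def __init__(self, k: int = 7, *, rng: np.random.Generator, dtype=np.float32):
        self.conv = Conv2d(2, 1, k=k, rng=rng, dtype=dtype)
        self._cache = None

    def forward(self, x, train=True):
        n, hh, ww, c = x.shape
        avg = x.mean(axis=3, keepdims=True)
        amax = x.argmax(axis=3)
        mx = np.take_along_axis(x, amax[..., None], axis=3)
        logits = self.conv.forward(np.concatenate([avg, mx], axis=3), train=train)
        s = _sigmoid(logits)
        self._cache = (x.shape, amax, s)
        return s

    def backward(self, ds):
        shape, amax, s = self._cache
        n, hh, ww, c = shape
        dlogits = ds * s * (1.0 - s)
        dcat = self.conv.backward(dlogits)
        davg, dmx = dcat[..., :1], dcat[..., 1:]
        dx = np.zeros(shape, dtype=dcat.dtype)
        dx += davg / c
        np.put_along_axis(
            dx, amax[..., None],
            np.take_along_axis(dx, amax[..., None], axis=3) + dmx, axis=3)
        return dx


class CBAM(Layer):
    """Channel attention followed by spatial attention, each applied
    multiplicatively (F' = F * Mc(F);  out = F' * Ms(F'))."""

    def __init__(self, c: int, reduction: int = 16, printed_form: bool = False,
                 *, rng: np.random.Generator, dtype=np.float32):
        self.cam = ChannelAttention(c, reduction, printed_form, rng=rng, dtype=dtype)
        self.sam = SpatialAttention(rng=rng, dtype=dtype)
        self._cache = None

    def forward(self, x, train=True):
        sc = self.cam.forward(x, train=train)
        xp = x * sc[:, None, None, :]
        ss = self.sam.forward(xp, train=train)
        y = xp * ss
        self._cache = (x, sc, xp, ss)
        return y

    def backward(self, dy):
        x, sc, xp, ss = self._cache
        dxp = dy * ss
        dss = (dy * xp).sum(axis=3, keepdims=True)
        dxp += self.sam.backward(dss)
        dx = dxp * sc[:, None, None, :]
        dsc = (dxp * x).sum(axis=(1, 2))
        dx += self.cam.backward(dsc)
        return dx


class CAMOnly(Layer):
    """Channel attention applied as a gate (the 'CAM connection' ablation)."""

    def __init__(self, c: int, reduction: int = 16, *, rng, dtype=np.float32):
        self.cam = ChannelAttention(c, reduction, rng=rng, dtype=dtype)
        self._cache = None

    def forward(self, x, train=True):
        s = self.cam.forward(x, train=train)
        self._cache = (x, s)
        return x * s[:, None, None, :]

    def backward(self, dy):
        x, s = self._cache
        dx = dy * s[:, None, None, :]
        dx += self.cam.backward((dy * x).sum(axis=(1, 2)))
        return dx


class SAMOnly(Layer):
    """Spatial attention applied as a gate (the 'SAM connection' ablation)."""

    def __init__(self, c: int, *, rng, dtype=np.float32):
        self.sam = SpatialAttention(rng=rng, dtype=dtype)
        self._cache = None

    def forward(self, x, train=True):
        s = self.sam.forward(x, train=train)
        self._cache = (x, s)
        return x * s

    def backward(self, dy):
        x, s = self._cache
        dx = dy * s
        dx += self.sam.backward((dy * x).sum(axis=3, keepdims=True))
        return dx


def make_attention(variant: str, c: int, reduction: int = 16,
                   printed_form: bool = False, *, rng, dtype=np.float32) -> Layer:
    if variant == "none":
        return Identity()
    if variant == "cam":
        return CAMOnly(c, reduction, rng=rng, dtype=dtype)
    if variant == "sam":
        return SAMOnly(c, rng=rng, dtype=dtype)
    if variant == "cbam":
        return CBAM(c, reduction, printed_form, rng=rng, dtype=dtype)
    raise ValueError(f"unknown attention variant {variant!r}; "
                     f"expected one of {ATTENTION_VARIANTS}")


class AttentionGate(Layer):
    """Additive attention gate.

    The gating signal (upsampled decoder feature) and the skip feature are
    each projected by a 1x1 convolution + batch-norm into a common
    intermediate width (skip channels / 2), summed, passed through ReLU, then
    reduced to a single-channel sigmoid coefficient map alpha which rescales
    the skip feature pixel-wise.
    """

    def __init__(self, skip_c: int, gate_c: int, *, rng: np.random.Generator,
                 dtype=np.float32):
        inter = max(skip_c // 2, 1)
        self.theta = Conv2d(skip_c, inter, k=1, rng=rng, dtype=dtype)
        self.bn_theta = BatchNorm2d(inter, dtype=dtype)
        self.phi = Conv2d(gate_c, inter, k=1, rng=rng, dtype=dtype)
        self.bn_phi = BatchNorm2d(inter, dtype=dtype)
        self.psi = Conv2d(inter, 1, k=1, rng=rng, dtype=dtype)
        self.bn_psi = BatchNorm2d(1, dtype=dtype)
        self._cache = None

    def forward(self, gate: np.ndarray, skip: np.ndarray, train: bool = True):
        if gate.shape[1:3] != skip.shape[1:3]:
            raise ValueError(
                f"gate spatial size {gate.shape[1:3]} != skip {skip.shape[1:3]}")
        a = (self.bn_phi.forward(self.phi.forward(gate, train), train)
             + self.bn_theta.forward(self.theta.forward(skip, train), train))
        relu_mask = a > 0
        a = a * relu_mask
        logits = self.bn_psi.forward(self.psi.forward(a, train), train)
        alpha = _sigmoid(logits)
        self._cache = (skip, relu_mask, alpha)
        return skip * alpha

    __call__ = forward

    def backward(self, dy):
        skip, relu_mask, alpha = self._cache
        dskip = dy * alpha
        dalpha = (dy * skip).sum(axis=3, keepdims=True)
        dlogits = dalpha * alpha * (1.0 - alpha)
        da = self.psi.backward(self.bn_psi.backward(dlogits)) * relu_mask
        dgate = self.phi.backward(self.bn_phi.backward(da))
        dskip += self.theta.backward(self.bn_theta.backward(da))
        return dgate, dskip
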