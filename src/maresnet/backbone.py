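"""Residual encoder-decoder backbone and full-model assembly.

The skeleton is a depth-4 U-Net: per encoder stage a (residual) double-conv
block then 2x2 max-pool, channel width doubling from ``base_width``; a
bottleneck block at 1/16 resolution; per decoder level a 2x2 transposed-conv
upsample, optional attention gating of the skip, concatenation and another
block; a final 1x1 convolution with sigmoid yields the lesion probability
map.  Architecture switches (``use_residual``, ``use_sfem``, ``use_mcem``,
``use_ag``) select every ablation variant down to a plain U-Net baseline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .attention import ATTENTION_VARIANTS, AttentionGate
from .mcem import MCEM
from .nn import (BatchNorm2d, Conv2d, ConvTranspose2x2, Layer, MaxPool2x2,
                 ReLU, Sequential, Sigmoid)
from .sfem import SFEM


class ConfigurationError(ValueError):
    """Invalid model or training configuration."""


class ShapeError(ValueError):
    """Input shape incompatible with the architecture."""


@dataclass
class ModelConfig:
    """Architecture switches and sizes.

    ``use_residual`` adds identity/projection shortcuts to every conv block;
    ``use_sfem`` puts a scale-aware feature extraction module on each skip;
    ``use_mcem`` runs the multi-scale compression-excitation cascade over the
    (possibly SFEM-refined) skips; ``use_ag`` gates each skip with an
    attention gate before decoder concatenation.  All flags off is the plain
    U-Net baseline; all on is the full MARes-Net.
    """

    base_width: int = 16
    depth: int = 4
    in_channels: int = 1
    use_residual: bool = True
    use_sfem: bool = True
    use_mcem: bool = True
    use_ag: bool = True
    sfem_attention: str = "cbam"
    cam_printed_form: bool = False
    se_reduction: int = 16
    seed: int = 0
    dtype: str = "float32"

    def validate(self) -> None:
        if self.base_width < 4:
            raise ConfigurationError(f"base_width must be >= 4, got {self.base_width}")
        if self.depth < 2:
            raise ConfigurationError(f"depth must be >= 2, got {self.depth}")
        if self.in_channels < 1:
            raise ConfigurationError(
                f"in_channels must be >= 1, got {self.in_channels}")
        if self.sfem_attention not in ATTENTION_VARIANTS:
            raise ConfigurationError(
                f"sfem_attention must be one of {ATTENTION_VARIANTS}, "
                f"got {self.sfem_attention!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        cfg.validate()
        return cfg

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def stage_channels(self) -> list[int]:
        """Per-stage encoder widths, finest first (e.g. [16, 32, 64, 128])."""
        return [self.base_width * 2 ** i for i in range(self.depth)]


@dataclass
class EncoderState:
    """Pre-pool features of every encoder stage (finest first) plus the
    bottleneck feature at 1/2**depth resolution."""

    stage_features: list[np.ndarray]
    bottleneck: np.ndarray


class ResidualBlock(Layer):
    """Two (3x3 conv -> BN -> ReLU) stages plus a shortcut: identity when the
    channel count is unchanged, else a 1x1 conv + BN projection.  With
    ``use_residual=False`` the shortcut is dropped (plain double-conv)."""

    def __init__(self, cin: int, cout: int, use_residual: bool = True, *,
                 rng, dtype=np.float32):
        if cout < 1:
            raise ConfigurationError(f"out_channels must be positive, got {cout}")
        self.f = Sequential(
            Conv2d(cin, cout, k=3, rng=rng, dtype=dtype),
            BatchNorm2d(cout, dtype=dtype), ReLU(),
            Conv2d(cout, cout, k=3, rng=rng, dtype=dtype),
            BatchNorm2d(cout, dtype=dtype), ReLU(),
        )
        self.use_residual = use_residual
        self.shortcut = None
        if use_residual and cin != cout:
            self.shortcut = Sequential(Conv2d(cin, cout, k=1, rng=rng, dtype=dtype),
                                       BatchNorm2d(cout, dtype=dtype))

    def forward(self, x, train=True):
        y = self.f.forward(x, train)
        if not self.use_residual:
            return y
        if self.shortcut is None:
            return y + x
        return y + self.shortcut.forward(x, train)

    def backward(self, dy):
        dx = self.f.backward(dy)
        if not self.use_residual:
            return dx
        if self.shortcut is None:
            return dx + dy
        return dx + self.shortcut.backward(dy)


def residual_block(x: np.ndarray, out_channels: int, *, use_residual: bool = True,
                   rng=None, dtype=np.float32) -> np.ndarray:
    """Convenience functional form: build a block and run one forward pass."""
    rng = rng if rng is not None else np.random.default_rng(0)
    block = ResidualBlock(x.shape[3], out_channels, use_residual, rng=rng, dtype=dtype)
    return block.forward(x, train=True)


class MaresNet(Layer):
    """Full model: encoder -> per-skip SFEM -> MCEM cascade -> attention-gated
    decoder -> 1x1 conv + sigmoid, each piece switchable via ModelConfig."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        dtype = config.np_dtype
        widths = config.stage_channels()
        res = config.use_residual

        self.enc_blocks, self.pools = [], []
        cin = config.in_channels
        for w in widths:
            self.enc_blocks.append(ResidualBlock(cin, w, res, rng=rng, dtype=dtype))
            self.pools.append(MaxPool2x2())
            cin = w
        bott_w = widths[-1] * 2
        self.bottleneck = ResidualBlock(widths[-1], bott_w, res, rng=rng, dtype=dtype)

        self.sfems = None
        if config.use_sfem:
            self.sfems = [SFEM(w, config.sfem_attention, config.cam_printed_form,
                               rng=rng, dtype=dtype) for w in widths]
        self.mcem = None
        if config.use_mcem:
            self.mcem = MCEM(widths, config.se_reduction, rng=rng, dtype=dtype)

        self.upconvs, self.gates, self.dec_blocks = [], [], []
        up_in = bott_w
        for w in reversed(widths):  # coarsest decoder level first
            self.upconvs.append(ConvTranspose2x2(up_in, w, rng=rng, dtype=dtype))
            if config.use_ag:
                self.gates.append(AttentionGate(w, w, rng=rng, dtype=dtype))
            self.dec_blocks.append(ResidualBlock(2 * w, w, res, rng=rng, dtype=dtype))
            up_in = w
        self.final = Conv2d(widths[0], 1, k=1, rng=rng, dtype=dtype)
        self.sigmoid = Sigmoid()

    # -- encoder -------------------------------------------------------------
    def _validate_spatial(self, h: int, w: int) -> None:
        factor = 2 ** self.config.depth
        for name, v in (("height", h), ("width", w)):
            if v % factor:
                raise ShapeError(
                    f"input {name} {v} is not divisible by 2**depth = {factor}")

    def encode(self, x: np.ndarray, train: bool = True) -> EncoderState:
        if x.ndim != 4:
            raise ShapeError(f"expected NHWC input, got ndim={x.ndim}")
        if x.shape[3] != self.config.in_channels:
            raise ShapeError(f"expected {self.config.in_channels} input "
                             f"channels, got {x.shape[3]}")
        self._validate_spatial(x.shape[1], x.shape[2])
        skips = []
        h = x
        for block, pool in zip(self.enc_blocks, self.pools):
            f = block.forward(h, train)
            skips.append(f)
            h = pool.forward(f, train)
        return EncoderState(stage_features=skips, bottleneck=self.bottleneck.forward(h, train))

    def decode(self, state: EncoderState, skips: list[np.ndarray],
               train: bool = True) -> np.ndarray:
        for s, f in zip(skips, state.stage_features):
            if s.shape[1:3] != f.shape[1:3]:
                raise ShapeError(f"skip spatial size {s.shape[1:3]} does not "
                                 f"match stage size {f.shape[1:3]}")
        h = state.bottleneck
        self._split_widths = []
        for lvl, (up, block) in enumerate(zip(self.upconvs, self.dec_blocks)):
            u = up.forward(h, train)
            sk = skips[len(skips) - 1 - lvl]
            if self.config.use_ag:
                sk = self.gates[lvl](u, sk, train=train)
            self._split_widths.append(u.shape[3])
            h = block.forward(np.concatenate([u, sk], axis=3), train)
        return self.sigmoid.forward(self.final.forward(h, train), train)

    def forward(self, x, train=True):
        state = self.encode(x, train)
        skips = state.stage_features
        if self.sfems is not None:
            skips = [m.forward(s, train) for m, s in zip(self.sfems, skips)]
        if self.mcem is not None:
            skips = self.mcem.forward(skips, train)
        return self.decode(state, skips, train)

    def backward(self, dprob):
        depth = self.config.depth
        d = self.final.backward(self.sigmoid.backward(dprob))
        dskips: list[np.ndarray | None] = [None] * depth
        for lvl in range(depth - 1, -1, -1):  # reverse of decoder order
            dcat = self.dec_blocks[lvl].backward(d)
            cu = self._split_widths[lvl]
            du, dsk = dcat[..., :cu].copy(), dcat[..., cu:]
            if self.config.use_ag:
                dg, dsk = self.gates[lvl].backward(dsk)
                du += dg
            dskips[depth - 1 - lvl] = dsk
            d = self.upconvs[lvl].backward(du)
        dh = self.bottleneck.backward(d)
        if self.mcem is not None:
            dskips = self.mcem.backward(dskips)
        if self.sfems is not None:
            dskips = [m.backward(ds) for m, ds in zip(self.sfems, dskips)]
        for i in range(depth - 1, -1, -1):
            df = self.pools[i].backward(dh) + dskips[i]
            dh = self.enc_blocks[i].backward(df)
        return dh


def build_model(config: ModelConfig) -> MaresNet:
    """Wire the architecture selected by ``config`` (all flags off = U-Net)."""
    return MaresNet(config)


def encoder_forward(image: np.ndarray, config: ModelConfig) -> EncoderState:
    """Build a fresh seeded model and run its encoder on ``image``."""
    return build_model(config).encode(image)


def decoder_forward(model: MaresNet, state: EncoderState,
                    skips: list[np.ndarray]) -> np.ndarray:
    return model.decode(state, skips)


def count_parameters(model: MaresNet) -> int:
    """Total number of trainable scalars (deterministic for a fixed config)."""
    return sum(p.size for p in model.parameters())


def model_name(config: ModelConfig) -> str:
    """Human name matching the ablation-table row convention."""
    flags = (config.use_ag, config.use_sfem, config.use_mcem)
    if config.use_residual and all(flags):
        return "MARes-Net"
    if not config.use_residual and not any(flags):
        return "U-Net"
    base = "ResU" if config.use_residual else "U-Net"
    parts = [base]
    if config.use_ag:
        parts.append("AG")
    if config.use_sfem:
        parts.append("SFEM")
    if config.use_mcem:
        parts.append("MCEM")
    return " + ".join(parts)


def parameter_report(config: ModelConfig) -> dict:
    """Name, raw trainable-parameter count and count in millions (2 dp)."""
    n = count_parameters(build_model(config))
    return {"model": model_name(config), "parameters": n,
            "millions": round(n / 1e6, 2)}
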