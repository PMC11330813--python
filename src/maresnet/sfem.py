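"""Scale-aware feature extraction: three parallel 3x3 convolutions at
dilation rates 1/3/5, pairwise fusion of neighbouring scales, attention
refinement (CBAM by default) and a residual aggregation with the input.

The module is shape-preserving (same H, W, C out as in), so it can sit on
any skip connection without changing the decoder's channel arithmetic.
"""

from __future__ import annotations

import numpy as np

from .attention import make_attention
from .nn import BatchNorm2d, Conv2d, Layer, ReLU, Sequential

DILATION_RATES = (1, 3, 5)


def dilated_branch(cin: int, rate: int, *, rng, dtype=np.float32) -> Sequential:
    """One branch: 3x3 conv with the given dilation (padding = rate, so shape
    is preserved), batch-norm, ReLU. Channel count is preserved."""
    if rate not in DILATION_RATES:
        raise ValueError(f"unsupported dilation rate {rate}; expected one of "
                         f"{DILATION_RATES}")
    return Sequential(
        Conv2d(cin, cin, k=3, dilation=rate, rng=rng, dtype=dtype),
        BatchNorm2d(cin, dtype=dtype),
        ReLU(),
    )


class SFEM(Layer):
    """Scale-aware feature extraction module.

    Pipeline for input ``Fin`` with C channels:

    * F1, F2, F3  — dilated branches at rates 1, 3, 5 (each C channels)
    * F12 = [F1, F2], F23 = [F2, F3]           (channel concatenation, 2C)
    * G = 3x3 conv(+BN+ReLU) of each fused pair (2C -> 2C)
    * refinement sees all parent scales: attn([G12, F1, F2]) -> F12' (4C)
    * Fout = 1x1 projection (+BN) of [F12', F23', Fin] back to C channels
    """

    def __init__(self, c: int, attention_variant: str = "cbam",
                 cam_printed_form: bool = False, *, rng, dtype=np.float32):
        self.c = c
        self.branches = [dilated_branch(c, r, rng=rng, dtype=dtype)
                         for r in DILATION_RATES]
        self.fuse12 = Sequential(Conv2d(2 * c, 2 * c, k=3, rng=rng, dtype=dtype),
                                 BatchNorm2d(2 * c, dtype=dtype), ReLU())
        self.fuse23 = Sequential(Conv2d(2 * c, 2 * c, k=3, rng=rng, dtype=dtype),
                                 BatchNorm2d(2 * c, dtype=dtype), ReLU())
        self.attn12 = make_attention(attention_variant, 4 * c,
                                     printed_form=cam_printed_form, rng=rng, dtype=dtype)
        self.attn23 = make_attention(attention_variant, 4 * c,
                                     printed_form=cam_printed_form, rng=rng, dtype=dtype)
        self.proj = Sequential(Conv2d(9 * c, c, k=1, rng=rng, dtype=dtype),
                               BatchNorm2d(c, dtype=dtype))

    def forward(self, x, train=True):
        c = self.c
        if x.shape[3] != c:
            raise ValueError(f"expected {c} channels, got {x.shape[3]}")
        f1 = self.branches[0].forward(x, train)
        f2 = self.branches[1].forward(x, train)
        f3 = self.branches[2].forward(x, train)
        g12 = self.fuse12.forward(np.concatenate([f1, f2], axis=3), train)
        g23 = self.fuse23.forward(np.concatenate([f2, f3], axis=3), train)
        r12 = self.attn12.forward(np.concatenate([g12, f1, f2], axis=3), train)
        r23 = self.attn23.forward(np.concatenate([g23, f2, f3], axis=3), train)
        return self.proj.forward(np.concatenate([r12, r23, x], axis=3), train)

    def backward(self, dy):
        c = self.c
        dcat = self.proj.backward(dy)
        dr12, dr23, dx = dcat[..., :4 * c], dcat[..., 4 * c:8 * c], dcat[..., 8 * c:]
        dx = dx.copy()

        d12 = self.attn12.backward(dr12)
        dg12, df1, df2 = d12[..., :2 * c], d12[..., 2 * c:3 * c], d12[..., 3 * c:]
        df1, df2 = df1.copy(), df2.copy()
        d23 = self.attn23.backward(dr23)
        dg23 = d23[..., :2 * c]
        df2 += d23[..., 2 * c:3 * c]
        df3 = d23[..., 3 * c:].copy()

        dfuse12 = self.fuse12.backward(dg12)
        df1 += dfuse12[..., :c]
        df2 += dfuse12[..., c:]
        dfuse23 = self.fuse23.backward(dg23)
        df2 += dfuse23[..., :c]
        df3 += dfuse23[..., c:]

        dx += self.branches[0].backward(df1)
        dx += self.branches[1].backward(df2)
        dx += self.branches[2].backward(df3)
        return dx
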