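"""Multi-scale compression-excitation over the four encoder scales.

Each level runs an independent compression-excitation path (3x3 conv ->
squeeze-excitation -> 1x1 conv).  A top-down cascade then injects coarse
context into finer levels: the coarsest output passes through untouched,
and every finer level fuses its own excited map with the next-coarser
output (1x1 channel projection, nearest x2 upsampling, element-wise
addition, 3x3 merging conv).  Every output keeps its input's shape, so the
module is transparent to the decoder.
"""

from __future__ import annotations

import numpy as np

from .attention import SEBlock
from .nn import BatchNorm2d, Conv2d, Layer, ReLU, Sequential, Upsample2xNearest


def compress_excite_path(c: int, se_reduction: int = 16, *, rng,
                         dtype=np.float32) -> Sequential:
    """One level's path: 3x3 conv (+BN+ReLU) -> SE channel reweighting ->
    1x1 conv; channels and spatial size preserved."""
    return Sequential(
        Conv2d(c, c, k=3, rng=rng, dtype=dtype),
        BatchNorm2d(c, dtype=dtype),
        ReLU(),
        SEBlock(c, se_reduction, rng=rng, dtype=dtype),
        Conv2d(c, c, k=1, rng=rng, dtype=dtype),
    )


class MCEM(Layer):
    """Multi-scale compression-excitation module over levels finest-first.

    ``channels`` lists per-level channel counts, finest level first; level
    i+1 must be spatially half of level i.
    """

    def __init__(self, channels: list[int], se_reduction: int = 16, *, rng,
                 dtype=np.float32):
        self.channels = list(channels)
        n = len(channels)
        self.paths = [compress_excite_path(c, se_reduction, rng=rng, dtype=dtype)
                      for c in channels]
        # lateral projection + upsample + merge conv for levels 0..n-2
        self.projs = [Conv2d(channels[i + 1], channels[i], k=1, rng=rng, dtype=dtype)
                      for i in range(n - 1)]
        self.ups = [Upsample2xNearest() for _ in range(n - 1)]
        self.merges = [Sequential(Conv2d(channels[i], channels[i], k=3, rng=rng,
                                         dtype=dtype),
                                  BatchNorm2d(channels[i], dtype=dtype), ReLU())
                       for i in range(n - 1)]

    def _check(self, xs):
        if len(xs) != len(self.channels):
            raise ValueError(f"expected {len(self.channels)} levels, got {len(xs)}")
        for i in range(len(xs) - 1):
            h, w = xs[i].shape[1:3]
            h2, w2 = xs[i + 1].shape[1:3]
            if (h, w) != (2 * h2, 2 * w2):
                raise ValueError(
                    f"level {i + 1} spatial size ({h2}, {w2}) is not half of "
                    f"level {i} ({h}, {w})")

    def forward(self, xs: list[np.ndarray], train: bool = True) -> list[np.ndarray]:
        self._check(xs)
        n = len(xs)
        ys = [self.paths[i].forward(xs[i], train) for i in range(n)]
        fs: list[np.ndarray | None] = [None] * n
        fs[n - 1] = ys[n - 1]  # coarsest level passes through uninterrupted
        for i in range(n - 2, -1, -1):
            ctx = self.ups[i].forward(self.projs[i].forward(fs[i + 1], train), train)
            fs[i] = self.merges[i].forward(ys[i] + ctx, train)
        return fs  # type: ignore[return-value]

    __call__ = forward

    def backward(self, dfs: list[np.ndarray]) -> list[np.ndarray]:
        n = len(self.channels)
        dfs = [d.copy() for d in dfs]
        dys: list[np.ndarray | None] = [None] * n
        for i in range(n - 1):  # fine to coarse: propagate context gradients up
            dsum = self.merges[i].backward(dfs[i])
            dys[i] = dsum
            dfs[i + 1] += self.projs[i].backward(self.ups[i].backward(dsum))
        dys[n - 1] = dfs[n - 1]
        return [self.paths[i].backward(dys[i]) for i in range(n)]
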