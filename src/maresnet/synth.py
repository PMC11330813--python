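"""Synthetic radiograph-like patch generator with exact lesion masks.

Stands in for a private clinical radiograph dataset: 8-bit grayscale
patches with a textured, intensity-graded background, a few bright
elliptical distractor structures (bone/teeth-like, deliberately *not* in
the mask, so attention has something to suppress), and 1-3 dark
(radiolucent) lesions built from randomly placed, rotated, possibly
overlapping ellipses.  Cystic lesions are fluid-filled and therefore
hypodense, so lesions darken the image; the ground-truth mask is the exact
pre-blur ellipse union, while the rendered lesion edge is Gaussian-blurred
to mimic the gradual boundary of real lucencies.  Fully deterministic per
seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import ImageSample, save_pairs


@dataclass
class SynthParams:
    size: int = 256
    lesion_count: tuple[int, int] = (1, 3)
    lesion_radius: tuple[float, float] = (12.0, 48.0)
    lesion_aspect: tuple[float, float] = (0.55, 1.0)    # minor/major axis ratio
    lesion_contrast: tuple[float, float] = (0.2, 0.5)   # intensity drop fraction
    edge_blur_sigma: tuple[float, float] = (2.0, 6.0)   # px
    texture_scale: float = 24.0                          # background blob size, px
    texture_sd: float = 14.0                             # intensity units
    gradient_amplitude: float = 25.0                     # intensity units
    base_intensity: float = 165.0
    noise_sd: float = 6.0                                # intensity units
    distractor_count: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.size < 16 or self.size % 16:
            raise ValueError(f"size must be a positive multiple of 16, got {self.size}")
        if self.lesion_count[0] < 0 or self.lesion_count[0] > self.lesion_count[1]:
            raise ValueError(f"bad lesion_count range {self.lesion_count}")
        for name in ("lesion_radius", "lesion_aspect", "lesion_contrast",
                     "edge_blur_sigma"):
            lo, hi = getattr(self, name)
            if lo <= 0 or lo > hi:
                raise ValueError(f"bad {name} range ({lo}, {hi})")
        if self.lesion_radius[1] >= self.size / 2:
            raise ValueError(
                f"lesion radius {self.lesion_radius[1]} exceeds half the image "
                f"size {self.size}")

    @classmethod
    def easy(cls, size: int = 128) -> "SynthParams":
        """High-contrast, sharp-edged, low-noise regime used for scaled-down
        training demonstrations."""
        return cls(size=size, lesion_count=(1, 2), lesion_radius=(10.0, 28.0),
                   lesion_contrast=(0.4, 0.55), edge_blur_sigma=(1.0, 2.0),
                   noise_sd=4.0, distractor_count=2)


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float) -> np.ndarray:
    """Exact point-in-ellipse raster (pixel centres)."""
    rows, cols = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    y, x = rows - cy, cols - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * y + st * x
    v = -st * y + ct * x
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def render_background(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Lesion-free render: smoothed-noise texture + linear intensity gradient
    + bright elliptical distractors.  Float image, un-noised, un-clipped."""
    s = params.size
    img = np.full((s, s), params.base_intensity, dtype=np.float64)
    # low-frequency texture
    tex = ndimage.gaussian_filter(rng.standard_normal((s, s)), params.texture_scale)
    sd = tex.std()
    if sd > 0:
        img += tex / sd * params.texture_sd
    # linear gradient in a random direction
    phi = rng.uniform(0, 2 * np.pi)
    rows, cols = np.meshgrid(np.linspace(-0.5, 0.5, s), np.linspace(-0.5, 0.5, s),
                             indexing="ij")
    img += params.gradient_amplitude * (np.cos(phi) * rows + np.sin(phi) * cols)
    # bright distractors (not part of the mask)
    for _ in range(params.distractor_count):
        cy, cx = rng.uniform(0, s, size=2)
        ry = rng.uniform(4, s / 8)
        rx = ry * rng.uniform(0.3, 1.0)
        amp = rng.uniform(20, 45)
        d = _ellipse_mask(s, cy, cx, ry, rx, rng.uniform(0, np.pi))
        img += amp * ndimage.gaussian_filter(d.astype(np.float64), 2.0)
    return img


def generate_sample(params: SynthParams, seed: int, return_debug: bool = False):
    """One synthetic patch; the mask is the exact pre-blur lesion union and
    every mask pixel is strictly darker (pre-noise) than the lesion-free
    render of the same scene."""
    params.validate()
    rng = np.random.default_rng(seed)
    s = params.size
    clean = render_background(params, rng)

    n_lo, n_hi = params.lesion_count
    n_lesions = int(rng.integers(n_lo, n_hi + 1))
    mask = np.zeros((s, s), dtype=bool)
    img = clean.copy()
    r_lo, r_hi = params.lesion_radius
    for _ in range(n_lesions):
        ry = rng.uniform(r_lo, r_hi)
        rx = ry * rng.uniform(*params.lesion_aspect)
        margin = max(ry, rx)
        cy = rng.uniform(margin, s - margin)
        cx = rng.uniform(margin, s - margin)
        theta = rng.uniform(0, np.pi)
        lesion = _ellipse_mask(s, cy, cx, ry, rx, theta)
        mask |= lesion
        contrast = rng.uniform(*params.lesion_contrast)
        sigma = rng.uniform(*params.edge_blur_sigma)
        profile = ndimage.gaussian_filter(lesion.astype(np.float64), sigma)
        img -= contrast * 255.0 * profile

    pre_noise = img.copy()
    img += rng.normal(0.0, params.noise_sd, size=(s, s))
    sample = ImageSample(
        image=np.clip(np.round(img), 0, 255).astype(np.uint8),
        mask=mask.astype(np.uint8),
        source_id=f"synth_{seed:08d}",
        lineage=f"synth(seed={seed})",
        seed=seed)
    if return_debug:
        return sample, {"lesion_free": clean, "pre_noise": pre_noise}
    return sample


def generate_samples(n: int, params: SynthParams, seed: int = 0) -> list[ImageSample]:
    """``n`` in-memory samples with per-sample seeds derived from ``seed``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n) % (2 ** 31)
    samples = []
    for i, cs in enumerate(child_seeds):
        s = generate_sample(params, int(cs))
        s.source_id = f"synth_{i:04d}_{int(cs):08d}"
        samples.append(s)
    return samples


def generate_dataset(n: int, params: SynthParams, seed: int, out_dir,
                     force: bool = False) -> list[ImageSample]:
    """Write ``n`` samples as images/ + masks/ PNG pairs plus manifest.json.

    Refuses a non-empty target directory unless ``force``.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
    samples = generate_samples(n, params, seed)
    save_pairs(samples, out_dir / "images", out_dir / "masks")
    manifest = {
        "n": n, "seed": seed, "params": asdict(params),
        "ids": [s.source_id for s in samples],
        "sample_seeds": [s.seed for s in samples],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return samples
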