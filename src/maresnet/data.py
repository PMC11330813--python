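"""Paired image/mask I/O, dataset splitting and geometric augmentation.

Images are 8-bit grayscale PNG (JPEG readable), masks are PNG with 0/255
values binarised to {0, 1} on load.  Augmentation applies one sampled
geometric transform — horizontal flip, rotation, isotropic scaling,
translation, grid-based elastic deformation — identically to image
(bilinear, reflect border) and mask (nearest, zero border, re-binarised).
Augment *after* splitting: copies inherit the source's split assignment, so
no augmented view of a test image can leak into training.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


@dataclass
class ImageSample:
    """One grayscale image paired with its binary lesion mask."""

    image: np.ndarray  # uint8, (H, W)
    mask: np.ndarray   # uint8 in {0, 1}, (H, W)
    source_id: str
    lineage: str = "original"
    seed: int = 0

    def validate(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"{self.source_id}: image shape {self.image.shape} != mask "
                f"shape {self.mask.shape}")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{self.source_id}: mask not binary, values {vals[:5]}")


def _load_gray(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def load_pairs(image_dir, mask_dir) -> list[ImageSample]:
    """Load matched image/mask pairs; filenames (stems) must correspond."""
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    exts = (".png", ".jpg", ".jpeg")
    images = {p.stem: p for p in sorted(image_dir.iterdir())
              if p.suffix.lower() in exts}
    masks = {p.stem: p for p in sorted(mask_dir.iterdir())
             if p.suffix.lower() == ".png"}
    orphan_img = sorted(set(images) - set(masks))
    orphan_msk = sorted(set(masks) - set(images))
    if orphan_img or orphan_msk:
        raise FileNotFoundError(
            f"unmatched files — images without masks: {orphan_img}; "
            f"masks without images: {orphan_msk}")
    samples = []
    for stem in sorted(images):
        img = _load_gray(images[stem])
        msk = (_load_gray(masks[stem]) > 127).astype(np.uint8)
        s = ImageSample(img, msk, source_id=stem)
        s.validate()
        samples.append(s)
    return samples


def save_pairs(samples: list[ImageSample], image_dir, mask_dir) -> None:
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    image_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        Image.fromarray(s.image).save(image_dir / f"{s.source_id}.png")
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(
            mask_dir / f"{s.source_id}.png")


# -- splitting ----------------------------------------------------------------

@dataclass
class SplitManifest:
    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int
    ratios: tuple[float, float, float]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def load(cls, path) -> "SplitManifest":
        d = json.loads(Path(path).read_text())
        d["ratios"] = tuple(d["ratios"])
        return cls(**d)

    def split_of(self, sample_id: str) -> str:
        """Split containing ``sample_id``; augmented copies named
        '<source>__augN' inherit their source's split."""
        source = sample_id.split("__aug")[0]
        for name in ("train", "validation", "test"):
            if source in set(getattr(self, name)):
                return name
        raise KeyError(f"{sample_id} (source {source}) not in manifest")


def split_dataset(samples, ratios=(0.6, 0.2, 0.2), seed: int = 0) -> SplitManifest:
    """Seeded shuffle then contiguous partition into train/validation/test.

    Validation and test sizes are ``floor(n * ratio)``; the remainder goes to
    train.  Deterministic for a fixed seed.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios) or abs(sum(ratios) - 1) > 1e-9:
        raise ValueError(f"ratios must be 3 non-negative fractions summing to 1, "
                         f"got {ratios}")
    ids = [s if isinstance(s, str) else s.source_id for s in samples]
    if len(ids) < 3:
        raise ValueError(f"need at least 3 samples to split, got {len(ids)}")
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_val = math.floor(n * ratios[1])
    n_test = math.floor(n * ratios[2])
    n_train = n - n_val - n_test
    return SplitManifest(
        train=shuffled[:n_train],
        validation=shuffled[n_train:n_train + n_val],
        test=shuffled[n_train + n_val:],
        seed=seed, ratios=ratios)


# -- augmentation -------------------------------------------------------------

@dataclass
class AugmentationSpec:
    """Geometric augmentation ranges.

    Defaults (flip p=0.5, rotation +-15 deg, scale 0.9-1.1, translation
    +-10%, elastic grid 32 px with 8 px magnitude, 2 copies per original)
    triple a dataset when originals are retained, the expansion regime the
    reference data layout describes (1535 -> ~4600).
    """

    flip_prob: float = 0.5
    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_frac: float = 0.10
    elastic_spacing: int = 32
    elastic_magnitude: float = 8.0
    copies: int = 2

    def validate(self) -> None:
        if not (0 <= self.flip_prob <= 1):
            raise ValueError("flip_prob must be in [0, 1]")
        if (self.rotation_deg < 0 or self.translation_frac < 0
                or self.elastic_magnitude < 0 or self.copies < 0):
            raise ValueError("ranges must be non-negative")
        if self.scale_range[0] > self.scale_range[1] or self.scale_range[0] <= 0:
            raise ValueError(f"bad scale_range {self.scale_range}")


def _sample_transform(spec: AugmentationSpec, rng: np.random.Generator) -> dict:
    return {
        "flip": bool(rng.random() < spec.flip_prob),
        "rot": float(rng.uniform(-spec.rotation_deg, spec.rotation_deg)),
        "scale": float(rng.uniform(*spec.scale_range)),
        "shift": (float(rng.uniform(-spec.translation_frac, spec.translation_frac)),
                  float(rng.uniform(-spec.translation_frac, spec.translation_frac))),
    }


def _warp_coords(shape, t: dict, spec: AugmentationSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Output-pixel -> input-pixel sampling coordinates for the composed
    transform (inverse affine, then additive elastic displacement)."""
    h, w = shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dy, dx = t["shift"][0] * h, t["shift"][1] * w
    # forward map: p_out = c + s * R(theta) * F * (p_in - c) + shift
    theta = math.radians(t["rot"])
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    ry = (rows - cy - dy) / t["scale"]
    rx = (cols - cx - dx) / t["scale"]
    # inverse rotation
    iy = cos_t * ry + sin_t * rx
    ix = -sin_t * ry + cos_t * rx
    if t["flip"]:
        ix = -ix
    coords = np.stack([iy + cy, ix + cx])
    if spec.elastic_magnitude > 0 and spec.elastic_spacing > 0:
        grid = (max(2, h // spec.elastic_spacing + 1),
                max(2, w // spec.elastic_spacing + 1))
        for axis in range(2):
            coarse = rng.normal(0.0, spec.elastic_magnitude, size=grid)
            fine = ndimage.zoom(coarse, (h / grid[0], w / grid[1]), order=1)
            coords[axis] += fine[:h, :w]
    return coords


def augment(sample: ImageSample, spec: AugmentationSpec,
            seed: int = 0) -> list[ImageSample]:
    """Produce ``spec.copies`` deterministically transformed copies.

    Each copy applies one sampled flip/rotation/scale/translation plus
    elastic deformation; image resampled bilinearly with reflect padding,
    mask with nearest neighbour and zero padding, then re-binarised.
    Deterministic per (seed, copy index).
    """
    spec.validate()
    sample.validate()
    out = []
    for i in range(spec.copies):
        rng = np.random.default_rng([seed, i])
        t = _sample_transform(spec, rng)
        coords = _warp_coords(sample.image.shape, t, spec, rng)
        img = ndimage.map_coordinates(sample.image.astype(np.float32), coords,
                                      order=1, mode="reflect")
        msk = ndimage.map_coordinates(sample.mask, coords, order=0,
                                      mode="constant", cval=0)
        lineage = (f"aug(seed={seed}, copy={i}, flip={t['flip']}, "
                   f"rot={t['rot']:.2f}deg, scale={t['scale']:.3f}, "
                   f"shift=({t['shift'][0]:.3f}, {t['shift'][1]:.3f}))")
        out.append(ImageSample(
            image=np.clip(np.round(img), 0, 255).astype(np.uint8),
            mask=(msk > 0).astype(np.uint8),
            source_id=f"{sample.source_id}__aug{i}",
            lineage=lineage, seed=seed))
    return out


def augment_dataset(samples: list[ImageSample], spec: AugmentationSpec,
                    seed: int = 0) -> list[ImageSample]:
    """Originals plus ``copies`` augmented views of each (sub-seeded per
    sample so the result is order-independent and reproducible)."""
    out = list(samples)
    for j, s in enumerate(samples):
        out.extend(augment(s, spec, seed=seed + j))
    return out
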