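"""Synthetic thermogram phantoms with ground truth.

Breast thermograms show a smooth warm background (body-surface temperature
gradients), optional hyperthermic lesion hot spots (tumor tissue runs warmer
than its surround), mild vignetting toward the image border, and sensor
noise.  The generator emulates exactly these ingredients:

* background — mean level plus a sum of 2-4 low-frequency cosine modes with
  seeded random phases and orientations;
* lesions — isotropic Gaussian bumps, each with a center, a radius (the
  Gaussian sigma, in pixels) and a positive peak intensity delta;
* vignette — radial quadratic darkening;
* noise — additive white Gaussian noise, then quantization to the requested
  bit depth.

The ground-truth mask marks pixels where the noiseless lesion contribution
exceeds half of that lesion's peak — for a Gaussian bump a disk of radius
``radius * sqrt(2 ln 2)``.  The label is "abnormal" iff at least one lesion
is present.  Everything is driven by one integer seed; the same spec always
produces bit-identical images.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import GrayImage
from .segmentation import BinaryMask

__all__ = ["Lesion", "PhantomSpec", "generate_phantom", "generate_cohort", "half_max_radius"]

LABEL_NORMAL = "normal"
LABEL_ABNORMAL = "abnormal"


@dataclass(frozen=True)
class Lesion:
    """One hyperthermic hot spot: Gaussian bump with positive peak delta."""

    center: tuple[float, float]  # (row, col)
    radius: float  # Gaussian sigma in pixels
    peak_delta: float

    def __post_init__(self):
        if self.peak_delta <= 0:
            raise ValueError("lesions must be hyperthermic: peak_delta > 0")
        if self.radius <= 0:
            raise ValueError("lesion radius must be positive")


def half_max_radius(radius: float) -> float:
    """Radius of the half-maximum level set of a Gaussian bump with sigma=radius."""
    return radius * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PhantomSpec:
    image_size: tuple[int, int] = (96, 96)
    background_level: float = 120.0
    gradient_amplitude: float = 20.0
    lesions: tuple[Lesion, ...] = ()
    noise_sigma: float = 10.0
    vignette_strength: float = 10.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError("image must be at least 8x8")
        if self.noise_sigma < 0 or self.vignette_strength < 0:
            raise ValueError("noise_sigma and vignette_strength must be >= 0")
        for les in self.lesions:
            r, c = les.center
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"lesion center {les.center} outside image {self.image_size}")


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, BinaryMask, str]:
    """Render one phantom: (image, ground-truth mask, label)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    ry = rows / h
    cx = cols / w

    n_modes = int(rng.integers(2, 5))
    background = np.full((h, w), spec.background_level)
    for _ in range(n_modes):
        freq = rng.uniform(0.5, 1.5)
        theta = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2 * np.pi)
        amp = spec.gradient_amplitude / n_modes
        background += amp * np.cos(2 * np.pi * freq * (ry * np.cos(theta) + cx * np.sin(theta)) + phase)

    r2 = (ry - 0.5) ** 2 + (cx - 0.5) ** 2
    vignette = -spec.vignette_strength * r2 / 0.5

    lesion_field = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=np.uint8)
    for les in spec.lesions:
        d2 = (rows - les.center[0]) ** 2 + (cols - les.center[1]) ** 2
        bump = les.peak_delta * np.exp(-d2 / (2.0 * les.radius**2))
        lesion_field += bump
        mask |= (bump > les.peak_delta / 2.0).astype(np.uint8)

    noise = rng.normal(0.0, spec.noise_sigma, size=(h, w)) if spec.noise_sigma > 0 else 0.0
    max_level = (1 << spec.bit_depth) - 1
    raw = background + vignette + lesion_field + noise
    pixels = np.clip(np.rint(raw), 0, max_level).astype(np.int64)
    label = LABEL_ABNORMAL if spec.lesions else LABEL_NORMAL
    return GrayImage(pixels, spec.bit_depth), BinaryMask(mask), label


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges for per-image phantom randomization."""

    n_lesions: tuple[int, int] = (1, 2)
    lesion_radius: tuple[float, float] = (5.0, 10.0)
    peak_delta: tuple[float, float] = (50.0, 70.0)
    margin: float = 16.0  # keep lesion centers this far from the border


def _child_seed(master_seed: int, index: int) -> int:
    digest = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def sample_spec(
    label: str,
    seed: int,
    image_size: tuple[int, int] = (96, 96),
    noise_sigma: float = 10.0,
    ranges: CohortRanges | None = None,
) -> PhantomSpec:
    """Draw one phantom spec for the requested class."""
    if ranges is None:
        ranges = CohortRanges()
    rng = np.random.default_rng(seed)
    lesions: list[Lesion] = []
    if label == LABEL_ABNORMAL:
        h, w = image_size
        m = ranges.margin
        k = int(rng.integers(ranges.n_lesions[0], ranges.n_lesions[1] + 1))
        for _ in range(k):
            lesions.append(
                Lesion(
                    center=(rng.uniform(m, h - m), rng.uniform(m, w - m)),
                    radius=rng.uniform(*ranges.lesion_radius),
                    peak_delta=rng.uniform(*ranges.peak_delta),
                )
            )
    return PhantomSpec(
        image_size=image_size,
        lesions=tuple(lesions),
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31)),
    )


def generate_cohort(
    n_normal: int,
    n_abnormal: int,
    out_dir: str | Path | None = None,
    seed: int = 0,
    image_size: tuple[int, int] = (96, 96),
    noise_sigma: float = 10.0,
    ranges: CohortRanges | None = None,
):
    """Generate a labelled cohort; optionally write PNGs plus a manifest CSV.

    Returns ``(manifest DataFrame, images, masks)``; when ``out_dir`` is
    given the manifest carries the written image/mask paths and is saved as
    ``manifest.csv`` alongside them.  Per-image seeds are derived from the
    master seed by hashing, so the cohort is reproducible file-for-file.
    """
    if n_normal + n_abnormal < 2:
        raise ValueError("cohort needs at least two images")
    labels = [LABEL_NORMAL] * n_normal + [LABEL_ABNORMAL] * n_abnormal
    images, masks, rows = [], [], []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i, label in enumerate(labels):
        spec = sample_spec(label, _child_seed(seed, i), image_size, noise_sigma, ranges)
        img, mask, lab = generate_phantom(spec)
        images.append(img)
        masks.append(mask)
        row = {"image_path": f"img_{i:04d}.png", "mask_path": f"mask_{i:04d}.png", "label": lab}
        if out_path is not None:
            from .io import write_gray_png, write_mask_png

            write_gray_png(out_path / row["image_path"], img)
            write_mask_png(out_path / row["mask_path"], mask)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return manifest, images, masks
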