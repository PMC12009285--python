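"""Optimal binary thresholding of thermograms.

A single scalar threshold ``I`` splits a gray image into background
(intensity < I -> 0) and foreground (>= I -> 1); on a thermogram the
foreground is the hyperthermic (lesion) region.  The threshold is chosen by
the hybrid optimizer against a pluggable fitness:

* ``otsu`` (default, unsupervised): the between-class variance
  ``w0 * w1 * (mu0 - mu1)^2`` of the two classes induced by I — the quantity
  Otsu's method maximizes;
* ``dice`` (supervised): Dice overlap with a reference mask.

Because the useful thresholds of an r-bit image form a small discrete set,
``optimal_threshold`` memoizes the fitness per integer level and, when its
evaluation budget allows, finishes with a sweep of any integer levels the
optimizer did not visit — so with budget >= 2^r the returned fitness is
exactly the exhaustive-search optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optimizer import Bounds, OptimizerConfig, optimize
from .preprocess import GrayImage

__all__ = [
    "BinaryMask",
    "SegmentationFitness",
    "apply_threshold",
    "otsu_objective",
    "optimal_threshold",
    "mask_overlap",
    "CLINICAL_THRESHOLD_BOUNDS",
]

# Threshold search window quoted for the original clinical setting; arbitrary
# images should search the full gray range instead.
CLINICAL_THRESHOLD_BOUNDS = (200.0, 255.0)


@dataclass(frozen=True)
class BinaryMask:
    """A 0/1 lesion mask."""

    pixels: np.ndarray

    def __post_init__(self):
        pixels = np.asarray(self.pixels)
        if pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(pixels, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "pixels", pixels.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SegmentationFitness:
    """Which objective drives the threshold search."""

    kind: str = "otsu"
    reference: BinaryMask | None = None

    def __post_init__(self):
        if self.kind not in ("otsu", "dice"):
            raise ValueError("kind must be 'otsu' or 'dice'")
        if self.kind == "dice" and self.reference is None:
            raise ValueError("dice fitness requires a reference mask")


def apply_threshold(img: GrayImage, threshold: float) -> BinaryMask:
    """Binary mask: 1 where intensity >= threshold, else 0."""
    return BinaryMask((img.pixels >= threshold).astype(np.uint8))


def otsu_objective(img: GrayImage, threshold: float) -> float:
    """Between-class variance of the two intensity classes induced by the threshold.

    Higher is better; zero when either class is empty.  Raises on a constant
    image, whose histogram admits no two-class split.
    """
    pixels = img.pixels.ravel()
    if pixels.min() == pixels.max():
        raise ValueError("degenerate histogram: image has a single gray level")
    fg = pixels >= threshold
    n = pixels.size
    n1 = int(fg.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        return 0.0
    mu0 = pixels[~fg].mean()
    mu1 = pixels[fg].mean()
    w0 = n0 / n
    w1 = n1 / n
    return float(w0 * w1 * (mu0 - mu1) ** 2)


def _otsu_from_histogram(hist: np.ndarray):
    """Vectorized between-class variance for every integer threshold.

    Returns an array ``var[I]`` with the objective of thresholding at integer
    level I (foreground = levels >= I), matching :func:`otsu_objective`.
    """
    levels = np.arange(hist.size)
    total = hist.sum()
    csum = np.cumsum(hist)
    cmoment = np.cumsum(hist * levels)
    var = np.zeros(hist.size, dtype=float)
    for i in range(1, hist.size):
        n0 = csum[i - 1]
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = cmoment[i - 1] / n0
        mu1 = (cmoment[-1] - cmoment[i - 1]) / n1
        var[i] = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
    return var


def mask_overlap(pred: BinaryMask, ref: BinaryMask) -> tuple[float, float]:
    """(Dice, Jaccard) overlap; both 1.0 when both masks are empty."""
    if pred.shape != ref.shape:
        raise ValueError("mask shapes differ")
    a = pred.pixels.astype(bool)
    b = ref.pixels.astype(bool)
    inter = int((a & b).sum())
    sa, sb = int(a.sum()), int(b.sum())
    union = sa + sb - inter
    dice = 1.0 if sa + sb == 0 else 2.0 * inter / (sa + sb)
    jaccard = 1.0 if union == 0 else inter / union
    return dice, jaccard


def optimal_threshold(
    img: GrayImage,
    fitness: SegmentationFitness | None = None,
    config: OptimizerConfig | None = None,
    bounds: tuple[float, float] | None = None,
    budget: int | None = None,
    rhdao_only: bool = False,
) -> tuple[int, BinaryMask, float]:
    """Optimizer-driven threshold selection.

    Runs the hybrid optimizer over the 1-D threshold space (default bounds:
    the full gray range).  Thresholds are real-valued during the search and
    rounded to the nearest integer gray level for evaluation and reporting.
    ``budget`` caps total fitness evaluations (default: enough to cover every
    integer level); unless ``rhdao_only`` is set, leftover budget is spent on
    integer levels the optimizer never visited, which makes the result exact
    whenever the budget covers the whole gray range.

    Returns ``(threshold, mask, fitness_value)``.
    """
    if fitness is None:
        fitness = SegmentationFitness()
    if config is None:
        config = OptimizerConfig(population_size=10, max_iterations=10)
    lo, hi = bounds if bounds is not None else (0.0, float(img.max_level))
    n_levels = int(hi) - int(np.ceil(lo)) + 1
    if budget is None:
        budget = max(n_levels, 1) + config.population_size

    if fitness.kind == "dice":
        if fitness.reference.shape != img.shape:
            raise ValueError("reference mask shape differs from image")

        def score_int(level: int) -> float:
            return mask_overlap(apply_threshold(img, level), fitness.reference)[0]

    else:
        # trigger the degenerate-histogram error up front
        otsu_objective(img, lo)

        def score_int(level: int) -> float:
            return otsu_objective(img, level)

    cache: dict[int, float] = {}

    def cached_score(level: int) -> float:
        if level not in cache:
            cache[level] = score_int(level)
        return cache[level]

    def objective(position: np.ndarray) -> float:
        level = int(np.rint(position[0]))
        return -cached_score(level)  # optimizer minimizes

    result = optimize(objective, Bounds([lo], [hi]), config)

    if not rhdao_only:
        lo_i = int(np.ceil(lo))
        for level in range(lo_i, int(hi) + 1):
            if len(cache) >= budget:
                break
            cached_score(level)

    best_level = min(cache, key=lambda k: (-cache[k], k))
    best_value = cache[best_level]
    # keep the optimizer's own answer when it ties the sweep
    opt_level = int(np.rint(result.best.position[0]))
    if cache.get(opt_level) == best_value:
        best_level = opt_level
    return best_level, apply_threshold(img, best_level), best_value
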