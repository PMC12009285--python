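"""Stacked weighted feature pool.

The three branch vectors are combined element-wise into a single stacked
feature ``SF = W1*f1 + W2*f2 + W3*f3`` with scalar weights in [0, 1] (not
required to sum to one).  The weights themselves are tuned by the hybrid
optimizer against a caller-supplied evaluator (typically validation accuracy
of the downstream ensemble); the equal-weights baseline (1/3, 1/3, 1/3) is
injected into the initial population so the tuned result can never fall
below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extractors import FeatureSet
from .optimizer import Bounds, OptimizerConfig, optimize

__all__ = ["FusionWeights", "FusedFeature", "fuse", "optimize_fusion_weights"]


@dataclass(frozen=True)
class FusionWeights:
    w1: float
    w2: float
    w3: float

    def __post_init__(self):
        for w in (self.w1, self.w2, self.w3):
            if not 0.0 <= w <= 1.0:
                raise ValueError("fusion weights must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3])


@dataclass(frozen=True)
class FusedFeature:
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())

    def __len__(self) -> int:
        return self.values.size


def _vec(f) -> np.ndarray:
    return f.values if isinstance(f, (FeatureSet, FusedFeature)) else np.asarray(f, dtype=float).ravel()


def fuse(f1, f2, f3, weights: FusionWeights, literal_typo: bool = False) -> FusedFeature:
    """Element-wise weighted sum of the three branch vectors.

    ``literal_typo=True`` reproduces a misprint found in some descriptions of
    this scheme where the second weight multiplies the third feature set
    (``W1*f1 + W2*f3 + W3*f3``); the default pairs each weight with its own
    branch.
    """
    v1, v2, v3 = _vec(f1), _vec(f2), _vec(f3)
    if not (v1.size == v2.size == v3.size):
        raise ValueError("feature vectors must have equal length")
    if literal_typo:
        return FusedFeature(weights.w1 * v1 + weights.w2 * v3 + weights.w3 * v3)
    return FusedFeature(weights.w1 * v1 + weights.w2 * v2 + weights.w3 * v3)


def optimize_fusion_weights(
    evaluator,
    config: OptimizerConfig | None = None,
    baseline: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> tuple[FusionWeights, float]:
    """Tune the three fusion weights to maximize ``evaluator(w1, w2, w3)``.

    The evaluator must be deterministic; it is negated internally because the
    optimizer minimizes.  Returns the best weights and their evaluator score.
    The baseline point is seeded into the initial population, so the returned
    score is always >= evaluator(baseline).
    """
    if config is None:
        config = OptimizerConfig(population_size=12, max_iterations=15)

    def objective(pos: np.ndarray) -> float:
        return -float(evaluator(pos[0], pos[1], pos[2]))

    bounds = Bounds([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
    result = optimize(objective, bounds, config, initial_positions=[np.asarray(baseline)])
    w = np.clip(result.best.position, 0.0, 1.0)
    return FusionWeights(*w), -result.best.fitness
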