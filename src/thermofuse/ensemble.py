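"""Score-voting ensemble classifier with metaheuristic hyperparameter tuning.

Three lightweight feed-forward heads (one hidden layer each, seeded
differently) are trained on the same stacked fused feature; at prediction
time their per-class probability vectors are summed and the argmax taken
(ties broken toward the lowest class index).  The tunable genome mirrors the
original design: three fusion weights in [0,1], epoch count in [50,100],
hidden-neuron count in [5,255], and a categorical activation drawn from
{relu, sigmoid, tanh}; an optional segmentation-threshold gene can join the
search when a supervised segmentation fitness is configured.  The hybrid
optimizer maximizes validation accuracy over this space, with the space
midpoint injected into the initial population so the tuned configuration is
never worse than it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .fusion import FusionWeights, fuse
from .optimizer import Bounds, OptimizerConfig, optimize

__all__ = [
    "HyperparameterSpace",
    "Hyperparameters",
    "ClassifierHead",
    "EnsemblePipeline",
    "fit_heads",
    "decide",
    "accuracy_fitness",
    "optimize_hyperparameters",
]

ACTIVATIONS = ("relu", "sigmoid", "tanh")
_SKLEARN_ACT = {"relu": "relu", "sigmoid": "logistic", "tanh": "tanh"}


@dataclass(frozen=True)
class HyperparameterSpace:
    """Search bounds of the tunable genome."""

    epochs_range: tuple[int, int] = (50, 100)
    hidden_range: tuple[int, int] = (5, 255)
    activations: tuple[str, ...] = ACTIVATIONS
    weight_range: tuple[float, float] = (0.0, 1.0)
    threshold_range: tuple[float, float] | None = None

    def bounds(self) -> Bounds:
        lo = [self.weight_range[0]] * 3 + [self.epochs_range[0], self.hidden_range[0], 0.0]
        hi = [self.weight_range[1]] * 3 + [self.epochs_range[1], self.hidden_range[1], float(len(self.activations))]
        if self.threshold_range is not None:
            lo.append(self.threshold_range[0])
            hi.append(self.threshold_range[1])
        return Bounds(lo, hi)

    def midpoint(self) -> np.ndarray:
        b = self.bounds()
        return (b.lower + b.upper) / 2.0

    def decode(self, genome: np.ndarray) -> "Hyperparameters":
        """Round integer genes, floor the categorical gene, clip to range."""
        w = np.clip(genome[:3], *self.weight_range)
        epochs = int(np.clip(np.rint(genome[3]), *self.epochs_range))
        hidden = int(np.clip(np.rint(genome[4]), *self.hidden_range))
        act_idx = int(np.clip(np.floor(genome[5]), 0, len(self.activations) - 1))
        threshold = None
        if self.threshold_range is not None and genome.size > 6:
            threshold = float(np.clip(genome[6], *self.threshold_range))
        return Hyperparameters(
            weights=FusionWeights(*w),
            epochs=epochs,
            hidden_neurons=hidden,
            activation=self.activations[act_idx],
            threshold=threshold,
        )


@dataclass(frozen=True)
class Hyperparameters:
    weights: FusionWeights
    epochs: int = 75
    hidden_neurons: int = 32
    activation: str = "relu"
    threshold: float | None = None

    def __post_init__(self):
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")


class ClassifierHead:
    """One feed-forward head: a single hidden layer trained for a fixed budget.

    Wraps a scikit-learn MLP with the genome's hidden width, activation and
    epoch cap; deterministic given its seed.  ``predict_scores`` returns
    per-class probabilities summing to one per sample.
    """

    def __init__(self, tag: str, hidden_neurons: int, activation: str, epochs: int, seed: int):
        self.tag = tag
        self.hidden_neurons = hidden_neurons
        self.activation = activation
        self.epochs = epochs
        self.seed = seed
        self._model = MLPClassifier(
            hidden_layer_sizes=(hidden_neurons,),
            activation=_SKLEARN_ACT[activation],
            solver="lbfgs",
            max_iter=epochs,
            random_state=seed,
        )

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "ClassifierHead":
        if len(features) == 0:
            raise ValueError("empty training set")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._model.fit(features, labels)
        return self

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        return self._model.predict_proba(features)

    @property
    def classes_(self) -> np.ndarray:
        return self._model.classes_


def fit_heads(
    train_features: np.ndarray,
    labels: np.ndarray,
    hp: Hyperparameters,
    seed: int = 0,
) -> list[ClassifierHead]:
    """Train the three heads on the fused feature matrix with derived seeds."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 1 or len(train_features) == 0:
        raise ValueError("empty training set")
    heads = []
    for i, tag in enumerate(("vgg-like", "resnet-like", "densenet-like")):
        head = ClassifierHead(tag, hp.hidden_neurons, hp.activation, hp.epochs, seed=(seed * 7919 + i + 1) % (2**32))
        heads.append(head.fit(train_features, labels))
    return heads


def decide(head_scores) -> tuple[np.ndarray, np.ndarray]:
    """Higher-score decision rule.

    ``head_scores`` is a sequence of per-head score arrays, each of shape
    (n_samples, n_classes) or (n_classes,).  Scores are summed element-wise
    across heads and the predicted class index is the argmax (lowest index
    wins ties).  Returns (predicted class indices, aggregated scores).
    """
    arrays = [np.atleast_2d(np.asarray(s, dtype=float)) for s in head_scores]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("heads report different class counts")
    agg = np.sum(arrays, axis=0)
    return np.argmax(agg, axis=1), agg


def accuracy_fitness(pred, truth) -> float:
    """Fraction of correct decisions: (TP+TN)/total in the binary case."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if truth.size == 0:
        raise ValueError("empty validation set")
    return float(np.mean(pred == truth))


@dataclass
class EnsemblePipeline:
    """Fusion + three heads + score voting, behind fit/predict."""

    hp: Hyperparameters
    seed: int = 0
    heads: list = field(default_factory=list)

    def fit(self, f1: np.ndarray, f2: np.ndarray, f3: np.ndarray, labels) -> "EnsemblePipeline":
        sf = self._fuse_matrix(f1, f2, f3)
        self.heads = fit_heads(sf, np.asarray(labels), self.hp, self.seed)
        return self

    def _fuse_matrix(self, f1, f2, f3) -> np.ndarray:
        w = self.hp.weights
        return np.stack([fuse(a, b, c, w).values for a, b, c in zip(f1, f2, f3)])

    def predict(self, f1, f2, f3) -> np.ndarray:
        idx, _ = self.decision(f1, f2, f3)
        return self.heads[0].classes_[idx]

    def decision(self, f1, f2, f3):
        if not self.heads:
            raise RuntimeError("pipeline is not fitted")
        sf = self._fuse_matrix(f1, f2, f3)
        scores = [h.predict_scores(sf) for h in self.heads]
        return decide(scores)

    def accuracy(self, f1, f2, f3, labels) -> float:
        return accuracy_fitness(self.predict(f1, f2, f3), np.asarray(labels))


def optimize_hyperparameters(
    train: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    space: HyperparameterSpace | None = None,
    config: OptimizerConfig | None = None,
) -> tuple[Hyperparameters, EnsemblePipeline, float]:
    """Tune the genome to maximize ensemble accuracy on the validation split.

    ``train`` and ``validation`` are (f1, f2, f3, labels) tuples of per-image
    branch feature matrices.  Returns the best hyperparameters, the pipeline
    refit under them, and its validation accuracy.
    """
    if space is None:
        space = HyperparameterSpace()
    if config is None:
        config = OptimizerConfig(population_size=6, max_iterations=5)
    f1t, f2t, f3t, yt = train
    f1v, f2v, f3v, yv = validation
    if np.unique(yt).size < 2:
        raise ValueError("training labels must contain at least two classes")

    def objective(genome: np.ndarray) -> float:
        hp = space.decode(genome)
        pipe = EnsemblePipeline(hp, seed=config.seed).fit(f1t, f2t, f3t, yt)
        return -pipe.accuracy(f1v, f2v, f3v, yv)

    result = optimize(objective, space.bounds(), config, initial_positions=[space.midpoint()])
    best_hp = space.decode(result.best.position)
    pipeline = EnsemblePipeline(best_hp, seed=config.seed).fit(f1t, f2t, f3t, yt)
    return best_hp, pipeline, -result.best.fitness
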