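"""Ensemble heads, score-voting decision rule, hyperparameter tuning."""

import numpy as np
import pytest

from thermofuse import (
    EnsemblePipeline,
    FusionWeights,
    HyperparameterSpace,
    Hyperparameters,
    OptimizerConfig,
    accuracy_fitness,
    decide,
    fit_heads,
    optimize_hyperparameters,
)


@pytest.fixture
def separable_data():
    """Two linearly separable classes in branch-feature form."""
    rng = np.random.default_rng(5)
    n = 40
    labels = np.repeat([0, 1], n // 2)
    shift = labels[:, None] * 3.0
    f1 = rng.normal(0, 0.4, (n, 16)) + shift
    f2 = rng.normal(0, 0.4, (n, 16)) + shift
    f3 = rng.normal(0, 0.4, (n, 16)) + shift
    return f1, f2, f3, labels


@pytest.fixture
def default_hp():
    return Hyperparameters(weights=FusionWeights(1 / 3, 1 / 3, 1 / 3), epochs=60, hidden_neurons=16)


class TestHeads:
    def test_separable_classes_fit_cleanly(self, separable_data, default_hp):
        f1, f2, f3, y = separable_data
        sf = (f1 + f2 + f3) / 3
        heads = fit_heads(sf, y, default_hp, seed=0)
        assert len(heads) == 3
        for head in heads:
            pred = head.classes_[np.argmax(head.predict_scores(sf), axis=1)]
            assert np.mean(pred == y) >= 0.95

    def test_scores_normalize_per_sample(self, separable_data, default_hp):
        f1, f2, f3, y = separable_data
        heads = fit_heads(f1, y, default_hp, seed=1)
        scores = heads[0].predict_scores(f1)
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-9)

    def test_one_sample_per_class_degenerate_fit(self, default_hp):
        features = np.array([[0.0, 0.0], [5.0, 5.0]])
        labels = np.array([0, 1])
        heads = fit_heads(features, labels, default_hp, seed=0)
        pred = heads[0].classes_[np.argmax(heads[0].predict_scores(features), axis=1)]
        assert np.array_equal(pred, labels)

    def test_same_seed_reproduces_head_parameters(self, separable_data, default_hp):
        f1, _, _, y = separable_data
        h1 = fit_heads(f1, y, default_hp, seed=3)
        h2 = fit_heads(f1, y, default_hp, seed=3)
        for a, b in zip(h1, h2):
            for wa, wb in zip(a._model.coefs_, b._model.coefs_):
                assert np.array_equal(wa, wb)

    def test_empty_training_set_rejected(self, default_hp):
        with pytest.raises(ValueError):
            fit_heads(np.zeros((0, 4)), np.array([]), default_hp)


class TestDecide:
    def test_unanimous_agreement(self):
        idx, agg = decide([[0.1, 0.9], [0.1, 0.9], [0.1, 0.9]])
        assert idx[0] == 1

    def test_score_sum_arithmetic(self):
        idx, agg = decide([[0.9, 0.1], [0.4, 0.6], [0.45, 0.55]])
        assert np.allclose(agg, [[1.75, 1.25]])
        assert idx[0] == 0

    def test_exact_tie_goes_to_lowest_class(self):
        idx, _ = decide([[0.5, 0.5], [0.5, 0.5], [0.5, 0.5]])
        assert idx[0] == 0

    def test_equals_majority_vote_on_agreement(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            winner = rng.integers(0, 3)
            scores = []
            for _h in range(3):
                s = rng.dirichlet(np.ones(3))
                s[winner] = s.max() + 0.1
                scores.append(s / s.sum())
            idx, _ = decide(scores)
            assert idx[0] == winner

    def test_mismatched_class_counts_rejected(self):
        with pytest.raises(ValueError):
            decide([[0.5, 0.5], [0.3, 0.3, 0.4], [0.5, 0.5]])


class TestAccuracyFitness:
    @pytest.mark.parametrize(
        "pred,truth,expected",
        [([1, 1], [1, 1], 1.0), ([0, 0], [1, 1], 0.0), ([1] * 14 + [0] * 6, [1] * 20, 0.70)],
    )
    def test_counting(self, pred, truth, expected):
        assert accuracy_fitness(pred, truth) == pytest.approx(expected)

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError):
            accuracy_fitness([], [])


class TestHyperparameterSearch:
    def test_decode_rounds_and_floors_genes(self):
        space = HyperparameterSpace()
        hp = space.decode(np.array([0.2, 0.9, 0.4, 72.6, 100.2, 2.7]))
        assert hp.epochs == 73
        assert hp.hidden_neurons == 100
        assert hp.activation == "tanh"  # floor(2.7) = 2

    def test_tuning_on_separable_data(self, separable_data):
        f1, f2, f3, y = separable_data
        train = (f1[::2], f2[::2], f3[::2], y[::2])
        val = (f1[1::2], f2[1::2], f3[1::2], y[1::2])
        cfg = OptimizerConfig(population_size=4, max_iterations=2, min_seeds=1, max_seeds=2, seed=0)
        hp, pipeline, acc = optimize_hyperparameters(train, val, config=cfg)
        assert acc >= 0.95
        space = HyperparameterSpace()
        assert space.epochs_range[0] <= hp.epochs <= space.epochs_range[1]
        assert space.hidden_range[0] <= hp.hidden_neurons <= space.hidden_range[1]

    def test_tuned_at_least_as_good_as_midpoint(self, separable_data):
        f1, f2, f3, y = separable_data
        train = (f1[::2], f2[::2], f3[::2], y[::2])
        val = (f1[1::2], f2[1::2], f3[1::2], y[1::2])
        space = HyperparameterSpace()
        cfg = OptimizerConfig(population_size=4, max_iterations=2, min_seeds=1, max_seeds=2, seed=1)
        _, _, acc = optimize_hyperparameters(train, val, space, cfg)
        mid = space.decode(space.midpoint())
        baseline = EnsemblePipeline(mid, seed=cfg.seed).fit(*train).accuracy(*val)
        assert acc >= baseline - 1e-12

    def test_collapsed_space_returns_single_point(self, separable_data):
        f1, f2, f3, y = separable_data
        space = HyperparameterSpace(
            epochs_range=(60, 61), hidden_range=(8, 9), activations=("relu",), weight_range=(0.49, 0.5)
        )
        cfg = OptimizerConfig(population_size=3, max_iterations=2, min_seeds=1, max_seeds=2, seed=0)
        hp, _, _ = optimize_hyperparameters((f1, f2, f3, y), (f1, f2, f3, y), space, cfg)
        assert hp.activation == "relu"
        assert 60 <= hp.epochs <= 61
        assert 8 <= hp.hidden_neurons <= 9

    def test_single_class_rejected(self, separable_data):
        f1, f2, f3, _ = separable_data
        y = np.zeros(len(f1), dtype=int)
        with pytest.raises(ValueError):
            optimize_hyperparameters((f1, f2, f3, y), (f1, f2, f3, y))

    def test_pipeline_determinism(self, separable_data, default_hp):
        f1, f2, f3, y = separable_data
        p1 = EnsemblePipeline(default_hp, seed=4).fit(f1, f2, f3, y)
        p2 = EnsemblePipeline(default_hp, seed=4).fit(f1, f2, f3, y)
        assert np.array_equal(p1.predict(f1, f2, f3), p2.predict(f1, f2, f3))
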