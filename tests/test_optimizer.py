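"""Unit and property tests of the hybrid optimizer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermofuse import Bounds, Candidate, OptimizerConfig, optimize
from thermofuse.optimizer import (
    circle_radius,
    compute_angle,
    da_assistant_radius,
    da_core_radius,
    da_seed_count,
    perturb_angle,
    rhso_leader_update,
    rhso_member_update,
    route_update,
    RADIUS_FLOOR_FRACTION,
)


class TestAngleAndRouting:
    @pytest.mark.parametrize(
        "cf,bf,wf,expected",
        [
            (1.0, 1.0, 5.0, 0.0),
            (5.0, 1.0, 5.0, 360.0),
            (3.0, 1.0, 5.0, 180.0),
            (2.0, 2.0, 2.0, 0.0),  # degenerate population
        ],
    )
    def test_angle_values(self, cf, bf, wf, expected):
        assert compute_angle(cf, bf, wf) == expected

    def test_angle_rejects_non_finite(self):
        with pytest.raises(ValueError):
            compute_angle(float("nan"), 0.0, 1.0)
        with pytest.raises(ValueError):
            compute_angle(1.0, float("inf"), 2.0)

    @pytest.mark.parametrize("angle,branch", [(360.0, "rhso"), (0.0, "da"), (180.0, "da")])
    def test_routing_boundary(self, angle, branch):
        """RHSO handles strictly angle > 180; 180 itself goes to the dandelion side."""
        assert route_update(angle) == branch

    def test_routing_exhaustive_predicate(self):
        for angle in np.linspace(0, 360, 721):
            assert route_update(angle) == ("rhso" if angle > 180 else "da")

    @given(st.floats(0, 360), st.floats(-500, 500))
    @settings(max_examples=200, derandomize=True)
    def test_perturb_angle_clamps(self, angle, delta):
        class _R:
            def uniform(self, lo, hi):
                return delta

        assert 0.0 <= perturb_angle(angle, _R()) <= 360.0

    def test_perturb_identity_and_saturation(self, forced_rng):
        assert perturb_angle(100.0, forced_rng([0.0])) == 100.0
        assert perturb_angle(360.0, forced_rng([30.0])) == 360.0
        assert perturb_angle(0.0, forced_rng([-30.0])) == 0.0


class TestRhsoUpdates:
    bounds = Bounds([-5.0, -5.0], [5.0, 5.0])

    @staticmethod
    def sphere(p):
        return float(np.sum(p**2))

    def test_leader_identity_when_l1_is_one(self, forced_rng):
        leader = Candidate(np.array([2.0, -1.0]), self.sphere(np.array([2.0, -1.0])))
        out = rhso_leader_update(leader, self.sphere, self.bounds, forced_rng([1.0]))
        assert np.allclose(out.position, leader.position)

    def test_leader_l1_zero_goes_to_origin(self, forced_rng):
        leader = Candidate(np.array([2.0, -1.0]), self.sphere(np.array([2.0, -1.0])))
        out = rhso_leader_update(leader, self.sphere, self.bounds, forced_rng([0.0]))
        assert np.allclose(out.position, 0.0)

    def test_greedy_acceptance_keeps_better_incumbent(self, forced_rng):
        # maximize distance from origin: contraction proposals are worse
        def anti_sphere(p):
            return -float(np.sum(p**2))

        member = Candidate(np.array([4.0, 4.0]), anti_sphere(np.array([4.0, 4.0])))
        out = rhso_member_update(member, anti_sphere, self.bounds, forced_rng([0.5, 90.0]))
        assert np.allclose(out.position, member.position)
        assert out.fitness == member.fitness

    def test_member_circle_zero_is_identity(self, forced_rng):
        member = Candidate(np.array([1.0, 2.0]), self.sphere(np.array([1.0, 2.0])))
        out = rhso_member_update(member, self.sphere, self.bounds, forced_rng([0.0, 45.0]))
        assert np.allclose(out.position, member.position)

    def test_member_circle_one_reaches_origin(self, forced_rng):
        member = Candidate(np.array([1.0, 2.0]), self.sphere(np.array([1.0, 2.0])))
        out = rhso_member_update(member, self.sphere, self.bounds, forced_rng([1.0, 45.0]))
        assert np.allclose(out.position, 0.0)

    def test_circle_equals_radius_over_angle_grid(self):
        for a in np.linspace(0, 2 * math.pi, 37):
            assert circle_radius(0.5, a) == pytest.approx(0.5, abs=1e-12)


class TestDandelionRules:
    bounds = Bounds([0.0], [255.0])

    @pytest.mark.parametrize(
        "h,hmin,hmax,expected",
        [(0.0, 0.0, 10.0, 10), (10.0, 0.0, 10.0, 2), (5.0, 0.0, 10.0, 5)],
    )
    def test_seed_count(self, h, hmin, hmax, expected):
        assert da_seed_count(h, hmin, hmax, min_seeds=2, max_seeds=10) == expected

    def test_seed_count_degenerate_fitness_spread(self):
        assert da_seed_count(3.0, 3.0, 3.0, min_seeds=2, max_seeds=10) == 10

    def test_assistant_radius_first_iteration_is_diameter(self):
        assert da_assistant_radius(None, 0.5, 0.0, 0.0, True, self.bounds) == 255.0

    def test_assistant_radius_floor(self):
        r = da_assistant_radius(10.0, 0.0, 2.0, 2.0, False, self.bounds)
        assert r == pytest.approx(RADIUS_FLOOR_FRACTION * 255.0)

    def test_assistant_radius_weighted_decay(self):
        assert da_assistant_radius(10.0, 0.5, 3.0, 1.0, False, self.bounds) == pytest.approx(7.0)

    def test_core_radius_branches(self):
        b = Bounds([-5.0], [5.0])
        assert da_core_radius(None, False, True, 1.1, 0.8, b) == 10.0
        assert da_core_radius(10.0, True, False, 1.1, 0.8, b) == pytest.approx(11.0)
        assert da_core_radius(10.0, False, False, 1.1, 0.8, b) == pytest.approx(8.0)


class TestOptimize:
    def test_quadratic_1d_recovers_optimum(self):
        hits = 0
        for seed in range(20):
            res = optimize(
                lambda p: float((p[0] - 3.0) ** 2),
                Bounds([0.0], [10.0]),
                OptimizerConfig(seed=seed),
            )
            hits += abs(res.best.position[0] - 3.0) < 0.1
        assert hits >= 18

    def test_constant_fitness_routes_everything_to_dandelion(self):
        res = optimize(
            lambda p: 7.5, Bounds([0.0], [1.0]), OptimizerConfig(seed=0, max_iterations=5)
        )
        assert res.best.fitness == 7.5
        assert all(c["rhso"] == 0 for c in res.branch_counts)

    def test_history_monotone_and_deterministic(self):
        def rosenbrock2(p):
            return float((1 - p[0]) ** 2 + 100 * (p[1] - p[0] ** 2) ** 2)

        cfg = OptimizerConfig(seed=11, max_iterations=15)
        r1 = optimize(rosenbrock2, Bounds([-2, -2], [2, 2]), cfg)
        r2 = optimize(rosenbrock2, Bounds([-2, -2], [2, 2]), cfg)
        assert all(a >= b for a, b in zip(r1.history, r1.history[1:]))
        assert np.array_equal(r1.best.position, r2.best.position)
        assert r1.history == r2.history

    def test_every_evaluated_position_is_inside_bounds(self):
        bounds = Bounds([-3.0, 0.0], [1.0, 2.0])
        seen = []

        def instrumented(p):
            seen.append(p.copy())
            return float(np.sum(p**2))

        optimize(instrumented, bounds, OptimizerConfig(seed=5, max_iterations=8))
        stacked = np.stack(seen)
        assert np.all(stacked >= bounds.lower) and np.all(stacked <= bounds.upper)

    def test_mode_purity_branch_counters(self):
        f = lambda p: float(np.sum(p**2))
        b = Bounds([-1, -1], [1, 1])
        rhso = optimize(f, b, OptimizerConfig(seed=2, max_iterations=5, mode="rhso"))
        da = optimize(f, b, OptimizerConfig(seed=2, max_iterations=5, mode="da"))
        assert all(c["da"] == 0 for c in rhso.branch_counts)
        assert all(c["rhso"] == 0 for c in da.branch_counts)

    def test_non_finite_fitness_names_position(self):
        with pytest.raises(ValueError, match="non-finite"):
            optimize(lambda p: float("nan"), Bounds([0], [1]), OptimizerConfig(seed=0))

    def test_initial_positions_guarantee_elitism_floor(self):
        # objective minimized exactly at the injected point
        target = np.array([0.25, 0.75])
        f = lambda p: float(np.sum((p - target) ** 2))
        res = optimize(
            f,
            Bounds([0, 0], [1, 1]),
            OptimizerConfig(seed=3, max_iterations=2),
            initial_positions=[target],
        )
        assert res.best.fitness <= f(target) + 1e-15

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OptimizerConfig(growth_factor=1.5)
        with pytest.raises(ValueError):
            OptimizerConfig(withering_factor=0.5)
        with pytest.raises(ValueError):
            OptimizerConfig(min_seeds=5, max_seeds=2)
        with pytest.raises(ValueError):
            OptimizerConfig(mode="annealing")

    def test_history_frame_schema(self):
        res = optimize(lambda p: float(p[0] ** 2), Bounds([-1], [1]), OptimizerConfig(seed=0, max_iterations=3))
        frame = res.history_frame()
        assert list(frame.columns) == ["iteration", "best_fitness", "branch_counts_rhso", "branch_counts_da"]
        assert len(frame) == 3
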