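"""Hybrid rock-hyrax / dandelion metaheuristic (RHDAO) for bounded minimization.

The optimizer maintains a population of candidate solutions inside a box.
Each generation every candidate is assigned a normalized fitness *angle* in
[0, 360]::

    angle = 360 * (CF - BF) / (WF - BF)

where CF, BF, WF are the candidate's, the best, and the worst fitness in the
current population.  Candidates with angle > 180 (the worse half) are updated
with rock-hyrax swarm rules (leader contraction and circular-motion member
moves); the rest are updated with dandelion sowing (fitness-proportional seed
counts inside adaptive radii).  Pure-RHSO and pure-DA modes are available for
ablation.  Elitism makes the best-so-far fitness non-increasing; with a fixed
seed the run is bit-reproducible.

Minimization is the core orientation; wrap a maximization objective with
negation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Bounds",
    "Candidate",
    "OptimizerConfig",
    "OptimizeResult",
    "compute_angle",
    "route_update",
    "rhso_leader_update",
    "rhso_member_update",
    "perturb_angle",
    "da_seed_count",
    "da_assistant_radius",
    "da_core_radius",
    "optimize",
]

# Relative floor for assistant sowing radii, as a fraction of the widest
# bound span; prevents radius collapse to zero.
RADIUS_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class Bounds:
    """Axis-aligned box constraints for the search space."""

    lower: np.ndarray
    upper: np.ndarray

    def __init__(self, lower, upper):
        lower = np.atleast_1d(np.asarray(lower, dtype=float))
        upper = np.atleast_1d(np.asarray(upper, dtype=float))
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if lower.size < 1:
            raise ValueError("dimension must be >= 1")
        if not np.all(lower < upper):
            raise ValueError("lower must be strictly below upper element-wise")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower, self.upper)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dim))


@dataclass
class Candidate:
    """A point in the search space together with its (minimization) fitness."""

    position: np.ndarray
    fitness: float

    def copy(self) -> "Candidate":
        return Candidate(self.position.copy(), self.fitness)


@dataclass
class OptimizerConfig:
    """Run-time knobs of the optimizer.

    ``growth_factor`` and ``withering_factor`` scale the core dandelion's
    sowing radius after an improving / stagnant generation and must lie in
    [1, 1.1] and [0.8, 1) respectively.
    """

    population_size: int = 30
    max_iterations: int = 25
    seed: int = 0
    min_seeds: int = 2
    max_seeds: int = 10
    growth_factor: float = 1.05
    withering_factor: float = 0.9
    mode: str = "rhdao"
    recentered: bool = False

    def __post_init__(self):
        if self.population_size < 1 or self.max_iterations < 1:
            raise ValueError("population_size and max_iterations must be positive")
        if not (1 <= self.min_seeds <= self.max_seeds):
            raise ValueError("need max_seeds >= min_seeds >= 1")
        if not (1.0 <= self.growth_factor <= 1.1):
            raise ValueError("growth_factor must be in [1, 1.1]")
        if not (0.8 <= self.withering_factor < 1.0):
            raise ValueError("withering_factor must be in [0.8, 1)")
        if self.mode not in ("rhdao", "rhso", "da"):
            raise ValueError("mode must be one of rhdao|rhso|da")


@dataclass
class OptimizeResult:
    best: Candidate
    history: list[float]
    branch_counts: list[dict] = field(default_factory=list)
    evaluations: int = 0

    def history_frame(self):
        """Per-iteration best fitness and branch counters as a DataFrame."""
        import pandas as pd

        rows = []
        for i, bf in enumerate(self.history):
            counts = self.branch_counts[i] if i < len(self.branch_counts) else {}
            rows.append(
                {
                    "iteration": i,
                    "best_fitness": bf,
                    "branch_counts_rhso": counts.get("rhso", 0),
                    "branch_counts_da": counts.get("da", 0),
                }
            )
        return pd.DataFrame(rows)


def compute_angle(cf: float, bf: float, wf: float) -> float:
    """Normalized fitness angle in [0, 360].

    Maps the current fitness ``cf`` linearly onto [0, 360] between the
    population best ``bf`` (angle 0) and worst ``wf`` (angle 360).  A
    degenerate population (wf == bf) yields 0.
    """
    if not (math.isfinite(cf) and math.isfinite(bf) and math.isfinite(wf)):
        raise ValueError("angle inputs must be finite")
    if wf < bf:
        raise ValueError("worst fitness must be >= best fitness")
    if wf == bf:
        return 0.0
    angle = (cf - bf) / (wf - bf) * 360.0
    return min(max(angle, 0.0), 360.0)


def route_update(angle: float) -> str:
    """Choose the update family for a candidate: 'rhso' iff angle > 180, else 'da'."""
    if not 0.0 <= angle <= 360.0:
        raise ValueError("angle must be in [0, 360]")
    return "rhso" if angle > 180.0 else "da"


def _evaluate(fitness: Callable, position: np.ndarray) -> float:
    value = float(fitness(position))
    if not math.isfinite(value):
        raise ValueError(f"fitness returned non-finite value {value!r} at position {position.tolist()}")
    return value


def rhso_leader_update(
    leader: Candidate,
    fitness: Callable,
    bounds: Bounds,
    rng: np.random.Generator,
) -> Candidate:
    """Leader contraction: proposal = l1 * position, l1 ~ U[0,1]; greedy acceptance."""
    l1 = rng.uniform(0.0, 1.0)
    proposal = bounds.clip(l1 * leader.position)
    value = _evaluate(fitness, proposal)
    if value < leader.fitness:
        return Candidate(proposal, value)
    return leader.copy()


def rhso_member_update(
    member: Candidate,
    fitness: Callable,
    bounds: Bounds,
    rng: np.random.Generator,
    leader: Candidate | None = None,
    recentered: bool = False,
) -> Candidate:
    """Circular-motion member move with greedy acceptance.

    The move scale ``circle = sqrt((s2 cos a)^2 + (s2 sin a)^2)`` collapses to
    ``|s2|`` identically; the literal rule contracts the position toward the
    origin by that factor.  With ``recentered=True`` the contraction is applied
    to the offset from the leader instead, which keeps the move useful on
    problems whose optimum is away from the origin.
    """
    s2 = rng.uniform(0.0, 1.0)
    move_angle = math.radians(rng.uniform(0.0, 360.0))
    circle = circle_radius(s2, move_angle)
    if recentered and leader is not None:
        proposal = member.position - circle * (member.position - leader.position)
    else:
        proposal = member.position - circle * member.position
    proposal = bounds.clip(proposal)
    value = _evaluate(fitness, proposal)
    if value < member.fitness:
        return Candidate(proposal, value)
    return member.copy()


def circle_radius(s2: float, move_angle_rad: float) -> float:
    """sqrt((s2 cos a)^2 + (s2 sin a)^2); equals |s2| up to rounding."""
    m1 = s2 * math.cos(move_angle_rad)
    m2 = s2 * math.sin(move_angle_rad)
    return math.sqrt(m1 * m1 + m2 * m2)


def perturb_angle(
    angle: float,
    rng: np.random.Generator,
    delta_low: float = -36.0,
    delta_high: float = 36.0,
) -> float:
    """Random walk on the angle, clamped to [0, 360].

    The default step is +-10% of the angle range.
    """
    delta = rng.uniform(delta_low, delta_high)
    return min(max(angle + delta, 0.0), 360.0)


def da_seed_count(
    h_y: float,
    h_min: float,
    h_max: float,
    min_seeds: int = 2,
    max_seeds: int = 10,
    epsilon: float | None = None,
) -> int:
    """Fitness-proportional number of seeds for one dandelion.

    Better (lower) fitness sows more seeds:
    ``n = floor(max_seeds * (h_max - h_y + eps) / (h_max - h_min + eps))``,
    never below ``min_seeds``.  ``eps`` defaults to the smallest positive
    normalized double and only guards the degenerate h_max == h_min case.
    """
    if epsilon is None:
        epsilon = np.finfo(float).tiny
    n = math.floor(max_seeds * (h_max - h_y + epsilon) / (h_max - h_min + epsilon))
    return max(n, min_seeds)


def da_assistant_radius(
    prev_radius: float | None,
    omega: float,
    core_norm: float,
    self_norm: float,
    first_iter: bool,
    bounds: Bounds,
) -> float:
    """Sowing radius of an assistant dandelion.

    First generation: the search-space diameter max(BU - BL).  Later:
    ``omega * prev + (||core||_inf - ||self||_inf)``, floored at a small
    positive fraction of the diameter so sowing never collapses entirely.
    """
    diameter = float(np.max(bounds.span))
    if first_iter or prev_radius is None:
        return diameter
    radius = omega * prev_radius + (core_norm - self_norm)
    return max(radius, RADIUS_FLOOR_FRACTION * diameter)


def da_core_radius(
    prev_radius: float | None,
    improved: bool,
    first_iter: bool,
    f: float,
    v: float,
    bounds: Bounds,
) -> float:
    """Sowing radius of the core (best-fitness) dandelion.

    Grows by factor ``f`` after a generation that improved the core fitness,
    withers by ``v`` otherwise; first generation starts at the search-space
    diameter.
    """
    diameter = float(np.max(bounds.span))
    if first_iter or prev_radius is None:
        return diameter
    radius = prev_radius * (f if improved else v)
    return max(radius, RADIUS_FLOOR_FRACTION * diameter)


class _Agent:
    """Population slot: candidate plus per-dandelion sowing-radius memory."""

    __slots__ = ("candidate", "radius")

    def __init__(self, candidate: Candidate, radius: float | None = None):
        self.candidate = candidate
        self.radius = radius


def optimize(
    fitness: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: OptimizerConfig | None = None,
    initial_positions: Sequence[np.ndarray] | None = None,
) -> OptimizeResult:
    """Run the hybrid optimizer and return the best candidate plus history.

    ``initial_positions`` lets the caller inject known-good starting points
    (e.g. a baseline configuration); elitism then guarantees the result is at
    least as good as any of them.  The rest of the initial population is drawn
    uniformly inside the bounds.
    """
    if config is None:
        config = OptimizerConfig()
    rng = np.random.default_rng(config.seed)
    pop_size = config.population_size

    positions = bounds.sample(rng, pop_size)
    if initial_positions:
        for i, p in enumerate(initial_positions[:pop_size]):
            positions[i] = bounds.clip(np.asarray(p, dtype=float))

    evals = 0

    def evaluate(pos: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        return _evaluate(fitness, pos)

    agents = [_Agent(Candidate(positions[i].copy(), evaluate(positions[i]))) for i in range(pop_size)]

    # omega's denominator: an upper bound on the evaluations one run can spend
    he_max = pop_size * (config.max_iterations + 1) * config.max_seeds

    history: list[float] = []
    branch_log: list[dict] = []
    core_radius: float | None = None
    prev_core_fitness: float | None = None

    for iteration in range(config.max_iterations):
        fits = [a.candidate.fitness for a in agents]
        best_idx = int(np.argmin(fits))  # ties -> lowest index
        worst_idx = int(np.argmax(fits))
        bf = fits[best_idx]
        wf = fits[worst_idx]
        leader = agents[best_idx].candidate

        first_iter = iteration == 0
        improved = prev_core_fitness is not None and bf < prev_core_fitness
        core_radius = da_core_radius(
            core_radius, improved, first_iter, config.growth_factor, config.withering_factor, bounds
        )
        prev_core_fitness = bf
        omega = min(max(1.0 - evals / he_max, 0.0), 1.0)
        core_norm = float(np.max(np.abs(leader.position)))

        counts = {"rhso": 0, "da": 0}
        pool: list[_Agent] = []
        for idx, agent in enumerate(agents):
            cand = agent.candidate
            angle = compute_angle(cand.fitness, bf, wf)
            if config.mode == "rhso":
                branch = "rhso"
            elif config.mode == "da":
                branch = "da"
            else:
                branch = route_update(perturb_angle(angle, rng))
            counts[branch] += 1

            if branch == "rhso":
                if idx == best_idx:
                    updated = rhso_leader_update(cand, evaluate, bounds, rng)
                else:
                    updated = rhso_member_update(
                        cand, evaluate, bounds, rng, leader=leader, recentered=config.recentered
                    )
                pool.append(_Agent(updated, agent.radius))
            else:
                if idx == best_idx:
                    radius = core_radius
                else:
                    radius = da_assistant_radius(
                        agent.radius,
                        omega,
                        core_norm,
                        float(np.max(np.abs(cand.position))),
                        first_iter,
                        bounds,
                    )
                n_seeds = da_seed_count(
                    cand.fitness, bf, wf, config.min_seeds, config.max_seeds
                )
                parent = _Agent(cand.copy(), radius)
                pool.append(parent)
                offsets = rng.uniform(-radius, radius, size=(n_seeds, bounds.dim))
                for k in range(n_seeds):
                    pos = bounds.clip(cand.position + offsets[k])
                    pool.append(_Agent(Candidate(pos, evaluate(pos)), radius))

        # elitist truncation: keep the population_size best of parents + seeds
        order = sorted(range(len(pool)), key=lambda i: (pool[i].candidate.fitness, i))
        agents = [pool[i] for i in order[:pop_size]]
        history.append(agents[0].candidate.fitness)
        branch_log.append(counts)

    best = agents[0].candidate.copy()
    return OptimizeResult(best=best, history=history, branch_counts=branch_log, evaluations=evals)
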