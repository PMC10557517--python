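"""Fireworks Algorithm (FWA) global optimizer.

The FWA is a swarm-intelligence minimizer inspired by fireworks exploding in
the night sky.  A population of ``n_fireworks`` candidate points ("fireworks")
each explodes into a cloud of "sparks": fitter fireworks receive *more* sparks
inside a *smaller* explosion radius (local exploitation), while poorer
fireworks receive fewer sparks spread over a larger radius (global
exploration).  A handful of Gaussian mutation sparks injects extra diversity,
and an elitist, crowding-aware selection carries ``n_fireworks`` individuals
into the next generation.

All randomness flows through a single :class:`numpy.random.Generator` seeded
from :attr:`FWAConfig.seed`; there is no global random state, so runs are
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, List, Sequence

import numpy as np
import yaml
from scipy.spatial.distance import cdist

__all__ = [
    "FWAError",
    "FireworkState",
    "FWAConfig",
    "FWAResult",
    "explosion_radii",
    "spark_counts",
    "generate_explosion_sparks",
    "gaussian_sparks",
    "map_to_bounds",
    "select_next_generation",
    "fwa_minimize",
]

#: Relative floor applied to explosion radii so the best firework keeps a
#: non-zero search radius (its raw radius is exactly zero by construction).
RADIUS_FLOOR_FRACTION = 1e-8

_MUTATION_MODES = ("canonical", "as_printed")


class FWAError(ValueError):
    """Invalid input or configuration for the fireworks optimizer."""


@dataclass
class FireworkState:
    """A candidate point in the bounded search space plus its objective value."""

    position: np.ndarray
    fitness: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.fitness = float(self.fitness)


@dataclass
class FWAConfig:
    """Hyperparameters of the fireworks optimizer.

    Defaults follow the reference setting: 100 iterations, population of 6
    fireworks, explosion amplitude 25, and 6 Gaussian mutation sparks.
    ``n_mutation_sparks`` is the *per-generation* total of mutation sparks
    (parents drawn uniformly from the current population), not a per-firework
    count.

    Parameters
    ----------
    n_fireworks : int
        Population size ("fireworks scale" n).
    spark_budget : int
        Total explosion-spark budget k shared across the population.
    amplitude : float
        Maximum explosion radius; a firework's actual radius scales with its
        fitness relative to the population best.
    clamp_low_frac, clamp_high_frac : float
        Per-firework spark counts are clamped to
        ``[round(clamp_low_frac * k), round(clamp_high_frac * k)]``.
    n_mutation_sparks : int
        Gaussian mutation sparks generated per generation.
    max_iterations : int
        Number of generations T.
    bounds : sequence of (lo, hi)
        Per-dimension search box; out-of-box sparks are mapped back in.
    mutation_mode : {"canonical", "as_printed"}
        ``canonical`` multiplies coordinates by N(1, 1) draws; ``as_printed``
        by N(0, 1) draws (which discards position information in expectation
        and is provided for fidelity to the original formulation only).
    seed : int
        Seed of the single random generator driving the run.
    """

    n_fireworks: int = 6
    spark_budget: int = 6
    amplitude: float = 25.0
    clamp_low_frac: float = 0.1
    clamp_high_frac: float = 0.5
    n_mutation_sparks: int = 6
    max_iterations: int = 100
    bounds: Sequence[Sequence[float]] | None = None
    mutation_mode: str = "canonical"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fireworks < 1:
            raise FWAError("n_fireworks must be a positive integer")
        if self.spark_budget < 1:
            raise FWAError("spark_budget must be a positive integer")
        if self.amplitude <= 0:
            raise FWAError("amplitude must be positive")
        if not (0 < self.clamp_low_frac < self.clamp_high_frac <= 1):
            raise FWAError(
                "require 0 < clamp_low_frac < clamp_high_frac <= 1, got "
                f"({self.clamp_low_frac}, {self.clamp_high_frac})"
            )
        if self.n_mutation_sparks < 0:
            raise FWAError("n_mutation_sparks must be non-negative")
        if self.max_iterations < 1:
            raise FWAError("max_iterations must be a positive integer")
        if self.mutation_mode not in _MUTATION_MODES:
            raise FWAError(
                f"unknown mutation_mode {self.mutation_mode!r}; "
                f"expected one of {_MUTATION_MODES}"
            )
        if self.bounds is not None:
            b = np.asarray(self.bounds, dtype=float)
            if b.ndim != 2 or b.shape[1] != 2:
                raise FWAError("bounds must be a sequence of (lo, hi) pairs")
            if not np.all(b[:, 0] < b[:, 1]):
                raise FWAError("every bound must satisfy lo < hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["bounds"] is not None:
            d["bounds"] = [list(map(float, pair)) for pair in d["bounds"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FWAConfig":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "FWAConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FWAConfig":
        return cls.from_dict(json.loads(text))


@dataclass
class FWAResult:
    """Outcome of one optimizer run.

    ``history`` holds the best fitness seen so far at the end of each
    generation, hence is non-increasing by construction (elitism).
    """

    best_position: np.ndarray
    best_fitness: float
    history: List[float] = field(default_factory=list)
    iterations_run: int = 0


def explosion_radii(fitnesses: np.ndarray, amplitude: float) -> np.ndarray:
    """Per-firework explosion radii, proportional to fitness above the best.

    ``radius_i = (f_i - f_min) / sum_j (f_j - f_min) * amplitude`` with a small
    floor so the best firework (whose raw radius is 0) still searches a tiny
    neighbourhood.  If all fitnesses coincide, every radius is ``amplitude/n``.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise FWAError("fitnesses must be a non-empty 1-D vector")
    if amplitude <= 0:
        raise FWAError("amplitude must be positive")
    diffs = f - f.min()
    denom = diffs.sum()
    if denom <= np.finfo(float).eps * max(1.0, np.abs(f).max()):
        return np.full(f.size, amplitude / f.size)
    radii = diffs / denom * amplitude
    return np.maximum(radii, RADIUS_FLOOR_FRACTION * amplitude)


def spark_counts(
    fitnesses: np.ndarray,
    spark_budget: int,
    clamp_low_frac: float = 0.1,
    clamp_high_frac: float = 0.5,
) -> np.ndarray:
    """Number of explosion sparks per firework (fitter fireworks get more).

    Raw counts ``s_i = (f_max - f_i) / sum_j (f_max - f_j) * k`` are rounded to
    the nearest integer (half to even) and clamped to
    ``[round(clamp_low_frac*k), round(clamp_high_frac*k)]`` with a hard minimum
    of one spark.  With all fitnesses equal the budget is split evenly.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise FWAError("fitnesses must be a non-empty 1-D vector")
    k = int(spark_budget)
    if k < 1:
        raise FWAError("spark_budget must be >= 1")
    diffs = f.max() - f
    denom = diffs.sum()
    if denom <= np.finfo(float).eps * max(1.0, np.abs(f).max()):
        per = max(1, int(np.rint(k / f.size)))
        return np.full(f.size, per, dtype=int)
    raw = diffs / denom * k
    s = np.rint(raw).astype(int)
    lo = int(np.rint(clamp_low_frac * k))
    hi = int(np.rint(clamp_high_frac * k))
    s = np.clip(s, lo, hi)
    return np.maximum(s, 1)


def map_to_bounds(position: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Map a position into the search box by modular reflection.

    In-box coordinates pass through unchanged; an out-of-box coordinate ``x``
    becomes ``lo + (|x - lo| mod (hi - lo))``.
    """
    pos = np.asarray(position, dtype=float).copy()
    b = np.asarray(bounds, dtype=float)
    lo, hi = b[:, 0], b[:, 1]
    width = hi - lo
    if np.any(width <= 0):
        raise FWAError("every bound must satisfy lo < hi")
    outside = (pos < lo) | (pos > hi)
    if np.any(outside):
        pos[outside] = lo[outside] + np.abs(pos[outside] - lo[outside]) % width[outside]
    return pos


def _parent_position(parent) -> np.ndarray:
    if isinstance(parent, FireworkState):
        return np.asarray(parent.position, dtype=float)
    return np.asarray(parent, dtype=float)


def generate_explosion_sparks(
    parent,
    radius: float,
    count: int,
    bounds: np.ndarray,
    rng: np.random.Generator,
) -> List[np.ndarray]:
    """Uniform displacement sparks around a firework.

    Each spark perturbs ``z ~ UniformInteger(1, D)`` randomly chosen dimensions
    by ``radius * Uniform(-1, 1)`` (fresh draw per dimension) and is mapped
    back into the search box.
    """
    if radius < 0:
        raise FWAError("radius must be non-negative")
    if count < 0:
        raise FWAError("count must be non-negative")
    base = _parent_position(parent)
    D = base.size
    sparks = []
    for _ in range(int(count)):
        z = int(rng.integers(1, D + 1))
        dims = rng.choice(D, size=z, replace=False)
        pos = base.copy()
        pos[dims] += radius * rng.uniform(-1.0, 1.0, size=z)
        sparks.append(map_to_bounds(pos, bounds))
    return sparks


def gaussian_sparks(
    parent,
    count: int,
    mode: str,
    bounds: np.ndarray,
    rng: np.random.Generator,
) -> List[np.ndarray]:
    """Gaussian mutation sparks: multiplicative noise on a dimension subset.

    On each of ``z ~ UniformInteger(1, D)`` chosen dimensions the coordinate is
    multiplied by ``g ~ N(1, 1)`` (``canonical``) or ``g ~ N(0, 1)``
    (``as_printed``); results are mapped into the box.
    """
    if count < 0:
        raise FWAError("count must be non-negative")
    if mode not in _MUTATION_MODES:
        raise FWAError(f"unknown mutation mode {mode!r}; expected one of {_MUTATION_MODES}")
    mean = 1.0 if mode == "canonical" else 0.0
    base = _parent_position(parent)
    D = base.size
    sparks = []
    for _ in range(int(count)):
        z = int(rng.integers(1, D + 1))
        dims = rng.choice(D, size=z, replace=False)
        pos = base.copy()
        pos[dims] *= rng.normal(mean, 1.0, size=z)
        sparks.append(map_to_bounds(pos, bounds))
    return sparks


def select_next_generation(
    candidates: Sequence[FireworkState],
    n: int,
    rng: np.random.Generator,
) -> List[FireworkState]:
    """Elitist, crowding-aware selection of the next generation.

    The best candidate (ties: lowest index) always survives.  The remaining
    ``n - 1`` slots are filled by sampling without replacement with probability
    proportional to each candidate's summed Euclidean distance to all other
    candidates, which prefers individuals in sparse regions.  If fewer than
    ``n`` candidates exist, all survive and the population is topped up with
    uniform re-draws.
    """
    if len(candidates) == 0:
        raise FWAError("candidates must be non-empty")
    if n < 1:
        raise FWAError("n must be >= 1")
    m = len(candidates)
    fitnesses = np.array([c.fitness for c in candidates])
    elite = int(np.argmin(fitnesses))
    if m <= n:
        out = list(candidates)
        while len(out) < n:
            out.append(candidates[int(rng.integers(m))])
        return out
    positions = np.vstack([c.position for c in candidates])
    weights = cdist(positions, positions).sum(axis=1)
    pool = [i for i in range(m) if i != elite]
    w = weights[pool].astype(float)
    chosen = [elite]
    for _ in range(n - 1):
        total = w.sum()
        if total <= 0:
            idx = int(rng.integers(len(pool)))
        else:
            idx = int(rng.choice(len(pool), p=w / total))
        chosen.append(pool.pop(idx))
        w = np.delete(w, idx)
    return [candidates[i] for i in chosen]


def fwa_minimize(objective: Callable[[np.ndarray], float], config: FWAConfig) -> FWAResult:
    """Run the fireworks optimizer on ``objective`` over the configured box.

    Each generation: evaluate the population, compute radii and spark counts,
    generate explosion and Gaussian mutation sparks, then select the next
    population from fireworks + sparks.  ``history`` records the best fitness
    seen so far after each generation and is therefore non-increasing.
    """
    if config.bounds is None:
        raise FWAError("config.bounds must be set for fwa_minimize")
    bounds = np.asarray(config.bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(config.seed)

    def evaluate(pos: np.ndarray) -> float:
        val = float(objective(pos))
        if not np.isfinite(val):
            raise FWAError(f"objective returned non-finite value {val!r} at position {pos!r}")
        return val

    fireworks = []
    for _ in range(config.n_fireworks):
        pos = rng.uniform(lo, hi)
        fireworks.append(FireworkState(pos, evaluate(pos)))

    best_idx = int(np.argmin([fw.fitness for fw in fireworks]))
    best_position = fireworks[best_idx].position.copy()
    best_fitness = fireworks[best_idx].fitness
    history: List[float] = []

    for _ in range(config.max_iterations):
        fitnesses = np.array([fw.fitness for fw in fireworks])
        radii = explosion_radii(fitnesses, config.amplitude)
        counts = spark_counts(
            fitnesses, config.spark_budget, config.clamp_low_frac, config.clamp_high_frac
        )
        candidates: List[FireworkState] = list(fireworks)
        for fw, radius, count in zip(fireworks, radii, counts):
            for pos in generate_explosion_sparks(fw, float(radius), int(count), bounds, rng):
                candidates.append(FireworkState(pos, evaluate(pos)))
        for _ in range(config.n_mutation_sparks):
            parent = fireworks[int(rng.integers(len(fireworks)))]
            for pos in gaussian_sparks(parent, 1, config.mutation_mode, bounds, rng):
                candidates.append(FireworkState(pos, evaluate(pos)))
        for cand in candidates:
            if cand.fitness < best_fitness:
                best_fitness = cand.fitness
                best_position = cand.position.copy()
        history.append(best_fitness)
        fireworks = select_next_generation(candidates, config.n_fireworks, rng)

    return FWAResult(
        best_position=best_position,
        best_fitness=best_fitness,
        history=history,
        iterations_run=config.max_iterations,
    )
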