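"""Shared search-space types and population machinery.

All optimizers in this package (GO, AOA and the GOAOA hybrid) minimise a
nonnegative objective over a box ``[lb, ub]^D`` using a population of N
continuous positions.  This module owns the types they share: the box
(:class:`SearchSpace`), the population state (:class:`Population`), the
parameter record (:class:`OptimizerConfig`) and the run output
(:class:`RunResult`), together with population initialization, bounds
handling and ranking.

Randomness contract
-------------------
Every optimizer run consumes a single :class:`numpy.random.Generator`
seeded from ``OptimizerConfig.seed``.  Draws are consumed in a documented
fixed order — phase-major, individual-major, dimension-major, with
per-dimension draws taken as whole vectors — so a seed fully determines a
trajectory and two runs with the same config are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

__all__ = [
    "BoundsError",
    "ConfigurationError",
    "EvaluationError",
    "StateError",
    "SearchSpace",
    "Individual",
    "Population",
    "OptimizerConfig",
    "RunResult",
    "make_rng",
    "init_population",
    "clip_to_bounds",
    "sort_and_rank",
]


class ConfigurationError(ValueError):
    """Invalid optimizer or fitness configuration."""


class BoundsError(ValueError):
    """Lower bound exceeds upper bound, or a vector violates the box."""


class StateError(RuntimeError):
    """An operation was called on a population in the wrong state."""


class EvaluationError(RuntimeError):
    """The objective returned a non-finite value."""


def make_rng(seed: Optional[int]) -> np.random.Generator:
    """Return the single random stream used for one optimizer run."""
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SearchSpace:
    """Box-constrained search domain ``[lower, upper]^dim``.

    For feature selection the box is always the unit cube: positions are
    thresholded at 0.5 into a binary feature mask.
    """

    dim: int
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ConfigurationError(f"dim must be >= 1, got {self.dim}")
        lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.dim,)).copy()
        upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.dim,)).copy()
        if np.any(lower > upper):
            raise BoundsError("lower bound exceeds upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @classmethod
    def unit(cls, dim: int) -> "SearchSpace":
        """The unit cube used for wrapper feature selection."""
        return cls(dim, 0.0, 1.0)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


@dataclass
class Individual:
    """One candidate solution: a continuous position and its fitness.

    ``fitness`` is the growth resistance GR of the GO literature; lower is
    better.  ``mask`` is the thresholded binary view used by the wrapper
    objective (``position >= 0.5``).
    """

    position: np.ndarray
    fitness: float = np.nan

    @property
    def mask(self) -> np.ndarray:
        return (self.position >= 0.5).astype(np.int8)


class Population:
    """Array-backed population with ranking and best-ever bookkeeping.

    Attributes
    ----------
    positions : (N, D) array, every row inside the search box.
    fitness : (N,) array, NaN until first evaluation.
    order : permutation of 0..N-1 sorting fitness ascending (stable).
    best_position, best_fitness : best-ever solution (gbestx); updated on
        every evaluation and never worsened.
    evals : cumulative number of objective evaluations.
    """

    def __init__(self, positions: np.ndarray, space: SearchSpace):
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != space.dim:
            raise ConfigurationError("positions must have shape (N, dim)")
        self.space = space
        self.positions = positions
        self.n = positions.shape[0]
        self.fitness = np.full(self.n, np.nan)
        self.order = np.arange(self.n)
        self.best_position: Optional[np.ndarray] = None
        self.best_fitness: float = np.inf
        self.iteration = 0
        self.evals = 0

    def evaluate_all(self, objective: Callable[[np.ndarray], float]) -> None:
        for i in range(self.n):
            self.fitness[i] = self.evaluate(objective, self.positions[i])

    def evaluate(self, objective: Callable[[np.ndarray], float], position: np.ndarray) -> float:
        """Evaluate one position, count it, and update the best-ever solution."""
        value = float(objective(position))
        if not np.isfinite(value):
            raise EvaluationError(f"objective returned {value!r} at position {position!r}")
        self.evals += 1
        if value < self.best_fitness:
            self.best_fitness = value
            self.best_position = position.copy()
        return value

    @property
    def rank_of(self) -> np.ndarray:
        """Inverse of ``order``: rank_of[i] is the 0-based rank of member i."""
        inv = np.empty(self.n, dtype=int)
        inv[self.order] = np.arange(self.n)
        return inv


def init_population(space: SearchSpace, n: int, rng: np.random.Generator) -> Population:
    """Uniform initialization ``lb + (ub - lb) * U[0,1)`` per coordinate.

    Fitness is left unset; callers evaluate lazily.
    """
    if n < 2:
        raise ConfigurationError(f"population size must be >= 2, got {n}")
    u = rng.random((n, space.dim))
    return Population(space.lower + space.width * u, space)


def clip_to_bounds(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Project a position onto the box; in-range coordinates are untouched."""
    position = np.asarray(position, dtype=float)
    if position.shape != (space.dim,):
        raise BoundsError(f"expected shape ({space.dim},), got {position.shape}")
    return np.clip(position, space.lower, space.upper)


def sort_and_rank(pop: Population) -> Population:
    """Rank members by ascending fitness (stable, index tie-break).

    Also refreshes the best-ever solution should a member beat it.
    """
    if np.any(np.isnan(pop.fitness)):
        raise StateError("cannot rank a population with unevaluated members")
    pop.order = np.argsort(pop.fitness, kind="stable")
    leader = pop.order[0]
    if pop.fitness[leader] < pop.best_fitness:
        pop.best_fitness = float(pop.fitness[leader])
        pop.best_position = pop.positions[leader].copy()
    return pop


@dataclass
class OptimizerConfig:
    """All tunable optimizer parameters in one validated record.

    Defaults follow the hybrid's published settings: ``p1=10, p2=0.004,
    p3=0.3`` with AOA sensitivity ``alpha=5`` and control ``mu=0.5``.  The
    plain Growth Optimizer uses ``p1=5, p2=0.001, p3=0.3``
    (:meth:`go_defaults`).  Population size and iteration budget are
    artifact configuration, not published values.
    """

    pop_size: int = 30
    max_iter: int = 100
    p1: int = 10
    p2: float = 0.004
    p3: float = 0.3
    aoa_alpha: float = 5.0
    aoa_mu: float = 0.5
    moa_min: float = 0.2
    moa_max: float = 1.0
    eps: float = 1e-12
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pop_size < 2:
            raise ConfigurationError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if not 0.0 <= self.p2 <= 1.0:
            raise ConfigurationError("p2 must lie in [0, 1]")
        if not 0.0 <= self.p3 <= 1.0:
            raise ConfigurationError("p3 must lie in [0, 1]")
        if not 1 <= self.p1 <= self.pop_size // 2:
            raise ConfigurationError(
                f"p1 must satisfy 1 <= p1 <= pop_size/2 (p1={self.p1}, pop_size={self.pop_size})"
            )
        if not self.moa_min < self.moa_max:
            raise ConfigurationError("moa_min must be < moa_max")
        if not self.eps > 0:
            raise ConfigurationError("eps must be positive")
        if not self.aoa_alpha > 0:
            raise ConfigurationError("aoa_alpha must be positive")

    @classmethod
    def go_defaults(cls, **overrides) -> "OptimizerConfig":
        """Published Growth Optimizer settings (p1=5, p2=0.001, p3=0.3)."""
        params = dict(p1=5, p2=0.001, p3=0.3)
        params.update(overrides)
        return cls(**params)

    @classmethod
    def goaoa_defaults(cls, **overrides) -> "OptimizerConfig":
        """Published hybrid settings (alpha=5, mu=0.5, p1=10, p2=0.004, p3=0.3)."""
        return cls(**overrides)

    def with_seed(self, seed: Optional[int]) -> "OptimizerConfig":
        return replace(self, seed=seed)


@dataclass
class RunResult:
    """Outcome of one optimizer run.

    ``trace`` holds the best-ever fitness after initialization and after
    each iteration (length ``max_iter + 1``) and is non-increasing by
    construction.  ``evals`` counts objective evaluations: N at
    initialization plus one per individual per phase, i.e.
    ``N + 2*N*max_iter`` for the two-phase optimizers and
    ``N + N*max_iter`` for single-phase AOA.
    """

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray
    evals: int
    algorithm: str = ""

    @property
    def best_mask(self) -> np.ndarray:
        """Thresholded binary view of the best position (>= 0.5)."""
        return (self.best_position >= 0.5).astype(np.int8)
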