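"""Arithmetic Optimization Algorithm: schedules, operators, standalone loop.

AOA steers a population around the best-ever solution with the four
arithmetic operators.  Division and multiplication make large,
explorative moves; subtraction and addition make small, exploitative
ones.  Two schedules control the balance over iterations t = 1..T:

* MOA (math optimizer accelerated), increasing — the gate between
  exploration (draw > MOA) and exploitation;
* MOP (math optimizer probability), decreasing — the step magnitude,
  ``1 - (t/T)^(1/alpha)``.

The hybrid reuses the exploration operator and the MOA gate; the
standalone loop here is the canonical greedy-acceptance AOA used as a
baseline comparator.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .core import (
    OptimizerConfig,
    Population,
    RunResult,
    SearchSpace,
    clip_to_bounds,
    init_population,
    make_rng,
    sort_and_rank,
)

__all__ = [
    "moa_schedule",
    "mop_schedule",
    "aoa_explore_dimension",
    "aoa_exploit_dimension",
    "aoa_explore_position",
    "run_aoa",
]

Objective = Callable[[np.ndarray], float]


def moa_schedule(t: int, max_iter: int, moa_min: float = 0.2, moa_max: float = 1.0) -> float:
    """Linear ramp from ``moa_min`` (t=0) to ``moa_max`` (t=max_iter)."""
    if not 0 <= t <= max_iter:
        raise ValueError(f"t must lie in [0, {max_iter}], got {t}")
    return moa_min + t * (moa_max - moa_min) / max_iter


def mop_schedule(t: int, max_iter: int, alpha: float = 5.0) -> float:
    """Decaying step magnitude ``1 - (t/max_iter)^(1/alpha)``, in [0, 1]."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    value = 1.0 - (t / max_iter) ** (1.0 / alpha)
    return float(min(1.0, max(0.0, value)))


def aoa_explore_dimension(
    best_j: float,
    mop: float,
    lb: float,
    ub: float,
    mu: float,
    eps: float,
    rng: np.random.Generator,
) -> float:
    """Division/multiplication move for one coordinate (pre-clipping is
    the caller's job via the box contract)."""
    scale = (ub - lb) * mu + lb
    if rng.random() < 0.5:
        return best_j / (mop + eps) * scale
    return best_j * mop * scale


def aoa_exploit_dimension(
    best_j: float,
    mop: float,
    lb: float,
    ub: float,
    mu: float,
    rng: np.random.Generator,
) -> float:
    """Subtraction/addition move for one coordinate, symmetric about
    ``best_j``."""
    scale = (ub - lb) * mu + lb
    if rng.random() < 0.5:
        return best_j - mop * scale
    return best_j + mop * scale


def aoa_explore_position(
    best: np.ndarray,
    mop: float,
    space: SearchSpace,
    mu: float,
    eps: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized exploration of a whole position around ``best``.

    Consumes one operator-choice vector of length D (division where the
    draw is < 0.5, multiplication otherwise); the result is clipped.
    """
    scale = space.width * mu + space.lower
    r = rng.random(space.dim)
    out = np.where(r < 0.5, best / (mop + eps) * scale, best * mop * scale)
    return clip_to_bounds(out, space)


def _aoa_candidate(
    best: np.ndarray,
    moa: float,
    mop: float,
    space: SearchSpace,
    mu: float,
    eps: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One full AOA candidate: per-dimension gate between exploration and
    exploitation.  Draw order: gate vector r1, then operator vector r."""
    scale = space.width * mu + space.lower
    r1 = rng.random(space.dim)
    r = rng.random(space.dim)
    explore = np.where(r < 0.5, best / (mop + eps) * scale, best * mop * scale)
    exploit = np.where(r < 0.5, best - mop * scale, best + mop * scale)
    return clip_to_bounds(np.where(r1 > moa, explore, exploit), space)


def run_aoa(objective: Objective, space: SearchSpace, cfg: OptimizerConfig) -> RunResult:
    """Canonical AOA loop with greedy acceptance.

    One candidate per individual per iteration, built coordinate-wise
    around the best-ever position; a candidate replaces its parent only
    if it strictly improves.  Evaluations: ``N + N*max_iter``.
    """
    rng = make_rng(cfg.seed)
    pop = init_population(space, cfg.pop_size, rng)
    pop.evaluate_all(objective)
    sort_and_rank(pop)
    trace = [pop.best_fitness]
    for t in range(1, cfg.max_iter + 1):
        pop.iteration = t
        moa = moa_schedule(t, cfg.max_iter, cfg.moa_min, cfg.moa_max)
        mop = mop_schedule(t, cfg.max_iter, cfg.aoa_alpha)
        for i in range(pop.n):
            candidate = _aoa_candidate(
                pop.best_position, moa, mop, space, cfg.aoa_mu, cfg.eps, rng
            )
            cand_fit = pop.evaluate(objective, candidate)
            if cand_fit < pop.fitness[i]:
                pop.positions[i] = candidate
                pop.fitness[i] = cand_fit
        sort_and_rank(pop)
        trace.append(pop.best_fitness)
    return RunResult(
        best_position=pop.best_position.copy(),
        best_fitness=pop.best_fitness,
        trace=np.asarray(trace),
        evals=pop.evals,
        algorithm="aoa",
    )
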