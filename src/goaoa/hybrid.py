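"""The GOAOA hybrid: GO learning gated with AOA exploration.

Each iteration ranks the population and runs two phases.  In the
learning phase every individual draws one gate variable against the MOA
schedule: above the gate it takes the AOA exploration branch
(division/multiplication moves anchored on the best-ever solution,
magnitude MOP), below it the full GO learning pipeline.  Either
candidate passes through GO's retention rule (improvement, or
probability ``p2`` retention that never displaces the rank-1 member).
The reflection phase is GO's, but with a gentler, iteration-indexed
attenuation factor ``AF = 0.02 + 0.33 * (1 - t/T)`` in place of GO's
evaluation-indexed one — less random restarting, more exploitation,
which suits the thresholded feature-selection landscape.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from . import aoa, go
from .core import (
    OptimizerConfig,
    Population,
    RunResult,
    SearchSpace,
    init_population,
    make_rng,
    sort_and_rank,
)

__all__ = [
    "attenuation_goaoa",
    "goaoa_learning_phase",
    "goaoa_reflection_phase",
    "run_goaoa",
]

Objective = Callable[[np.ndarray], float]


def attenuation_goaoa(it: int, max_iter: int) -> float:
    """Hybrid attenuation factor ``0.02 + 0.33 * (1 - it/max_iter)``."""
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")
    if not 0 <= it <= max_iter:
        raise ValueError(f"it must lie in [0, {max_iter}], got {it}")
    return 0.02 + 0.33 * (1.0 - it / max_iter)


def goaoa_learning_phase(
    pop: Population,
    cfg: OptimizerConfig,
    objective: Objective,
    rng: np.random.Generator,
    t: int,
) -> Population:
    """GO learning phase with the AOA exploration gate at iteration ``t``."""
    moa = aoa.moa_schedule(t, cfg.max_iter, cfg.moa_min, cfg.moa_max)
    mop = aoa.mop_schedule(t, cfg.max_iter, cfg.aoa_alpha)

    def explore(_x: np.ndarray, stream: np.random.Generator) -> np.ndarray:
        return aoa.aoa_explore_position(
            pop.best_position, mop, pop.space, cfg.aoa_mu, cfg.eps, stream
        )

    return go.learning_phase(pop, cfg, objective, rng, gate_moa=moa, explore_fn=explore)


def goaoa_reflection_phase(
    pop: Population,
    cfg: OptimizerConfig,
    objective: Objective,
    rng: np.random.Generator,
    t: int,
) -> Population:
    """GO reflection phase driven by the hybrid attenuation factor."""
    af = attenuation_goaoa(t, cfg.max_iter)
    return go.reflection_phase(pop, cfg, objective, rng, af)


def run_goaoa(objective: Objective, space: SearchSpace, cfg: OptimizerConfig) -> RunResult:
    """Full hybrid loop.

    Uniform initialization, then ``max_iter`` iterations of {rank,
    gated learning phase, reflection phase}.  Evaluations:
    ``N + 2*N*max_iter``; the returned trace has length ``max_iter + 1``
    and is non-increasing.
    """
    rng = make_rng(cfg.seed)
    pop = init_population(space, cfg.pop_size, rng)
    pop.evaluate_all(objective)
    sort_and_rank(pop)
    trace = [pop.best_fitness]
    for t in range(1, cfg.max_iter + 1):
        pop.iteration = t
        goaoa_learning_phase(pop, cfg, objective, rng, t)
        goaoa_reflection_phase(pop, cfg, objective, rng, t)
        trace.append(pop.best_fitness)
    return RunResult(
        best_position=pop.best_position.copy(),
        best_fitness=pop.best_fitness,
        trace=np.asarray(trace),
        evals=pop.evals,
        algorithm="goaoa",
    )
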