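"""Growth Optimizer: learning and reflection phases and the standalone loop.

The Growth Optimizer (GO) models social growth.  In the *learning phase*
each individual absorbs knowledge from four gaps between role players —
the leader (rank 1), an elite (one of ranks 2..P1), a bottom individual
(one of the P1 worst) and a random pair — scaled by normalized learning
factors LF_k and the individual's strength factor SF_i = GR_i / GR_max,
where growth resistance GR is the objective value.  In the *reflection
phase* each coordinate is, with probability P3, either re-initialized
uniformly (with probability AF, an attenuation factor that decays with
the evaluation budget) or pulled toward a top-P1 individual.  Both phases
accept a candidate if it improves, and otherwise retain it with small
probability P2 — never for the current rank-1 member, so the global best
cannot be displaced.

The learning phase implemented here carries an optional per-individual
exploration gate (``gate_moa`` with an ``explore_fn``): when a uniform
draw exceeds the gate, the whole position is regenerated by the supplied
exploration operator instead of the GO update.  Standalone GO runs with
the gate disabled (``gate_moa=1`` so the branch is never taken, the draw
still consumed); the hybrid enables it with the AOA schedule.  Sharing
one code path makes the hybrid reduce bit-exactly to GO when its gate is
pinned open.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ConfigurationError,
    Individual,
    OptimizerConfig,
    Population,
    RunResult,
    SearchSpace,
    StateError,
    clip_to_bounds,
    init_population,
    make_rng,
    sort_and_rank,
)

__all__ = [
    "select_roles",
    "compute_gaps",
    "learning_factors",
    "strength_factor",
    "knowledge_acquisition",
    "learning_update",
    "accept_individual",
    "attenuation_go",
    "reflection_update",
    "learning_phase",
    "reflection_phase",
    "run_go",
]

Objective = Callable[[np.ndarray], float]


def select_roles(
    pop: Population, i: int, p1: int, rng: np.random.Generator
) -> Tuple[Individual, Individual, Individual, Individual, Individual]:
    """Draw the five role players for individual ``i``'s learning step.

    Returns (best, better, worse, L1, L2): the leader, an elite drawn
    uniformly from ranks 2..P1, a bottom individual drawn uniformly from
    the P1 worst ranks, and two distinct random individuals different
    from ``i``.  Draw order: elite rank, bottom rank, random pair.
    """
    n = pop.n
    if n < 2 * p1:
        raise ConfigurationError(f"need pop_size >= 2*p1 (pop_size={n}, p1={p1})")
    order = pop.order

    def member(idx: int) -> Individual:
        return Individual(pop.positions[idx], float(pop.fitness[idx]))

    best = member(order[0])
    better = member(order[rng.integers(1, p1)])
    worse = member(order[rng.integers(n - p1, n)])
    candidates = np.delete(np.arange(n), i)
    l1, l2 = rng.choice(candidates, size=2, replace=False)
    return best, better, worse, member(l1), member(l2)


def compute_gaps(
    best: np.ndarray,
    better: np.ndarray,
    worse: np.ndarray,
    l1: np.ndarray,
    l2: np.ndarray,
) -> np.ndarray:
    """The four learning gaps, stacked as a (4, D) array.

    Gap_1 = best - better, Gap_2 = best - worse, Gap_3 = better - worse,
    Gap_4 = L1 - L2.
    """
    arrs = [np.asarray(a, dtype=float) for a in (best, better, worse, l1, l2)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("role vectors must share one shape")
    best, better, worse, l1, l2 = arrs
    return np.stack([best - better, best - worse, better - worse, l1 - l2])


def learning_factors(gaps: np.ndarray) -> np.ndarray:
    """Normalized Euclidean norms of the four gaps (they sum to 1).

    When the population has collapsed and every gap is zero, the factors
    fall back to 0.25 each by symmetry.
    """
    norms = np.linalg.norm(np.asarray(gaps, dtype=float), axis=1)
    total = norms.sum()
    if total == 0.0:
        return np.full(4, 0.25)
    return norms / total


def strength_factor(gr_i: float, gr_max: float, eps: float = 1e-12) -> float:
    """GR_i / GR_max: how much knowledge the individual can absorb.

    Returns 1 when GR_max is (numerically) zero — the whole population is
    already at a zero-resistance optimum.
    """
    if gr_i > gr_max:
        raise StateError(f"gr_i ({gr_i}) exceeds gr_max ({gr_max})")
    if gr_max <= eps:
        return 1.0
    return gr_i / gr_max


def knowledge_acquisition(sf: float, lf_k: float, gap_k: np.ndarray) -> np.ndarray:
    """KA_k = SF_i * LF_k * Gap_k, element-wise."""
    return sf * lf_k * np.asarray(gap_k, dtype=float)


def learning_update(x: np.ndarray, ka: Sequence[np.ndarray], space: SearchSpace) -> np.ndarray:
    """Grow by assimilating the four knowledge terms; clip to the box."""
    out = np.asarray(x, dtype=float) + np.sum(np.asarray(ka, dtype=float), axis=0)
    return clip_to_bounds(out, space)


def accept_individual(
    old_fitness: float,
    candidate_fitness: float,
    old_is_leader: bool,
    p2: float,
    rng: np.random.Generator,
) -> bool:
    """Retention rule: keep the candidate?

    A strictly better candidate always replaces its parent.  A worse one
    is retained only with probability ``p2`` and never when the parent is
    the current rank-1 individual, which protects the global optimum from
    being displaced.  The best-ever solution is tracked separately at
    evaluation time and is never worsened by this rule.
    """
    if np.isnan(old_fitness) or np.isnan(candidate_fitness):
        raise StateError("both individuals must be evaluated before acceptance")
    if candidate_fitness < old_fitness:
        return True
    r1 = rng.random()
    return bool(r1 < p2 and not old_is_leader)


def attenuation_go(fes: int, max_fes: int) -> float:
    """GO's attenuation factor AF = 0.01 + 0.99 * (1 - FEs / MaxFEs)."""
    if max_fes <= 0:
        raise ValueError("max_fes must be positive")
    if not 0 <= fes <= max_fes:
        raise ValueError(f"fes must lie in [0, {max_fes}], got {fes}")
    return 0.01 + 0.99 * (1.0 - fes / max_fes)


def reflection_update(
    x: np.ndarray,
    top: np.ndarray,
    af: float,
    p3: float,
    space: SearchSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    """One reflection step for a whole position.

    ``top`` is the (P1, D) block of top-ranked positions.  One guide R is
    drawn uniformly from it per individual.  Per dimension j, with
    probability ``p3`` the coordinate reflects: re-initialized uniformly
    in the box with probability ``af``, otherwise pulled toward R_j by a
    uniform fraction.  Draw order per individual: guide index, then the
    r2, r3, r4, r5 vectors of length D.
    """
    top = np.atleast_2d(np.asarray(top, dtype=float))
    if top.shape[0] == 0:
        raise StateError("reflection requires a non-empty top-P1 block")
    x = np.asarray(x, dtype=float)
    d = space.dim
    guide = top[rng.integers(0, top.shape[0])]
    r2 = rng.random(d)
    r3 = rng.random(d)
    r4 = rng.random(d)
    r5 = rng.random(d)
    reinit = space.lower + r4 * space.width
    attract = x + r5 * (guide - x)
    out = np.where(r2 < p3, np.where(r3 < af, reinit, attract), x)
    return clip_to_bounds(out, space)


ExploreFn = Callable[[np.ndarray, np.random.Generator], np.ndarray]


def learning_phase(
    pop: Population,
    cfg: OptimizerConfig,
    objective: Objective,
    rng: np.random.Generator,
    gate_moa: float = 1.0,
    explore_fn: Optional[ExploreFn] = None,
) -> Population:
    """Run one learning phase in place (ranks first, then updates members).

    Per individual, in member order: one gate draw ``r``; if
    ``r > gate_moa`` and an exploration operator is supplied, the
    candidate comes from ``explore_fn`` (the hybrid's AOA branch),
    otherwise from the GO learning pipeline (roles -> gaps -> LF/SF ->
    knowledge -> update).  The candidate is clipped, evaluated, and
    passed through the retention rule.  Growth resistances for SF are
    snapshot at phase start; positions update in place.
    """
    sort_and_rank(pop)
    gr = pop.fitness.copy()
    gr_max = float(gr.max())
    rank_of = pop.rank_of
    for i in range(pop.n):
        r_gate = rng.random()
        if r_gate > gate_moa and explore_fn is not None:
            candidate = clip_to_bounds(explore_fn(pop.positions[i], rng), pop.space)
        else:
            best, better, worse, l1, l2 = select_roles(pop, i, cfg.p1, rng)
            gaps = compute_gaps(
                best.position, better.position, worse.position, l1.position, l2.position
            )
            lf = learning_factors(gaps)
            sf = strength_factor(float(gr[i]), gr_max, cfg.eps)
            ka = [knowledge_acquisition(sf, lf[k], gaps[k]) for k in range(4)]
            candidate = learning_update(pop.positions[i], ka, pop.space)
        cand_fit = pop.evaluate(objective, candidate)
        if accept_individual(
            float(pop.fitness[i]), cand_fit, rank_of[i] == 0, cfg.p2, rng
        ):
            pop.positions[i] = candidate
            pop.fitness[i] = cand_fit
    return pop


def reflection_phase(
    pop: Population,
    cfg: OptimizerConfig,
    objective: Objective,
    rng: np.random.Generator,
    af: float,
) -> Population:
    """Run one reflection phase in place with attenuation factor ``af``."""
    sort_and_rank(pop)
    top = pop.positions[pop.order[: cfg.p1]].copy()
    rank_of = pop.rank_of
    for i in range(pop.n):
        candidate = reflection_update(
            pop.positions[i], top, af, cfg.p3, pop.space, rng
        )
        cand_fit = pop.evaluate(objective, candidate)
        if accept_individual(
            float(pop.fitness[i]), cand_fit, rank_of[i] == 0, cfg.p2, rng
        ):
            pop.positions[i] = candidate
            pop.fitness[i] = cand_fit
    return pop


def run_go(objective: Objective, space: SearchSpace, cfg: OptimizerConfig) -> RunResult:
    """Standalone Growth Optimizer loop.

    Initialization, then ``max_iter`` iterations of learning phase
    followed by reflection phase, with AF decaying over the evaluation
    budget (``MaxFEs = N + 2*N*max_iter``).  Returns the best-ever
    solution, its fitness trace and the evaluation count.
    """
    rng = make_rng(cfg.seed)
    pop = init_population(space, cfg.pop_size, rng)
    pop.evaluate_all(objective)
    max_fes = cfg.pop_size + 2 * cfg.pop_size * cfg.max_iter
    trace = [pop.best_fitness if pop.best_position is not None else np.inf]
    sort_and_rank(pop)
    trace[0] = pop.best_fitness
    for t in range(1, cfg.max_iter + 1):
        pop.iteration = t
        learning_phase(pop, cfg, objective, rng)
        af = attenuation_go(pop.evals, max_fes)
        reflection_phase(pop, cfg, objective, rng, af)
        trace.append(pop.best_fitness)
    return RunResult(
        best_position=pop.best_position.copy(),
        best_fitness=pop.best_fitness,
        trace=np.asarray(trace),
        evals=pop.evals,
        algorithm="go",
    )
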