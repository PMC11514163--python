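import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goaoa.core import (
    ConfigurationError,
    OptimizerConfig,
    Population,
    SearchSpace,
    StateError,
    make_rng,
    sort_and_rank,
)
from goaoa.go import (
    accept_individual,
    attenuation_go,
    compute_gaps,
    knowledge_acquisition,
    learning_factors,
    learning_update,
    reflection_update,
    run_go,
    select_roles,
    strength_factor,
)
from conftest import sphere


def ranked_population(fitnesses, dim=2, seed=0):
    n = len(fitnesses)
    rng = make_rng(seed)
    pop = Population(rng.random((n, dim)), SearchSpace.unit(dim))
    pop.fitness = np.asarray(fitnesses, dtype=float)
    return sort_and_rank(pop)


class TestSelectRoles:
    def test_roles_come_from_correct_rank_bands(self):
        pop = ranked_population(list(range(10)))
        rng = make_rng(1)
        for _ in range(50):
            best, better, worse, l1, l2 = select_roles(pop, 0, 5, rng)
            assert best.fitness == 0
            assert 1 <= better.fitness <= 4  # ranks 2..P1
            assert 5 <= worse.fitness <= 9  # bottom P1
            assert not np.array_equal(l1.position, l2.position) or l1.fitness != l2.fitness

    def test_random_pair_excludes_self_and_is_distinct(self):
        pop = ranked_population([0.0, 1.0, 2.0, 3.0])
        rng = make_rng(3)
        own = pop.positions[1].copy()
        for _ in range(30):
            _, _, _, l1, l2 = select_roles(pop, 1, 2, rng)
            assert not np.array_equal(l1.position, own)
            assert not np.array_equal(l2.position, own)

    def test_p1_too_large_rejected(self):
        pop = ranked_population([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ConfigurationError):
            select_roles(pop, 0, 4, make_rng(0))


class TestGaps:
    def test_direct_subtraction(self):
        gaps = compute_gaps([1, 1], [0.5, 0.5], [0, 0], [1, 0], [0, 1])
        assert np.allclose(gaps[0], [0.5, 0.5])
        assert np.allclose(gaps[1], [1, 1])
        assert np.allclose(gaps[2], [0.5, 0.5])
        assert np.allclose(gaps[3], [1, -1])

    def test_identical_inputs_zero_gaps(self):
        v = np.ones(3)
        assert np.all(compute_gaps(v, v, v, v, v) == 0)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=15, max_size=15))
    def test_gap1_plus_gap3_equals_gap2(self, flat):
        v = np.array(flat).reshape(5, 3)
        gaps = compute_gaps(*v)
        assert np.allclose(gaps[0] + gaps[2], gaps[1], atol=1e-9)


class TestLearningFactors:
    def test_equal_norms_give_quarter_each(self):
        gaps = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float)
        assert np.allclose(learning_factors(gaps), 0.25)

    def test_normalization(self):
        gaps = np.array([[3, 0], [1, 0], [0, 0], [0, 0]], dtype=float)
        assert np.allclose(learning_factors(gaps), [0.75, 0.25, 0, 0])

    def test_all_zero_policy(self):
        assert np.allclose(learning_factors(np.zeros((4, 3))), 0.25)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=12, max_size=12))
    def test_factors_sum_to_one_whenever_any_gap_nonzero(self, flat):
        gaps = np.array(flat).reshape(4, 3)
        lf = learning_factors(gaps)
        assert lf.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((lf >= 0) & (lf <= 1))


class TestStrengthFactor:
    def test_ratio(self):
        assert strength_factor(0.5, 1.0) == 0.5

    def test_identity_at_max(self):
        assert strength_factor(1.0, 1.0) == 1.0

    def test_zero_max_policy(self):
        assert strength_factor(0.0, 0.0) == 1.0

    def test_gr_above_max_rejected(self):
        with pytest.raises(StateError):
            strength_factor(2.0, 1.0)


class TestKnowledgeAndUpdate:
    def test_substitution(self):
        assert np.allclose(knowledge_acquisition(1.0, 0.5, np.array([2.0, 0.0])), [1, 0])

    def test_zero_strength_absorbs(self):
        assert np.all(knowledge_acquisition(0.0, 0.7, np.ones(3)) == 0)

    def test_update_sums_and_clips(self):
        space = SearchSpace.unit(2)
        ka = [np.array([0.1, 0.0])] * 4
        assert np.allclose(learning_update(np.zeros(2), ka, space), [0.4, 0.0])
        ka_big = [np.array([0.5, 0.0])] * 4
        assert np.allclose(learning_update(np.zeros(2), ka_big, space), [1.0, 0.0])


class TestAcceptance:
    def test_better_candidate_always_kept(self):
        assert accept_individual(0.2, 0.1, False, 0.0, make_rng(0))

    def test_worse_candidate_usually_dropped(self):
        rng = make_rng(0)
        kept = sum(accept_individual(0.1, 0.2, False, 0.004, rng) for _ in range(2000))
        assert kept < 30  # ~ p2 * n

    def test_leader_never_replaced_by_worse(self):
        rng = make_rng(0)
        assert not any(accept_individual(0.1, 0.2, True, 1.0, rng) for _ in range(100))

    def test_unevaluated_raises(self):
        with pytest.raises(StateError):
            accept_individual(float("nan"), 0.1, False, 0.1, make_rng(0))


class TestAttenuation:
    def test_endpoints_and_midpoint(self):
        assert attenuation_go(0, 100) == pytest.approx(1.0)
        assert attenuation_go(100, 100) == pytest.approx(0.01)
        assert attenuation_go(50, 100) == pytest.approx(0.505)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            attenuation_go(101, 100)


class TestReflection:
    def test_p3_zero_is_identity(self):
        space = SearchSpace.unit(4)
        rng = make_rng(5)
        x = rng.random(4)
        top = rng.random((3, 4))
        out = reflection_update(x, top, af=0.5, p3=0.0, space=space, rng=rng)
        assert np.array_equal(out, x)

    def test_full_reinitialization_branch(self):
        # p3=1, af=1: every coordinate freshly uniform in the box
        space = SearchSpace(4, -2.0, -1.0)
        rng = make_rng(5)
        x = np.full(4, -1.5)
        out = reflection_update(x, np.full((2, 4), -1.2), af=1.0, p3=1.0, space=space, rng=rng)
        assert np.all((out >= -2.0) & (out <= -1.0))
        assert not np.array_equal(out, x)

    def test_attraction_branch_is_convex_combination(self):
        space = SearchSpace.unit(4)
        rng = make_rng(11)
        x = np.full(4, 0.2)
        top = np.full((1, 4), 0.8)
        out = reflection_update(x, top, af=0.0, p3=1.0, space=space, rng=rng)
        assert np.all((out >= 0.2) & (out <= 0.8))

    def test_empty_top_block_rejected(self):
        with pytest.raises(StateError):
            reflection_update(
                np.zeros(2), np.empty((0, 2)), 0.5, 0.5, SearchSpace.unit(2), make_rng(0)
            )


class TestRunGo:
    def test_constant_objective(self, unit5, small_cfg):
        res = run_go(lambda x: 3.0, unit5, small_cfg)
        assert res.best_fitness == 3.0
        assert np.all(res.trace == 3.0)
        assert res.evals == 10 + 2 * 10 * 20

    def test_sphere_trace_monotone_and_reproducible(self):
        space = SearchSpace(10, -1, 1)
        cfg = OptimizerConfig.go_defaults(pop_size=20, max_iter=50, seed=3)
        res1 = run_go(sphere, space, cfg)
        res2 = run_go(sphere, space, cfg)
        assert np.all(np.diff(res1.trace) <= 0)
        assert np.array_equal(res1.trace, res2.trace)
        assert res1.best_fitness <= res1.trace[0]

    def test_sphere_convergence_order_of_magnitude(self):
        # median final fitness at least 10x below the median initial best
        space = SearchSpace(10, -1, 1)
        initials, finals = [], []
        for seed in range(10):
            cfg = OptimizerConfig.go_defaults(pop_size=20, max_iter=100, seed=seed)
            res = run_go(sphere, space, cfg)
            initials.append(res.trace[0])
            finals.append(res.best_fitness)
        assert np.median(finals) < np.median(initials) / 10
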