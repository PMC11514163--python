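import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goaoa.core import ConfigurationError
from goaoa.fitness import (
    DatasetSplit,
    FitnessConfig,
    WrapperObjective,
    binarize,
    classification_error,
    exhaustive_best_subset,
    fitness,
)
from conftest import make_split


class TestBinarize:
    @pytest.mark.parametrize(
        "position,expected",
        [
            ([0.6, 0.4, 0.5], [1, 0, 1]),  # threshold includes 0.5 itself
            ([0.49, 0.51], [0, 1]),
            ([0.0, 1.0], [0, 1]),
        ],
    )
    def test_threshold(self, position, expected):
        assert binarize(np.array(position)).tolist() == expected

    def test_empty_mask_forces_largest_coordinate(self):
        assert binarize(np.array([0.1, 0.4, 0.2])).tolist() == [0, 1, 0]

    def test_empty_mask_tie_goes_to_lowest_index(self):
        assert binarize(np.array([0.3, 0.3, 0.1])).tolist() == [1, 0, 0]

    def test_worst_fitness_policy_keeps_empty(self):
        assert binarize(np.array([0.1, 0.2]), policy="worst_fitness").sum() == 0


class TestClassificationError:
    def test_separated_classes_zero_error(self):
        # means 10 sd apart: no 5-NN mistakes at this sample size
        ds, split = make_split(n_features=3, n_informative=1, separation=10.0, n_samples=200)
        err = classification_error(split, np.array([1, 0, 0]))
        assert err == 0.0

    def test_random_labels_error_near_half(self):
        rng = np.random.default_rng(0)
        errs = []
        for rep in range(20):
            X = rng.standard_normal((200, 4))
            y = rng.integers(0, 2, 200)
            split = DatasetSplit(X[:160], y[:160], X[160:], y[160:])
            errs.append(classification_error(split, np.ones(4)))
        assert 0.35 <= np.mean(errs) <= 0.65

    def test_train_equals_test_with_one_neighbor(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 3))
        y = rng.integers(0, 2, 30)
        split = DatasetSplit(X, y, X, y)
        assert classification_error(split, np.ones(3), FitnessConfig(k_neighbors=1)) == 0.0

    def test_empty_mask_scores_one(self):
        _ds, split = make_split()
        assert classification_error(split, np.zeros(split.n_features)) == 1.0

    def test_k_exceeding_train_rejected(self):
        _ds, split = make_split(n_samples=150)
        with pytest.raises(ConfigurationError):
            classification_error(split, np.ones(split.n_features), FitnessConfig(k_neighbors=500))


class TestFitness:
    def test_hand_blend(self):
        """alpha=0.99, E=0.1, 5 of 10 selected -> 0.99*0.1 + 0.01*0.5."""
        class FixedErr(WrapperObjective):
            def error_for_mask(self, mask):
                return 0.1

        _ds, split = make_split(n_features=10, n_samples=150)
        obj = FixedErr(split, FitnessConfig(alpha_weight=0.99))
        position = np.array([0.9] * 5 + [0.1] * 5)
        assert obj(position) == pytest.approx(0.104)

    def test_all_features_alpha_zero(self):
        class ZeroErr(WrapperObjective):
            def error_for_mask(self, mask):
                return 0.0

        _ds, split = make_split(n_features=4)
        obj = ZeroErr(split, FitnessConfig(alpha_weight=0.0))
        assert obj(np.ones(4)) == pytest.approx(1.0)  # pure subset-size penalty

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=8, max_size=8))
    def test_fitness_bounded_in_unit_interval(self, coords):
        _ds, split = make_split()
        value = fitness(np.array(coords), split)
        assert 0.0 <= value <= 1.0

    def test_depends_only_on_threshold_crossing(self):
        _ds, split = make_split()
        a = fitness(np.array([0.6, 0.2, 0.7, 0.1, 0.9, 0.3, 0.51, 0.499]), split)
        b = fitness(np.array([0.9, 0.4, 0.5, 0.0, 0.6, 0.01, 0.99, 0.2]), split)
        assert a == b


class TestWrapperObjective:
    def test_memoization_consistent_with_direct(self):
        _ds, split = make_split()
        obj = WrapperObjective(split)
        pos = np.array([0.8, 0.8, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        assert obj(pos) == fitness(pos, split)
        assert obj(pos) == obj(pos)  # cached second call


class TestExhaustiveOracle:
    def test_enumerates_all_nonempty_subsets(self):
        _ds, split = make_split(n_features=3, n_informative=1, n_samples=100)
        mask, fit = exhaustive_best_subset(split)
        # independent recount by direct enumeration
        obj = WrapperObjective(split)
        fits = {}
        for m in range(1, 8):
            bits = np.array([(m >> j) & 1 for j in range(2, -1, -1)], dtype=np.int8)
            fits[tuple(bits)] = obj.fitness_for_mask(bits)
        assert len(fits) == 7
        assert fit == pytest.approx(min(fits.values()))

    def test_informative_feature_dominates(self):
        ds, split = make_split(n_features=3, n_informative=1, separation=10.0, n_samples=200)
        mask, fit = exhaustive_best_subset(split)
        assert mask.tolist() == [1, 0, 0]
        assert fit == pytest.approx(0.01 * (1 / 3), abs=1e-9)

    def test_tie_prefers_smaller_subset(self):
        # duplicated perfect feature: both singletons tie, the pair loses
        ds, split = make_split(n_features=4, n_informative=1, separation=8.0, n_samples=200)
        split.train_X[:, 1] = split.train_X[:, 0]
        split.test_X[:, 1] = split.test_X[:, 0]
        mask, _fit = exhaustive_best_subset(split)
        assert mask.sum() == 1
        # the tied singletons are {0} and {1}; as bit tuples (0,1,0,0)
        # precedes (1,0,0,0), so the lexicographic rule picks feature 1
        assert mask.tolist() == [0, 1, 0, 0]

    def test_refuses_wide_problems(self):
        _ds, split = make_split(n_features=8)
        with pytest.raises(ConfigurationError):
            exhaustive_best_subset(split, d_max=6)
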