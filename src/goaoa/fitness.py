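"""Wrapper feature-selection objective.

A continuous position in the unit cube is thresholded at 0.5 into a
binary feature mask (``BX``).  The fitness combines the test error of a
k-nearest-neighbour classifier trained on the selected columns with the
fraction of features kept::

    Fit = alpha * E + (1 - alpha) * |BX| / D

with ``alpha`` close to 1 so the error dominates and the feature-count
term breaks ties toward smaller subsets.  Features are min-max scaled
using training-partition statistics before distance computation.  The
module also provides a brute-force subset enumeration used as an
independent optimum oracle on small problems.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .core import ConfigurationError

__all__ = [
    "DatasetSplit",
    "FitnessConfig",
    "binarize",
    "classification_error",
    "fitness",
    "exhaustive_best_subset",
    "WrapperObjective",
]


@dataclass
class DatasetSplit:
    """Stratified train/test partition of one feature table (80/20 by
    default upstream)."""

    train_X: np.ndarray
    train_y: np.ndarray
    test_X: np.ndarray
    test_y: np.ndarray

    def __post_init__(self) -> None:
        self.train_X = np.asarray(self.train_X, dtype=float)
        self.test_X = np.asarray(self.test_X, dtype=float)
        self.train_y = np.asarray(self.train_y)
        self.test_y = np.asarray(self.test_y)
        if self.train_X.shape[1] != self.test_X.shape[1]:
            raise ValueError("train and test must share the feature dimension")

    @property
    def n_features(self) -> int:
        return self.train_X.shape[1]


@dataclass
class FitnessConfig:
    """Objective parameters.

    alpha_weight : trade-off in [0, 1] between classification error and
        selected-feature ratio (default 0.99, error-dominant).
    k_neighbors : KNN neighbourhood size (default 5).
    empty_policy : what to do with an all-zero mask —
        ``"force_max_coordinate"`` switches on the dimension with the
        largest coordinate (lowest index on ties) so the classifier stays
        defined; ``"worst_fitness"`` scores the empty mask as error 1.
    """

    alpha_weight: float = 0.99
    k_neighbors: int = 5
    empty_policy: str = "force_max_coordinate"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_weight <= 1.0:
            raise ConfigurationError("alpha_weight must lie in [0, 1]")
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be >= 1")
        if self.empty_policy not in ("force_max_coordinate", "worst_fitness"):
            raise ConfigurationError(f"unknown empty_policy {self.empty_policy!r}")


def binarize(position: np.ndarray, policy: str = "force_max_coordinate") -> np.ndarray:
    """Threshold a position at 0.5 into a feature mask.

    Under the default policy an all-zero mask gets its largest coordinate
    switched on (lowest index on ties); under ``worst_fitness`` it is
    returned empty and scored maximally downstream.
    """
    position = np.asarray(position, dtype=float)
    mask = (position >= 0.5).astype(np.int8)
    if mask.sum() == 0 and policy == "force_max_coordinate":
        mask[int(np.argmax(position))] = 1
    return mask


def _minmax_scale(train_X: np.ndarray, test_X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    lo = train_X.min(axis=0)
    span = train_X.max(axis=0) - lo
    span[span == 0] = 1.0
    return (train_X - lo) / span, (test_X - lo) / span


def _knn_error(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    k: int,
) -> float:
    clf = KNeighborsClassifier(n_neighbors=k, metric="euclidean", algorithm="brute")
    clf.fit(train_X, train_y)
    return 1.0 - float(clf.score(test_X, test_y))


def classification_error(
    split: DatasetSplit, mask: np.ndarray, cfg: Optional[FitnessConfig] = None
) -> float:
    """Held-out error of a KNN trained on the selected columns.

    Features are min-max scaled with training statistics.  An empty mask
    returns error 1.0 without fitting (``worst_fitness`` semantics).
    """
    cfg = cfg or FitnessConfig()
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        return 1.0
    if cfg.k_neighbors > split.train_X.shape[0]:
        raise ConfigurationError("k_neighbors exceeds the training-set size")
    tr, te = _minmax_scale(split.train_X[:, mask], split.test_X[:, mask])
    return _knn_error(tr, split.train_y, te, split.test_y, cfg.k_neighbors)


def fitness(
    position: np.ndarray, split: DatasetSplit, cfg: Optional[FitnessConfig] = None
) -> float:
    """Wrapper fitness of a continuous position (threshold, error, blend)."""
    cfg = cfg or FitnessConfig()
    mask = binarize(position, cfg.empty_policy)
    err = classification_error(split, mask, cfg)
    return cfg.alpha_weight * err + (1 - cfg.alpha_weight) * mask.sum() / split.n_features


class WrapperObjective:
    """Callable objective over positions, with per-mask memoization.

    The wrapper error is a deterministic function of the binary mask
    given a fixed split, so repeat masks (ubiquitous once the search
    concentrates) are looked up rather than re-fit.  The scaled feature
    matrices are precomputed once.
    """

    def __init__(self, split: DatasetSplit, config: Optional[FitnessConfig] = None):
        self.split = split
        self.config = config or FitnessConfig()
        if self.config.k_neighbors > split.train_X.shape[0]:
            raise ConfigurationError("k_neighbors exceeds the training-set size")
        self.train_X, self.test_X = _minmax_scale(split.train_X, split.test_X)
        self._cache: Dict[bytes, float] = {}
        self.n_features = split.n_features

    def error_for_mask(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask).astype(bool)
        if mask.sum() == 0:
            return 1.0
        key = np.packbits(mask).tobytes()
        err = self._cache.get(key)
        if err is None:
            err = _knn_error(
                self.train_X[:, mask],
                self.split.train_y,
                self.test_X[:, mask],
                self.split.test_y,
                self.config.k_neighbors,
            )
            self._cache[key] = err
        return err

    def fitness_for_mask(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask).astype(np.int8)
        err = self.error_for_mask(mask)
        a = self.config.alpha_weight
        return a * err + (1 - a) * mask.sum() / self.n_features

    def __call__(self, position: np.ndarray) -> float:
        return self.fitness_for_mask(binarize(position, self.config.empty_policy))


def exhaustive_best_subset(
    split: DatasetSplit,
    cfg: Optional[FitnessConfig] = None,
    d_max: int = 12,
) -> Tuple[np.ndarray, float]:
    """Enumerate every non-empty subset and return the fitness minimizer.

    Ties go to the smaller subset, then the lexicographically smallest
    mask.  Refuses problems wider than ``d_max`` features (2^D blow-up);
    this is the independent optimum oracle for small instances, not a
    production selector.
    """
    cfg = cfg or FitnessConfig()
    d = split.n_features
    if d > d_max:
        raise ConfigurationError(f"exhaustive search refused for D={d} > d_max={d_max}")
    objective = WrapperObjective(split, cfg)
    best_key = None
    best_mask = None
    for bits in itertools.product((0, 1), repeat=d):
        mask = np.asarray(bits, dtype=np.int8)
        if mask.sum() == 0:
            continue
        fit = objective.fitness_for_mask(mask)
        key = (fit, int(mask.sum()), bits)
        if best_key is None or key < best_key:
            best_key = key
            best_mask = mask
    return best_mask, best_key[0]
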