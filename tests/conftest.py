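import numpy as np
import pytest

from goaoa import (
    FitnessConfig,
    OptimizerConfig,
    SearchSpace,
    SyntheticSpec,
    WrapperObjective,
    stratified_split,
    synthetic_classification,
)


def sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


@pytest.fixture
def unit5() -> SearchSpace:
    return SearchSpace.unit(5)


@pytest.fixture
def small_cfg() -> OptimizerConfig:
    return OptimizerConfig(pop_size=10, max_iter=20, p1=3, seed=7)


def make_split(n_features=8, n_informative=2, separation=6.0, n_samples=150, seed=0):
    """Ground-truthed split used across fitness/optimizer tests."""
    ds = synthetic_classification(
        SyntheticSpec(
            n_samples=n_samples,
            n_features=n_features,
            n_informative=n_informative,
            class_separation=separation,
            seed=seed,
        )
    )
    return ds, stratified_split(ds, 0.2, seed=seed)


@pytest.fixture
def tiny_objective():
    _ds, split = make_split()
    return WrapperObjective(split, FitnessConfig())
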