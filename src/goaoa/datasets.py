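"""Dataset readers, stratified splitting and synthetic benchmark generators.

Real inputs are delimited text (CSV with a header and one label column)
or dense ARFF.  The synthetic generators produce two kinds of ground-
truthed benchmarks: generic feature tables with a known informative
subset plus pure-noise columns, and high-dimensional "deep feature"
tables emulating embeddings extracted from bone-scintigraphy images by a
compact vision backbone (two balanced classes of Gaussian vectors whose
means differ along one random direction).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff
from sklearn.model_selection import train_test_split

from .fitness import DatasetSplit
from .stats import MetricMatrix

__all__ = [
    "TabularDataset",
    "SyntheticSpec",
    "read_tabular",
    "stratified_split",
    "synthetic_classification",
    "synthetic_deep_features",
    "load_fixture_tables",
]


@dataclass
class TabularDataset:
    """A named feature table with integer-coded labels.

    ``informative`` records the ground-truth informative column indices
    for synthetic data (None for real tables).
    """

    name: str
    X: np.ndarray
    y: np.ndarray
    feature_names: Optional[Sequence[str]] = None
    informative: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        classes, counts = np.unique(self.y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("a classification dataset needs >= 2 classes")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def _encode_frame(df: pd.DataFrame, name: str, label_column) -> TabularDataset:
    if isinstance(label_column, int) and label_column not in df.columns:
        label_column = df.columns[label_column]
    if label_column not in df.columns:
        raise KeyError(f"label column {label_column!r} not found in {list(df.columns)}")
    y_raw = df[label_column]
    feats = df.drop(columns=[label_column])
    # drop incomplete rows rather than impute; UCI-style tables are near-complete
    keep = feats.notna().all(axis=1) & y_raw.notna()
    feats, y_raw = feats[keep], y_raw[keep]
    cols = []
    for col in feats.columns:
        series = feats[col]
        if series.dtype == object or str(series.dtype) == "category":
            series = pd.Series(pd.factorize(series, sort=True)[0], index=series.index)
        cols.append(pd.to_numeric(series))
    X = pd.concat(cols, axis=1).to_numpy(dtype=float)
    y = pd.factorize(y_raw, sort=True)[0]
    return TabularDataset(name, X, y, feature_names=list(feats.columns))


def read_tabular(
    path: str,
    label_column="label",
    fmt: Optional[str] = None,
    delimiter: str = ",",
) -> TabularDataset:
    """Load a CSV (header row) or dense ARFF classification table.

    Numeric features are kept as-is; categorical/nominal ones are
    integer-coded (sorted order).  Rows with missing entries are dropped.
    ``fmt`` defaults from the file extension.
    """
    path = str(path)
    if fmt is None:
        fmt = "arff" if path.lower().endswith(".arff") else "csv"
    name = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    if fmt == "csv":
        df = pd.read_csv(path, delimiter=delimiter)
    elif fmt == "arff":
        data, _meta = scipy_arff.loadarff(path)
        df = pd.DataFrame(data)
        for col in df.columns:  # scipy returns nominal fields as bytes
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _encode_frame(df, name, label_column)


def stratified_split(
    ds: TabularDataset, test_fraction: float = 0.2, seed: Optional[int] = None
) -> DatasetSplit:
    """Per-class proportional train/test split (80/20 default)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    _classes, counts = np.unique(ds.y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 instances for stratification")
    tr_X, te_X, tr_y, te_y = train_test_split(
        ds.X,
        ds.y,
        test_size=test_fraction,
        stratify=ds.y,
        random_state=None if seed is None else int(seed),
    )
    return DatasetSplit(tr_X, tr_y, te_X, te_y)


@dataclass
class SyntheticSpec:
    """Recipe for a ground-truthed synthetic classification table.

    ``class_separation`` is the distance between the two class means in
    each informative column (in units of ``noise_sd``); the remaining
    ``n_features - n_informative`` columns are standard normal noise
    independent of the class.
    """

    n_samples: int = 300
    n_features: int = 20
    n_informative: int = 5
    class_separation: float = 4.0
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")


def synthetic_classification(spec: SyntheticSpec) -> TabularDataset:
    """Two-class Gaussian table with a known informative subset.

    Informative columns have class-conditional means of minus/plus
    ``class_separation/2`` (sd ``noise_sd``); noise columns are standard
    normal.  Identical spec + seed reproduces the table bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n_samples * (1 - spec.class_balance)))
    y = np.concatenate([np.zeros(n1, dtype=int), np.ones(spec.n_samples - n1, dtype=int)])
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    informative = np.arange(spec.n_informative)
    shift = spec.class_separation / 2.0
    X[:, informative] = X[:, informative] * spec.noise_sd
    X[np.ix_(y == 0, informative)] -= shift
    X[np.ix_(y == 1, informative)] += shift
    perm = rng.permutation(spec.n_samples)
    return TabularDataset(
        name=f"synthetic(k={spec.n_informative},D={spec.n_features})",
        X=X[perm],
        y=y[perm],
        informative=informative,
    )


def synthetic_deep_features(
    n_per_class: int = 1400,
    dim: int = 256,
    separation: float = 8.0,
    seed: Optional[int] = None,
) -> TabularDataset:
    """Emulated deep-feature vectors for normal/abnormal bone scans.

    Two balanced classes of ``dim``-dimensional unit Gaussians whose
    means differ by a vector of magnitude ``separation`` along a seeded
    random direction — so the problem projects onto a one-dimensional
    two-Gaussian discrimination of that difficulty.  Defaults mirror a
    1400 + 1400 cohort with 256-dimensional embeddings.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(dim)
    direction /= np.linalg.norm(direction)
    shift = direction * separation / 2.0
    X0 = rng.standard_normal((n_per_class, dim)) - shift
    X1 = rng.standard_normal((n_per_class, dim)) + shift
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)])
    perm = rng.permutation(2 * n_per_class)
    return TabularDataset(
        name=f"deep_features(dim={dim})", X=X[perm], y=y[perm], informative=None
    )


_FIXTURES = {
    "accuracy": ("accuracy.tsv", True),
    "sensitivity": ("sensitivity.tsv", True),
    "specificity": ("specificity.tsv", True),
}


def load_fixture_tables(which: str) -> MetricMatrix:
    """Published benchmark matrices (algorithms x UCI datasets).

    ``which`` is one of ``accuracy``, ``sensitivity``, ``specificity``.
    Accuracy and sensitivity cover 13 datasets, specificity 12; values
    are the printed three-decimal figures, transcribed verbatim.
    """
    try:
        fname, higher = _FIXTURES[which]
    except KeyError:
        raise ValueError(f"unknown fixture table {which!r}") from None
    text = resources.files("goaoa").joinpath("fixtures", fname).read_text()
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    return MetricMatrix(df, higher_is_better=higher)
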