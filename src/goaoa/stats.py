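"""Evaluation statistics: classification metrics, run summaries,
Friedman mean ranks and parameter sweeps.

The Friedman analysis here follows the benchmark-comparison convention
of the metaheuristic literature: within each dataset the m algorithms
receive ranks 1..m with the *larger* metric getting the *larger* rank
(midranks on ties), and the mean over datasets is reported per
algorithm, so the best method carries the highest mean rank.  Note many
statistics textbooks rank in the opposite direction; the
``higher_is_better`` flag makes the convention explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConfusionCounts",
    "MetricMatrix",
    "RankSummary",
    "confusion_metrics",
    "confusion_from_predictions",
    "std",
    "avg",
    "summarize_runs",
    "friedman_mean_ranks",
    "parameter_sweep",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary-classification cell counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("confusion counts are all zero")


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from cell counts.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP).  A zero denominator raises, naming the
    metric.
    """
    total = c.tp + c.tn + c.fp + c.fn
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive instances")
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative instances")
    return (
        (c.tp + c.tn) / total,
        c.tp / (c.tp + c.fn),
        c.tn / (c.tn + c.fp),
    )


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, positive: int = 1
) -> ConfusionCounts:
    """Count confusion cells treating ``positive`` as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def std(values: Sequence[float]) -> float:
    """Sample standard deviation (N-1 denominator)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("std needs at least two observations")
    return float(np.std(values, ddof=1))


def avg(values: Sequence[float]) -> float:
    """Arithmetic mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("avg needs at least one observation")
    return float(np.mean(values))


def summarize_runs(fitness_per_run: Sequence[float]) -> Dict[str, float]:
    """Min/Max/Avg/Std of the objective over repeated runs — the summary
    row reported per algorithm per dataset in benchmark tables."""
    values = np.asarray(fitness_per_run, dtype=float)
    if values.size < 2:
        raise ValueError("summaries need at least two runs")
    return {
        "min": float(values.min()),
        "max": float(values.max()),
        "avg": avg(values),
        "std": std(values),
    }


class MetricMatrix:
    """An algorithms x datasets performance table.

    Thin wrapper over a pandas DataFrame (index = algorithms, columns =
    datasets) carrying the rank direction.  Serialized as tab-delimited
    text with a header row and row labels.
    """

    def __init__(self, values: pd.DataFrame, higher_is_better: bool = True):
        if values.isna().any().any():
            raise ValueError("metric matrix has missing cells")
        if values.shape[0] < 2 or values.shape[1] < 2:
            raise ValueError("need >= 2 algorithms and >= 2 datasets")
        self.values = values.astype(float)
        self.higher_is_better = higher_is_better

    @property
    def algorithms(self) -> list:
        return list(self.values.index)

    @property
    def datasets(self) -> list:
        return list(self.values.columns)

    @classmethod
    def from_rows(
        cls,
        algorithms: Sequence[str],
        datasets: Sequence[str],
        values: np.ndarray,
        higher_is_better: bool = True,
    ) -> "MetricMatrix":
        df = pd.DataFrame(np.asarray(values, float), index=list(algorithms), columns=list(datasets))
        return cls(df, higher_is_better)

    @classmethod
    def read(cls, path: str, higher_is_better: bool = True) -> "MetricMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.isna().any().any():
            raise ValueError(f"ragged or incomplete metric matrix in {path}")
        return cls(df, higher_is_better)

    def write(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class RankSummary:
    """Friedman mean ranks per algorithm, plus the chi-square test."""

    mean_rank: pd.Series
    chi2: float
    pvalue: float

    def __getitem__(self, algorithm: str) -> float:
        return float(self.mean_rank[algorithm])


def friedman_mean_ranks(m: MetricMatrix) -> RankSummary:
    """Mean within-dataset ranks (midranks on ties) per algorithm.

    With ``higher_is_better`` the best algorithm receives rank m within
    each dataset; ranks per dataset always sum to m(m+1)/2.  The
    chi-square statistic and p-value of the Friedman test (with the
    standard tie correction) are attached for reference.
    """
    arr = m.values.to_numpy()
    if not m.higher_is_better:
        arr = -arr
    # rank within each dataset (column-wise over algorithms)
    ranks = np.apply_along_axis(sps.rankdata, 0, arr)
    mean_rank = pd.Series(ranks.mean(axis=1), index=m.values.index)
    if arr.shape[0] >= 3:  # the chi-square test needs >= 3 groups
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2, pvalue = sps.friedmanchisquare(*[arr[i] for i in range(arr.shape[0])])
    else:
        chi2, pvalue = float("nan"), float("nan")
    return RankSummary(mean_rank=mean_rank, chi2=float(chi2), pvalue=float(pvalue))


def parameter_sweep(
    param: str,
    values: Sequence,
    splits: Mapping[str, "DatasetSplit"],
    base_config,
    runner: Optional[Callable] = None,
    fitness_config=None,
    seed: Optional[int] = None,
) -> Dict[str, pd.DataFrame]:
    """Re-run the optimizer across a one-parameter grid.

    For each grid value the named ``OptimizerConfig`` field is replaced,
    the optimizer is run once per dataset (seeded deterministically per
    grid point), and accuracy/sensitivity/specificity of the selected
    subset are tabulated.  Returns one ``datasets x metrics`` frame per
    grid value plus an ``"average"`` frame of per-value means — the
    layout of published parameter-analysis tables.
    """
    from dataclasses import replace

    from .fitness import FitnessConfig, WrapperObjective
    from .hybrid import run_goaoa
    from .model import mask_test_metrics
    from .core import SearchSpace

    if len(values) == 0:
        raise ValueError("empty parameter grid")
    runner = runner or run_goaoa
    fitness_config = fitness_config or FitnessConfig()
    out: Dict[str, pd.DataFrame] = {}
    averages = {}
    for value in values:
        cfg = replace(base_config, **{param: value})
        rows = {}
        for ds_name, split in splits.items():
            objective = WrapperObjective(split, fitness_config)
            run_cfg = cfg.with_seed(seed)
            result = runner(objective, SearchSpace.unit(split.n_features), run_cfg)
            rows[ds_name] = mask_test_metrics(split, result.best_mask, fitness_config)
        frame = pd.DataFrame(rows).T[["accuracy", "sensitivity", "specificity"]]
        out[str(value)] = frame
        averages[str(value)] = frame.mean()
    out["average"] = pd.DataFrame(averages).T
    return out
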