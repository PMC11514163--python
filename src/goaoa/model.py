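"""Model/Results front end for wrapper feature selection.

:class:`WrapperSelectionModel` is built from a feature table and labels,
holds the stratified split and the optimizer/fitness configuration, and
``fit()`` runs the chosen metaheuristic (GO, AOA, the GOAOA hybrid, or
any plugged-in optimizer with the same signature), returning a
:class:`WrapperSelectionResults` with the selected subset, the fitness
trace, repeated-run summaries and held-out classification metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier

from .aoa import run_aoa
from .core import OptimizerConfig, RunResult, SearchSpace
from .datasets import TabularDataset, stratified_split
from .fitness import DatasetSplit, FitnessConfig, WrapperObjective, _minmax_scale
from .go import run_go
from .hybrid import run_goaoa
from .stats import confusion_from_predictions, confusion_metrics, summarize_runs

__all__ = ["WrapperSelectionModel", "WrapperSelectionResults", "mask_test_metrics", "ALGORITHMS"]

ALGORITHMS: Dict[str, Callable] = {
    "go": run_go,
    "aoa": run_aoa,
    "goaoa": run_goaoa,
}


def mask_test_metrics(
    split: DatasetSplit, mask: np.ndarray, cfg: Optional[FitnessConfig] = None
) -> Dict[str, float]:
    """Accuracy/sensitivity/specificity of a KNN restricted to ``mask``,
    scored on the held-out partition (class 1 is the positive class)."""
    cfg = cfg or FitnessConfig()
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("cannot score an empty feature subset")
    tr, te = _minmax_scale(split.train_X[:, mask], split.test_X[:, mask])
    clf = KNeighborsClassifier(n_neighbors=cfg.k_neighbors, metric="euclidean", algorithm="brute")
    clf.fit(tr, split.train_y)
    pred = clf.predict(te)
    acc, sens, spec = confusion_metrics(confusion_from_predictions(split.test_y, pred))
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


class WrapperSelectionModel:
    """Wrapper feature selection posed as a fittable model.

    Parameters
    ----------
    X, y : feature matrix and labels (any hashable labels; integer-coded
        internally by the dataset layer when loaded from disk).
    algorithm : "go", "aoa", "goaoa" or a callable
        ``optimizer(objective, space, config) -> RunResult``.
    config : optimizer parameters; defaults to the published hybrid
        settings (and to the GO settings when ``algorithm="go"``).
    fitness : objective parameters (error/subset-size trade-off, KNN k).
    test_fraction : held-out share of rows, stratified per class (0.2).
    split_seed : seed of the train/test partition; defaults to the fit
        seed so one integer reproduces the whole experiment.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        *,
        algorithm: Union[str, Callable] = "goaoa",
        config: Optional[OptimizerConfig] = None,
        fitness: Optional[FitnessConfig] = None,
        test_fraction: float = 0.2,
        split_seed: Optional[int] = None,
        feature_names: Optional[Sequence[str]] = None,
    ):
        self.dataset = TabularDataset("model", X, y, feature_names=feature_names)
        if callable(algorithm):
            self.algorithm_name = getattr(algorithm, "__name__", "plugin")
            self._runner = algorithm
        else:
            if algorithm not in ALGORITHMS:
                raise ValueError(
                    f"unknown algorithm {algorithm!r}; expected one of {sorted(ALGORITHMS)} or a callable"
                )
            self.algorithm_name = algorithm
            self._runner = ALGORITHMS[algorithm]
        if config is None:
            config = (
                OptimizerConfig.go_defaults()
                if self.algorithm_name == "go"
                else OptimizerConfig.goaoa_defaults()
            )
        self.config = config
        self.fitness_config = fitness or FitnessConfig()
        self.test_fraction = test_fraction
        self.split_seed = split_seed
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{j}" for j in range(self.dataset.n_features)]
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label: str, **kwargs
    ) -> "WrapperSelectionModel":
        """Build from a DataFrame with a named label column."""
        y = df[label].to_numpy()
        feats = df.drop(columns=[label])
        return cls(feats.to_numpy(dtype=float), y, feature_names=list(feats.columns), **kwargs)

    @classmethod
    def from_dataset(cls, ds: TabularDataset, **kwargs) -> "WrapperSelectionModel":
        kwargs.setdefault("feature_names", ds.feature_names)
        return cls(ds.X, ds.y, **kwargs)

    def fit(self, seed: Optional[int] = None, n_runs: int = 1) -> "WrapperSelectionResults":
        """Run the optimizer ``n_runs`` times (seeds ``seed, seed+1, ...``)
        and return results built around the best run."""
        if n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        split_seed = self.split_seed if self.split_seed is not None else seed
        split = stratified_split(self.dataset, self.test_fraction, seed=split_seed)
        objective = WrapperObjective(split, self.fitness_config)
        space = SearchSpace.unit(self.dataset.n_features)
        runs: List[RunResult] = []
        for r in range(n_runs):
            run_seed = None if seed is None else seed + r
            runs.append(self._runner(objective, space, self.config.with_seed(run_seed)))
        return WrapperSelectionResults(model=self, split=split, runs=runs)


@dataclass
class WrapperSelectionResults:
    """Fitted feature-selection results.

    ``runs`` holds every seeded run; scalar attributes describe the best
    one (lowest final fitness, first on ties).
    """

    model: WrapperSelectionModel
    split: DatasetSplit
    runs: List[RunResult]
    _metrics: Optional[Dict[str, float]] = field(default=None, repr=False)

    @property
    def best_run(self) -> RunResult:
        return min(self.runs, key=lambda r: r.best_fitness)

    @property
    def mask(self) -> np.ndarray:
        """Selected-feature mask of the best run, with the objective's
        empty-subset policy applied (a best position may sit entirely
        below the 0.5 threshold)."""
        from .fitness import binarize

        return binarize(
            self.best_run.best_position, self.model.fitness_config.empty_policy
        )

    @property
    def support(self) -> np.ndarray:
        """Indices of the selected features."""
        return np.flatnonzero(self.mask)

    @property
    def selected_features(self) -> List[str]:
        return [self.model.feature_names[j] for j in self.support]

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    @property
    def fitness(self) -> float:
        return self.best_run.best_fitness

    @property
    def trace(self) -> np.ndarray:
        return self.best_run.trace

    @property
    def fitness_summary(self) -> Dict[str, float]:
        """Min/Max/Avg/Std of the final fitness across runs (Std is NaN
        for a single run)."""
        finals = [r.best_fitness for r in self.runs]
        if len(finals) >= 2:
            return summarize_runs(finals)
        return {"min": finals[0], "max": finals[0], "avg": finals[0], "std": float("nan")}

    @property
    def test_metrics(self) -> Dict[str, float]:
        """Held-out accuracy/sensitivity/specificity of the selected subset."""
        if self._metrics is None:
            self._metrics = mask_test_metrics(self.split, self.mask, self.model.fitness_config)
        return self._metrics

    def baseline_error(self) -> float:
        """Held-out KNN error using all features (no selection)."""
        full = np.ones(self.model.dataset.n_features, dtype=np.int8)
        return 1.0 - mask_test_metrics(self.split, full, self.model.fitness_config)["accuracy"]

    def summary(self) -> str:
        """Plain-text report in the spirit of statsmodels results."""
        m = self.test_metrics
        s = self.fitness_summary
        d = self.model.dataset.n_features
        lines = [
            "Wrapper Feature Selection Results",
            "=" * 46,
            f"algorithm:           {self.model.algorithm_name}",
            f"features:            {self.n_selected} selected of {d}",
            f"best fitness:        {self.fitness:.6g}",
            f"runs:                {len(self.runs)}"
            + (
                f"  (min {s['min']:.6g}, max {s['max']:.6g}, avg {s['avg']:.6g}, std {s['std']:.3g})"
                if len(self.runs) > 1
                else ""
            ),
            f"evaluations/run:     {self.best_run.evals}",
            f"test accuracy:       {m['accuracy']:.4f}",
            f"test sensitivity:    {m['sensitivity']:.4f}",
            f"test specificity:    {m['specificity']:.4f}",
            f"selected features:   {', '.join(self.selected_features)}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Best-fitness convergence trace(s); one line per run."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        for i, run in enumerate(self.runs):
            ax.plot(run.trace, label=f"run {i}", lw=1)
        ax.set_xlabel("iteration")
        ax.set_ylabel("best fitness")
        ax.set_title(f"{self.model.algorithm_name} convergence")
        if len(self.runs) > 1:
            ax.legend(fontsize="small")
        return ax
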