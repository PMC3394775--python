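"""Two-level external cross-validation and cross-method comparisons.

The harness re-runs feature selection inside every training fold (external
CV): the selector and the classifier only ever see training rows, so no
test-fold information can leak into gene selection or model fitting.  An
optional nested inner CV performs hyperparameter grid search on the
training fold alone (the second level).

Method comparisons follow the average-rank convention: within each block
(a dataset x selector cell, say) methods are ranked by decreasing accuracy
with mid-ranks for ties, the per-method ranks are averaged over blocks,
and a Friedman test (with tie correction) assesses whether the methods
differ; Holm's step-down procedure adjusts post-hoc pairwise p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionDataset, FoldPlan, make_fold_plan
from .rules import LearnerParams, RuleEnsemble
from .selection import FeatureSet
from . import evolve


class Classifier(Protocol):
    """fit/predict contract the CV harness expects."""

    def fit(self, train: ExpressionDataset) -> "Classifier": ...

    def predict(self, values: np.ndarray, genes: list[str]) -> np.ndarray: ...


class RuleLearnerClassifier:
    """Ensemble of evolutionary decision lists behind the harness contract."""

    def __init__(self, learner: str = "biohel", params: LearnerParams | None = None,
                 n_members: int = 100, base_seed: int = 0):
        self.learner = learner
        self.params = params
        self.n_members = n_members
        self.base_seed = base_seed
        self.ensemble: RuleEnsemble | None = None

    def fit(self, train: ExpressionDataset) -> "RuleLearnerClassifier":
        self.ensemble = evolve.train_ensemble(
            train, learner=self.learner, params=self.params,
            n_members=self.n_members, base_seed=self.base_seed,
        )
        return self

    def predict(self, values: np.ndarray, genes: list[str]) -> np.ndarray:
        assert self.ensemble is not None, "fit before predict"
        return self.ensemble.predict(values, genes)


class SklearnClassifier:
    """Adapter plugging any sklearn-style estimator into the harness."""

    def __init__(self, estimator):
        self.estimator = estimator
        self._genes: list[str] | None = None

    def fit(self, train: ExpressionDataset) -> "SklearnClassifier":
        self._genes = train.genes
        self.estimator.fit(train.values, train.label_array().astype(str))
        return self

    def predict(self, values: np.ndarray, genes: list[str]) -> np.ndarray:
        if genes != self._genes:
            raise ValueError("test columns do not match training columns")
        return np.asarray(self.estimator.predict(values), dtype=object)


class MajorityClassifier:
    """Baseline: always the majority training class (ties lexicographic)."""

    def fit(self, train: ExpressionDataset) -> "MajorityClassifier":
        y = train.label_array().astype(str)
        classes, counts = np.unique(y, return_counts=True)
        tied = sorted(classes[counts == counts.max()])
        self._class = tied[0]
        return self

    def predict(self, values: np.ndarray, genes: list[str]) -> np.ndarray:
        return np.full(values.shape[0], self._class, dtype=object)


@dataclass
class CVResult:
    """Per-fold accuracies (percent) plus selections and predictions."""

    fold_accuracies: list[float]
    selected: list[FeatureSet | None]
    predictions: dict[str, str]
    scheme: str
    seed: int
    avg: float = field(init=False)
    stddev: float = field(init=False)

    def __post_init__(self) -> None:
        self.avg, self.stddev = accuracy_stats(self.fold_accuracies)
        if not 0.0 <= self.avg <= 100.0:
            raise ValueError("average accuracy outside [0,100]")


class FoldError(RuntimeError):
    pass


Selector = Callable[[ExpressionDataset], FeatureSet]


def external_cv(
    dataset: ExpressionDataset,
    fold_plan: FoldPlan,
    classifier_factory: Callable[[], Classifier],
    selector: Selector | None = None,
) -> CVResult:
    """External CV: selector and classifier see training rows only.

    Per fold, the selector (if any) runs on the training samples, the
    classifier trains on the selected gene columns, and the held-out
    samples are predicted.  ``selector=None`` trains on all genes.
    """
    accs: list[float] = []
    selections: list[FeatureSet | None] = []
    predictions: dict[str, str] = {}
    for f, (train_idx, test_idx) in enumerate(fold_plan.folds()):
        train_ds = dataset.subset_samples(train_idx)
        genes = dataset.genes
        fs = None
        if selector is not None:
            fs = selector(train_ds)
            if not fs.genes:
                raise FoldError(f"fold {f}: selector returned no features")
            genes = fs.genes
            train_ds = train_ds.subset_genes(genes)
        try:
            model = classifier_factory().fit(train_ds)
            test_ds = dataset.subset_samples(test_idx).subset_genes(genes)
            pred = model.predict(test_ds.values, test_ds.genes)
        except Exception as exc:  # noqa: BLE001 - report the failing fold
            raise FoldError(f"fold {f}: {exc}") from exc
        truth = test_ds.label_array().astype(str)
        accs.append(float((np.asarray(pred, dtype=object).astype(str) == truth).mean()) * 100.0)
        selections.append(fs)
        for s, c in zip(test_ds.samples, pred):
            predictions[s] = str(c)
    return CVResult(fold_accuracies=accs, selected=selections,
                    predictions=predictions, scheme=fold_plan.scheme,
                    seed=fold_plan.seed)


def nested_param_search(
    train_fold: ExpressionDataset,
    classifier_family: Callable[[dict], Callable[[], Classifier]],
    grid: list[dict],
    inner_k: int = 5,
    seed: int = 0,
) -> dict:
    """Inner stratified CV on the training fold only; best grid point wins.

    Ties go to the first point in declared grid order.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    inner_plan = make_fold_plan(train_fold.labels, scheme="k-fold",
                                k=inner_k, seed=seed, samples=train_fold.samples)
    best_params, best_acc = None, -np.inf
    for point in grid:
        res = external_cv(train_fold, inner_plan, classifier_family(point))
        if res.avg > best_acc:
            best_params, best_acc = point, res.avg
    return best_params


def accuracy_stats(per_fold_accuracies: list[float]) -> tuple[float, float]:
    """(mean, sample SD) of per-fold accuracies on the 0-100 scale.

    A single fold has SD 0 by convention.  Report tables round to whole
    percent; the returned values keep full precision.
    """
    a = np.asarray(per_fold_accuracies, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one fold")
    return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0


@dataclass
class RankTable:
    """Per-block and average ranks of methods, with the Friedman test."""

    table: pd.DataFrame            # blocks x methods accuracies
    ranks: pd.DataFrame            # blocks x methods ranks (1 = best)
    average_ranks: pd.Series       # per-method mean rank over blocks
    statistic: float
    p_value: float


def friedman_average_ranks(accuracy_table: pd.DataFrame) -> RankTable:
    """Rank methods within each block (1 = highest accuracy, mid-ranks for
    ties), average over blocks, and run the Friedman test.

    Raises on missing cells, naming the block and method.
    """
    tbl = accuracy_table.astype(float)
    if tbl.shape[0] < 2 or tbl.shape[1] < 2:
        raise ValueError("need at least 2 blocks and 2 methods")
    if tbl.isna().any().any():
        block = tbl.index[tbl.isna().any(axis=1)][0]
        method = tbl.columns[tbl.isna().any(axis=0)][0]
        raise ValueError(f"missing accuracy for block {block!r}, method {method!r}")
    ranks = tbl.apply(lambda row: stats.rankdata(-row.to_numpy(), method="average"),
                      axis=1, result_type="expand")
    ranks.columns = tbl.columns
    avg = ranks.mean(axis=0)
    m = tbl.shape[1]
    if m >= 3:
        with np.errstate(invalid="ignore"):
            statistic, p_value = stats.friedmanchisquare(*[tbl[c] for c in tbl.columns])
        if np.isnan(statistic):  # every block fully tied: no evidence at all
            statistic, p_value = 0.0, 1.0
    else:
        # two methods: untied chi-square form (tie correction not needed for
        # the m=2 case in our use; scipy requires m >= 3)
        n = tbl.shape[0]
        statistic = 12.0 * n / (m * (m + 1)) * float(((avg - (m + 1) / 2) ** 2).sum())
        p_value = float(stats.chi2.sf(statistic, df=m - 1))
    return RankTable(table=tbl, ranks=ranks, average_ranks=avg,
                     statistic=float(statistic), p_value=float(p_value))


def holm_adjust(pairwise_pvalues: list[float], alpha: float = 0.05
                ) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjustment: (adjusted p-values, reject flags).

    Adjusted p-values are monotone and capped at 1; rejection compares the
    i-th smallest p against alpha/(m-i+1) and stops at the first failure.
    """
    p = np.asarray(pairwise_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return adjusted, reject
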