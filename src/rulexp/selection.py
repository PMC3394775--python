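"""Feature selection for two-class expression data.

Three selectors of different character are provided:

* :func:`plss_rank` — univariate ranking by the one-way ANOVA F statistic,
  which orders genes identically to the absolute first-component weights of
  a partial-least-squares fit (an optional ``mode="pls"`` computes the PLS
  weights instead).
* :func:`cfs_select` — correlation-based feature selection: a best-first
  search over subsets scored by the CFS merit
  ``k * r_cf / sqrt(k + k(k-1) * r_ff)``, which rewards correlation with
  the class and penalises redundancy among the chosen genes.
* :func:`rfs_rank` — embedded selection by random-forest mean decrease in
  Gini impurity.

All selectors respect a maximum subset size (default 30) to limit model
complexity and false-positive gene inclusion.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier

from .data import ExpressionDataset

log = logging.getLogger(__name__)

MAX_FEATURES = 30


@dataclass
class FeatureRanking:
    """Genes ordered by decreasing score; ties broken by gene identifier."""

    genes: list[str]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("one score per gene required")
        if np.any(np.diff(self.scores[np.isfinite(self.scores)]) > 1e-12):
            # +inf sentinels sit at the front; the finite tail must be sorted
            raise ValueError("scores must be non-increasing in rank order")


@dataclass
class FeatureSet:
    """Unordered selected genes, bounded by ``max_size``."""

    genes: list[str]
    method: str
    max_size: int = MAX_FEATURES

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in feature set")
        if len(self.genes) > self.max_size:
            raise ValueError(f"{len(self.genes)} genes exceed max_size={self.max_size}")
        self.genes = sorted(self.genes)


def _ranked(genes: list[str], scores: np.ndarray, method: str) -> FeatureRanking:
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return FeatureRanking(
        genes=[genes[i] for i in order], scores=scores[order], method=method
    )


def f_statistic(values: np.ndarray, labels: np.ndarray | list[str]) -> float:
    """One-way ANOVA F for two groups (equals the squared pooled-variance t).

    Conventions: a gene constant across all samples scores 0; zero
    within-group variance with non-zero between-group variance scores
    ``+inf`` (a perfect separator, ranked first).
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=object)
    classes = np.unique(y.astype(str))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    a, b = values[y.astype(str) == classes[0]], values[y.astype(str) == classes[1]]
    return float(_f_from_groups(a[None, :], b[None, :])[0])


def _f_from_groups(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorised two-group F over rows (one row per gene)."""
    n1, n2 = A.shape[1], B.shape[1]
    m1, m2 = A.mean(axis=1), B.mean(axis=1)
    ss_within = ((A - m1[:, None]) ** 2).sum(axis=1) + ((B - m2[:, None]) ** 2).sum(axis=1)
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ss_between = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    df_within = n1 + n2 - 2
    out = np.zeros(A.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / 1.0) / (ss_within / df_within)
    nonzero_between = ss_between > 0
    out[nonzero_between & (ss_within > 0)] = f[nonzero_between & (ss_within > 0)]
    out[nonzero_between & (ss_within == 0)] = np.inf
    return out


def plss_rank(dataset: ExpressionDataset, mode: str = "f") -> FeatureRanking:
    """Univariate gene ranking by decreasing F statistic.

    ``mode="pls"`` ranks by the absolute weights of the first PLS latent
    component instead; the two orderings agree (up to ties) for two-class
    data, the F route is simply the direct computation.
    """
    dataset.require_two_classes()
    y = dataset.label_array().astype(str)
    classes = sorted(set(y))
    if mode == "pls":
        ybin = (y == classes[1]).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls = PLSRegression(n_components=1, scale=True).fit(dataset.values, ybin)
        scores = np.abs(pls.x_weights_[:, 0])
    elif mode == "f":
        A = dataset.values[y == classes[0]].T
        B = dataset.values[y == classes[1]].T
        scores = _f_from_groups(A, B)
    else:
        raise ValueError(f"unknown PLSS mode {mode!r}")
    return _ranked(dataset.genes, scores, method="plss")


def cfs_merit(k: int, r_cf: float, r_ff: float) -> float:
    """CFS subset merit ``k*r_cf / sqrt(k + k(k-1)*r_ff)``.

    ``r_cf`` is the mean absolute feature-class correlation over the subset
    and ``r_ff`` the mean absolute feature-feature correlation over distinct
    pairs (0 by convention for k=1).  Correlations must be absolute-valued
    before averaging.
    """
    if k < 1:
        raise ValueError("subset size k must be >= 1")
    if not (0 <= r_cf <= 1 and 0 <= r_ff <= 1):
        raise ValueError("correlation averages must lie in [0,1] (take absolute values)")
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = np.zeros_like(X)
    ok = sd > 0
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return Z


def class_correlations(dataset: ExpressionDataset) -> np.ndarray:
    """|point-biserial| correlation of every gene with the 0/1 class code."""
    dataset.require_two_classes()
    y = dataset.label_array().astype(str)
    ybin = (y == sorted(set(y))[1]).astype(float)
    ys = ybin - ybin.mean()
    sd = ys.std()
    if sd == 0:
        raise ValueError("class labels are constant")
    ys /= sd
    Z = _standardize(dataset.values)
    return np.abs(Z.T @ ys) / dataset.n_samples


def cfs_select(
    dataset: ExpressionDataset,
    max_size: int = MAX_FEATURES,
    stall: int = 5,
    max_expansions: int = 1000,
) -> FeatureSet:
    """Best-first search over gene subsets scored by the CFS merit.

    Feature-class correlation is the absolute point-biserial correlation
    with a 0/1 class code; feature-feature correlation is absolute Pearson.
    The search expands the best open subset by adding one gene at a time,
    and stops after ``stall`` consecutive expansions that fail to improve
    the best merit seen, or when subsets reach ``max_size``.  The best
    subset visited is returned and may be (much) smaller than ``max_size``.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    rcf = class_correlations(dataset)
    Z = _standardize(dataset.values)
    n, p = Z.shape
    corr_rows: dict[int, np.ndarray] = {}

    def corr_row(g: int) -> np.ndarray:
        if g not in corr_rows:
            corr_rows[g] = np.abs(Z.T @ Z[:, g]) / n
        return corr_rows[g]

    # nodes: (-merit, tiebreak, members tuple, sum_rcf, pair_sum)
    counter = itertools.count()
    open_heap: list[tuple[float, int, tuple[int, ...], float, float]] = []
    for g in range(p):
        heapq.heappush(open_heap, (-rcf[g], next(counter), (g,), float(rcf[g]), 0.0))
    best_merit, best_members = -np.inf, ()
    visited: set[tuple[int, ...]] = set()
    stall_count = expansions = 0
    while open_heap and stall_count < stall and expansions < max_expansions:
        neg_merit, _, members, sum_rcf, pair_sum = heapq.heappop(open_heap)
        if members in visited:
            continue
        visited.add(members)
        if -neg_merit > best_merit:
            best_merit, best_members = -neg_merit, members
        if len(members) >= max_size:
            continue
        expansions += 1
        improved = False
        member_set = set(members)
        rows = np.stack([corr_row(m) for m in members])  # |S| x p
        add_pair = rows.sum(axis=0)
        k = len(members) + 1
        for g in range(p):
            if g in member_set:
                continue
            child = tuple(sorted(members + (g,)))
            if child in visited:
                continue
            s_rcf = sum_rcf + rcf[g]
            s_pair = pair_sum + add_pair[g]
            r_cf = s_rcf / k
            r_ff = s_pair / (k * (k - 1) / 2)
            merit = cfs_merit(k, min(r_cf, 1.0), min(r_ff, 1.0))
            if merit > best_merit:
                improved = True
            heapq.heappush(open_heap, (-merit, next(counter), child, s_rcf, s_pair))
        stall_count = 0 if improved else stall_count + 1
    genes = sorted(dataset.genes[i] for i in best_members)
    return FeatureSet(genes=genes, method="cfs", max_size=max_size)


def rfs_rank(dataset: ExpressionDataset, n_trees: int = 500, seed: int = 0) -> FeatureRanking:
    """Gene ranking by random-forest mean decrease in Gini impurity.

    Trees use sqrt(p) candidate features per split; the score of a gene is
    its total Gini impurity reduction over all nodes of all trees
    (normalised so scores sum to 1).  Deterministic given ``seed``.
    """
    dataset.require_two_classes()
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    rf.fit(dataset.values, dataset.label_array().astype(str))
    return _ranked(dataset.genes, rf.feature_importances_, method="rfs")


def select_top_k(ranking: FeatureRanking, k: int) -> FeatureSet:
    """First ``k`` genes of a ranking (ranking ties already resolved by
    gene identifier, so the boundary is deterministic)."""
    if not 1 <= k <= len(ranking.genes):
        raise ValueError(f"k={k} out of range for ranking of {len(ranking.genes)} genes")
    return FeatureSet(genes=ranking.genes[:k], method=ranking.method, max_size=max(k, MAX_FEATURES))


@dataclass
class ConsensusResult:
    """Genes picked by at least ``min_methods`` selectors, with the number
    of agreeing methods per gene (the consensus 'frequency')."""

    genes: list[str]
    method_counts: dict[str, int] = field(default_factory=dict)


def consensus_selection(
    per_method_fold_selections: dict[str, list[FeatureSet]],
    top_k: int = 20,
    min_methods: int = 2,
) -> ConsensusResult:
    """Cross-method consensus over per-fold selections.

    For each method, genes are ranked by the number of CV folds in which
    they were selected and the ``top_k`` most frequent are kept (ties by
    gene identifier).  Genes present in at least ``min_methods`` of those
    per-method top lists form the consensus, each annotated with its
    number of supporting methods.
    """
    if len(per_method_fold_selections) < 2:
        raise ValueError("consensus needs at least two methods")
    top_lists: dict[str, set[str]] = {}
    for method, fold_sets in per_method_fold_selections.items():
        counts: dict[str, int] = {}
        for fs in fold_sets:
            for g in fs.genes:
                counts[g] = counts.get(g, 0) + 1
        ordered = sorted(counts, key=lambda g: (-counts[g], g))
        top_lists[method] = set(ordered[:top_k])
    if all(not s for s in top_lists.values()):
        log.warning("all per-method selections empty; consensus is empty")
        return ConsensusResult(genes=[])
    support: dict[str, int] = {}
    for genes in top_lists.values():
        for g in genes:
            support[g] = support.get(g, 0) + 1
    consensus = sorted(g for g, c in support.items() if c >= min_methods)
    return ConsensusResult(genes=consensus, method_counts={g: support[g] for g in consensus})
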