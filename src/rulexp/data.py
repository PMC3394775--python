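"""Core containers for two-class expression data and cross-validation folds.

The in-memory model is samples x genes (the orientation machine-learning
code expects), even though expression matrices on disk are usually written
genes-as-rows.  Labels are class *names*, never integer codes; exactly two
classes are required for training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold


class DataFormatError(ValueError):
    """Malformed input: duplicate identifiers, non-numeric cells, bad labels."""


class StratificationError(ValueError):
    """A class is too small to place at least one member in every fold."""


@dataclass
class ExpressionDataset:
    """Numeric samples x genes matrix with per-sample class labels.

    Parameters
    ----------
    genes
        Ordered, unique gene (probe) identifiers, one per column.
    samples
        Ordered, unique sample identifiers, one per row.
    values
        Float matrix of shape ``(n_samples, n_genes)``; no missing values.
    labels
        Per-sample class name; at most two distinct classes.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.labels = list(self.labels)
        if self.values.ndim != 2:
            raise DataFormatError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.samples) or p != len(self.genes):
            raise DataFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )
        for name, ids in (("gene", self.genes), ("sample", self.samples)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise DataFormatError(f"duplicate {name} identifier: {x!r}")
                seen.add(x)
        if len(self.labels) != n:
            raise DataFormatError("one label per sample required")
        if not np.isfinite(self.values).all():
            raise DataFormatError("expression matrix contains missing/non-finite values")
        if len(set(self.labels)) > 2:
            raise DataFormatError(f"more than two classes: {sorted(set(self.labels))}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def classes(self) -> list[str]:
        """Class names in lexicographic order (first = reporting 'positive')."""
        return sorted(set(self.labels))

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def subset_samples(self, idx: np.ndarray | list[int]) -> "ExpressionDataset":
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            genes=self.genes,
            samples=[self.samples[i] for i in idx],
            values=self.values[idx],
            labels=[self.labels[i] for i in idx],
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        cols = [self.gene_index(g) for g in genes]
        return ExpressionDataset(
            genes=list(genes),
            samples=self.samples,
            values=self.values[:, cols],
            labels=self.labels,
        )

    def require_two_classes(self) -> None:
        if len(set(self.labels)) != 2:
            raise DataFormatError(
                f"training data needs exactly two classes, got {sorted(set(self.labels))}"
            )


@dataclass
class FoldPlan:
    """Per-sample fold assignment for k-fold or leave-one-out CV.

    k-fold plans are stratified: per-class counts across folds differ by at
    most one.  Leave-one-out yields ``n`` singleton folds in sample order.
    """

    scheme: str  # "k-fold" | "leave-one-out"
    assignments: np.ndarray  # fold index per sample
    seed: int
    samples: list[str] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return int(self.assignments.max()) + 1

    def folds(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(train_idx, test_idx) pairs, one per fold."""
        out = []
        all_idx = np.arange(len(self.assignments))
        for f in range(self.n_folds):
            test = all_idx[self.assignments == f]
            train = all_idx[self.assignments != f]
            out.append((train, test))
        return out


def make_fold_plan(
    labels: list[str],
    scheme: str = "k-fold",
    k: int = 10,
    seed: int = 0,
    samples: list[str] | None = None,
) -> FoldPlan:
    """Build a deterministic fold plan over the given labels.

    ``scheme="k-fold"`` gives a stratified, shuffled k-fold split (seeded);
    ``scheme="leave-one-out"`` ignores ``k`` and yields n singleton folds.
    """
    labels = list(labels)
    n = len(labels)
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if scheme == "leave-one-out":
        return FoldPlan(scheme=scheme, assignments=np.arange(n), seed=seed, samples=samples)
    if scheme != "k-fold":
        raise ValueError(f"unknown CV scheme {scheme!r}")
    if not 2 <= k <= n:
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    counts = {c: labels.count(c) for c in set(labels)}
    small = [c for c, m in counts.items() if m < k]
    if small:
        raise StratificationError(
            f"class(es) {sorted(small)} have fewer than k={k} members; "
            "every fold must contain at least one member of each class"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    y = np.asarray(labels, dtype=object)
    for f, (_, test) in enumerate(skf.split(np.zeros((n, 1)), y)):
        assignments[test] = f
    return FoldPlan(scheme="k-fold", assignments=assignments, seed=seed, samples=samples)
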