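"""Synthetic two-class expression data and literature-corpus counts.

The expression generator plants a small set of informative genes whose
class-2 mean is shifted by ``effect`` noise-standard-deviations on an
otherwise Gaussian background, optionally with correlated redundant copies
(to exercise redundancy-penalising selectors) and an optional perfectly
separable marker gene.  Scales mirror typical two-class microarray studies:
on the order of 10^2-10^4 genes, ~100 samples, possibly imbalanced classes.

The corpus generator simulates per-document term occurrences so that
relative frequencies are exactly counts/n_docs: a disease term and gene
terms occur independently at a base rate, except for planted associated
genes whose co-occurrence probability with the disease term is lifted by a
multiplicative factor (marginals preserved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset
from .litmine import CorpusCounts

log = logging.getLogger(__name__)


@dataclass
class ExpressionSimSpec:
    """Parameters of the planted-genes expression simulator.

    Defaults match a balanced two-class study with 200 genes of which 10
    carry a 2-SD mean shift — a down-scaled analogue of microarray cancer
    cohorts (~100 samples, thousands of genes, moderate effect sizes).
    """

    n_per_class: tuple[int, int] = (50, 50)
    n_genes: int = 200
    n_informative: int = 10
    effect: float = 2.0
    noise_sd: float = 1.0
    n_redundant_blocks: int = 0
    block_size: int = 3
    block_rho: float = 0.8
    separable: bool = False
    class_names: tuple[str, str] = ("class1", "class2")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_class) < 1 or self.n_genes < 1:
            raise ValueError("sample and gene counts must be positive")
        if self.effect < 0 or self.noise_sd <= 0:
            raise ValueError("effect must be >= 0 and noise_sd > 0")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0,1)")
        extra = self.n_redundant_blocks * self.block_size
        if self.n_informative + extra > self.n_genes:
            raise ValueError(
                f"{self.n_informative} informative + {extra} redundant genes "
                f"exceed n_genes={self.n_genes}"
            )
        if self.n_redundant_blocks > 0 and self.n_informative == 0:
            raise ValueError("redundant blocks need at least one informative parent gene")


def generate_expression(spec: ExpressionSimSpec) -> tuple[ExpressionDataset, set[str]]:
    """Generate a dataset and the set of planted informative gene names.

    Background genes are Normal(0, noise_sd) in both classes; informative
    genes get ``+effect * noise_sd`` added in class 2.  Redundant block
    members correlate with their parent informative gene at ~``block_rho``.
    With ``separable=True``, gene 0 is given disjoint class value ranges so
    a single interval rule can classify the training data perfectly.
    Bit-identical output for identical spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_per_class
    n = n1 + n2
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_genes))
    is2 = np.zeros(n, dtype=bool)
    is2[n1:] = True
    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    informative = list(range(spec.n_informative))
    X[np.ix_(is2, informative)] += spec.effect * spec.noise_sd
    col = spec.n_informative
    for b in range(spec.n_redundant_blocks):
        parent = informative[b % max(spec.n_informative, 1)]
        for _ in range(spec.block_size):
            noise = rng.normal(0.0, spec.noise_sd, size=n)
            X[:, col] = spec.block_rho * X[:, parent] + np.sqrt(1 - spec.block_rho**2) * noise
            col += 1
    if spec.separable:
        lo = rng.uniform(0.0, 1.0, size=n1) * spec.noise_sd
        hi = (2.0 + rng.uniform(0.0, 1.0, size=n2)) * spec.noise_sd
        X[~is2, 0] = lo
        X[is2, 0] = hi
        informative = sorted(set(informative) | {0})
    labels = [spec.class_names[0]] * n1 + [spec.class_names[1]] * n2
    ds = ExpressionDataset(
        genes=genes,
        samples=[f"s{i:04d}" for i in range(n)],
        values=X,
        labels=labels,
    )
    truth = {genes[i] for i in informative}
    return ds, truth


@dataclass
class CorpusSimSpec:
    """Parameters of the document-level corpus simulator.

    ``assoc_lift`` multiplies the joint probability of (planted gene,
    disease term) relative to independence; marginal term rates stay at
    ``base_rate``.  Defaults give a corpus large enough for co-occurrence
    counts of rare terms to be informative (20k documents at a 1% rate).
    """

    n_docs: int = 20000
    n_genes: int = 500
    disease_terms: tuple[str, ...] = ("disease",)
    base_rate: float = 0.01
    n_assoc_genes: int = 10
    assoc_lift: float = 8.0
    seed: int = 0
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if not 0 < self.base_rate < 1:
            raise ValueError("base_rate must be in (0,1)")
        if self.assoc_lift < 1:
            raise ValueError("assoc_lift must be >= 1")
        if self.n_assoc_genes > self.n_genes:
            raise ValueError("planted genes must be a subset of the gene universe")
        if not self.gene_names:
            self.gene_names = [f"GENE{i:04d}" for i in range(self.n_genes)]
        elif len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names length must equal n_genes")


def generate_corpus(spec: CorpusSimSpec) -> tuple[CorpusCounts, set[str]]:
    """Generate document counts and the set of planted associated genes.

    Per document, the disease term occurs with probability ``base_rate``;
    each gene term occurs with probability ``base_rate`` independently,
    except planted genes whose conditional probability given the disease
    term is ``lift * base_rate`` (capped at 1, with a logged warning), with
    the off-disease probability adjusted to preserve the marginal rate.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.base_rate
    disease = spec.disease_terms[0]
    d_occ = rng.random(spec.n_docs) < p
    n_d = int(d_occ.sum())
    p1 = spec.assoc_lift * p  # P(gene | disease doc)
    if p1 > 1.0:
        log.warning("assoc_lift %.3g * base_rate %.3g > 1; capping at 1", spec.assoc_lift, p)
        p1 = 1.0
    p0 = max((p - p * p1) / (1 - p), 0.0) if p < 1 else 0.0  # keeps marginal ~= p
    assoc = set(spec.gene_names[: spec.n_assoc_genes])
    term_counts: dict[str, int] = {disease: n_d}
    pair_counts: dict[frozenset[str], int] = {}
    for g in spec.gene_names:
        if g in assoc:
            occ = np.where(d_occ, rng.random(spec.n_docs) < p1, rng.random(spec.n_docs) < p0)
        else:
            occ = rng.random(spec.n_docs) < p
        term_counts[g] = int(occ.sum())
        both = int((occ & d_occ).sum())
        if both:
            pair_counts[frozenset((g, disease))] = both
    counts = CorpusCounts(n_docs=spec.n_docs, term_counts=term_counts,
                          pair_counts=pair_counts)
    return counts, assoc
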