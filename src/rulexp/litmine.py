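"""Pointwise-mutual-information scoring of gene-disease term associations.

Document counts (how many documents mention a term, how many mention a
pair of terms) define relative frequencies f(x) = count(x)/n_docs.  The
PMI of a gene and a disease term,

    PMI(x, y) = log2( f(x, y) / (f(x) * f(y)) ),

is positive when the terms co-occur more often than independence predicts.
A gene set is scored by the sum of its positive PMIs (negative or
undefined PMIs count as zero: their magnitude is noise), and significance
is estimated by comparing against matched-size gene sets drawn uniformly
from the platform's gene universe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: sentinel for "PMI undefined" (some frequency is zero); compares <= 0 so
#: downstream positive-PMI sums treat it as irrelevant.
PMI_UNDEFINED = -math.inf


@dataclass
class CorpusCounts:
    """Document counts per term and per unordered term pair."""

    n_docs: int
    term_counts: dict[str, int]
    pair_counts: dict[frozenset[str], int]

    def __post_init__(self) -> None:
        if self.n_docs < 0:
            raise ValueError("n_docs must be non-negative")
        for t, c in self.term_counts.items():
            if not 0 <= c <= self.n_docs:
                raise ValueError(f"count for {t!r} outside [0, n_docs]")
        for pair, c in self.pair_counts.items():
            cmin = min(self.term_counts.get(t, 0) for t in pair)
            if not 0 <= c <= cmin:
                raise ValueError(f"pair count for {set(pair)} exceeds a member's count")

    def term_count(self, term: str) -> int:
        return self.term_counts.get(term, 0)

    def pair_count(self, a: str, b: str) -> int:
        return self.pair_counts.get(frozenset((a, b)), 0)


def pmi(x: str, y: str, corpus: CorpusCounts) -> float:
    """log2 f(x,y) / (f(x) f(y)); :data:`PMI_UNDEFINED` if any frequency is 0.

    Unknown terms are treated as count 0 (with a debug notice).  Symmetric
    in its arguments.
    """
    if corpus.n_docs < 1:
        raise ValueError("corpus must contain at least one document")
    fx = corpus.term_count(x) / corpus.n_docs
    fy = corpus.term_count(y) / corpus.n_docs
    fxy = corpus.pair_count(x, y) / corpus.n_docs
    for term, f in ((x, fx), (y, fy)):
        if f == 0.0:
            log.debug("term %r absent from corpus; PMI undefined", term)
    if fx == 0.0 or fy == 0.0 or fxy == 0.0:
        return PMI_UNDEFINED
    return math.log2(fxy / (fx * fy))


def gene_set_pmi_score(genes: list[str] | set[str], disease_term: str,
                       corpus: CorpusCounts) -> float:
    """Sum over genes of max(0, PMI(gene, disease)); undefined PMIs add 0."""
    if not genes:
        raise ValueError("gene set must be non-empty")
    return float(sum(max(0.0, pmi(g, disease_term, corpus)) for g in genes))


@dataclass
class PrioritizationResult:
    """Observed positive-PMI sum of a gene set and its permutation null."""

    genes: list[str]
    disease_term: str
    per_gene_pmi: dict[str, float]
    score: float
    null_scores: np.ndarray
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0,1]")


def permutation_pvalue(genes: list[str], disease_term: str, corpus: CorpusCounts,
                       universe: list[str], n_perm: int = 100,
                       seed: int = 0) -> PrioritizationResult:
    """Significance of a gene set's PMI score against matched-size random sets.

    Draws ``n_perm`` without-replacement sets of size ``len(genes)`` from
    ``universe`` and reports p = #{null score > observed} / n_perm (strict
    inequality, so an all-zero null against an observed 0 gives p = 0).
    Deterministic given ``seed``.
    """
    genes = list(genes)
    universe = list(universe)
    if len(universe) < len(genes):
        raise ValueError("universe smaller than the gene set")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = gene_set_pmi_score(genes, disease_term, corpus)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(len(universe), size=len(genes), replace=False)
        null[i] = gene_set_pmi_score([universe[j] for j in draw], disease_term, corpus)
    p = float((null > observed).sum() / n_perm)
    return PrioritizationResult(
        genes=genes,
        disease_term=disease_term,
        per_gene_pmi={g: pmi(g, disease_term, corpus) for g in genes},
        score=observed,
        null_scores=null,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# counts I/O: term TSV + pair TSV with an ``#n_docs=N`` header


def write_corpus_counts(corpus: CorpusCounts, term_path: str | Path,
                        pair_path: str | Path) -> None:
    with open(term_path, "w") as fh:
        fh.write(f"#n_docs={corpus.n_docs}\n")
        for t in sorted(corpus.term_counts):
            fh.write(f"{t}\t{corpus.term_counts[t]}\n")
    with open(pair_path, "w") as fh:
        fh.write(f"#n_docs={corpus.n_docs}\n")
        for pair in sorted(corpus.pair_counts, key=lambda p: tuple(sorted(p))):
            a, b = sorted(pair)
            fh.write(f"{a}\t{b}\t{corpus.pair_counts[pair]}\n")


def read_corpus_counts(term_path: str | Path, pair_path: str | Path) -> CorpusCounts:
    def header_n_docs(path: str | Path) -> int:
        first = Path(path).open().readline().strip()
        if not first.startswith("#n_docs="):
            raise ValueError(f"{path}: missing '#n_docs=' header")
        return int(first.split("=", 1)[1])

    n_docs = header_n_docs(term_path)
    if header_n_docs(pair_path) != n_docs:
        raise ValueError("term and pair files disagree on n_docs")
    term_counts: dict[str, int] = {}
    for line in Path(term_path).read_text().splitlines()[1:]:
        if line.strip():
            t, c = line.split("\t")
            term_counts[t] = int(c)
    pair_counts: dict[frozenset[str], int] = {}
    for line in Path(pair_path).read_text().splitlines()[1:]:
        if line.strip():
            a, b, c = line.split("\t")
            pair_counts[frozenset((a, b))] = int(c)
    return CorpusCounts(n_docs=n_docs, term_counts=term_counts, pair_counts=pair_counts)
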