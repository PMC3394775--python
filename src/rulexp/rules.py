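"""Interval-rule representation: predicates, rules, decision lists, ensembles.

A rule is a conjunction of closed per-gene intervals plus a predicted class;
a decision list is an ordered sequence of rules evaluated first-match,
closed by a predicate-free default rule so every sample gets a prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class IntervalPredicate:
    """``lo <= Exp(gene) <= hi`` with closed bounds."""

    gene: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo <= self.hi:
            raise ValueError(f"empty interval for {self.gene}: [{self.lo}, {self.hi}]")

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass
class Rule:
    """Conjunction of interval predicates with a predicted class.

    An empty-predicate rule matches every sample (default-rule form).  At
    most one predicate per gene.
    """

    predicates: tuple[IntervalPredicate, ...]
    predicted_class: str

    def __post_init__(self) -> None:
        self.predicates = tuple(self.predicates)
        genes = [p.gene for p in self.predicates]
        if len(genes) != len(set(genes)):
            raise ValueError("at most one predicate per gene in a rule")

    @property
    def is_default(self) -> bool:
        return len(self.predicates) == 0

    @property
    def genes(self) -> set[str]:
        return {p.gene for p in self.predicates}


def rule_matches(rule: Rule, sample_values: dict[str, float]) -> bool:
    """True iff every predicate interval contains the sample's value.

    An empty-predicate rule matches anything.  A predicate on a gene the
    sample does not provide raises ``KeyError`` naming the gene.
    """
    for p in rule.predicates:
        if p.gene not in sample_values:
            raise KeyError(f"sample provides no value for gene {p.gene!r}")
        if not p.contains(sample_values[p.gene]):
            return False
    return True


def rule_matches_matrix(rule: Rule, values: np.ndarray, gene_index: dict[str, int]) -> np.ndarray:
    """Vectorised match mask over a samples x genes matrix."""
    mask = np.ones(values.shape[0], dtype=bool)
    for p in rule.predicates:
        if p.gene not in gene_index:
            raise KeyError(f"matrix provides no column for gene {p.gene!r}")
        col = values[:, gene_index[p.gene]]
        mask &= (col >= p.lo) & (col <= p.hi)
    return mask


@dataclass
class DecisionList:
    """Ordered rules with first-match semantics, ending in a default rule."""

    rules: list[Rule]
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("decision list needs at least a default rule")
        if not self.rules[-1].is_default:
            raise ValueError("last rule must be a predicate-free default rule")
        for r in self.rules[:-1]:
            if r.is_default:
                raise ValueError("only the final rule may be a default rule")

    @property
    def default_class(self) -> str:
        return self.rules[-1].predicted_class

    @property
    def specific_rules(self) -> list[Rule]:
        return self.rules[:-1]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.rules:
            out |= r.genes
        return out

    def predict_sample(self, sample_values: dict[str, float]) -> str:
        for r in self.rules:
            if rule_matches(r, sample_values):
                return r.predicted_class
        raise AssertionError("unreachable: default rule matches everything")

    def predict(self, values: np.ndarray, genes: list[str]) -> np.ndarray:
        """Vectorised first-match prediction over a samples x genes matrix."""
        gi = {g: j for j, g in enumerate(genes)}
        n = values.shape[0]
        pred = np.empty(n, dtype=object)
        undecided = np.ones(n, dtype=bool)
        for r in self.rules:
            if not undecided.any():
                break
            m = rule_matches_matrix(r, values, gi) & undecided
            pred[m] = r.predicted_class
            undecided &= ~m
        return pred


def predict_decision_list(dl: DecisionList, sample_values: dict[str, float]) -> str:
    """Class of the first matching rule (always defined via the default)."""
    return dl.predict_sample(sample_values)


@dataclass
class LearnerParams:
    """Knobs of the evolutionary rule learners.

    ``coverage_breakpoint`` (CB) is the coverage fraction up to which the
    fitness coverage term rises steeply; past it the marginal reward drops
    to slope ``coverage_slope_after``.  ``complexity_weight`` penalises each
    predicate.  Generalize/specialize are the mutation biases toward wider
    (fewer) vs. narrower (more) predicates.
    """

    ga_generations: int = 500
    population_size: int = 500
    tournament_size: int = 4
    crossover_prob: float = 0.6
    mutation_prob: float = 0.6
    p_generalize: float = 0.5
    p_specialize: float = 0.5
    coverage_breakpoint: float = 0.25
    coverage_slope_after: float = 0.1
    complexity_weight: float = 0.001
    max_genes_per_ruleset: int = 30
    min_rule_accuracy: float = 0.5
    init_fraction: float = 0.5
    max_init_predicates: int = 3
    max_rules: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_prob", "mutation_prob", "p_generalize", "p_specialize"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.coverage_breakpoint <= 1.0:
            raise ValueError("coverage_breakpoint must be in (0,1]")
        for name in ("ga_generations", "population_size", "tournament_size",
                     "max_genes_per_ruleset", "max_rules", "max_init_predicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def coverage_term(cov: float, params: LearnerParams) -> float:
    """Piecewise-linear coverage reward, continuous at the breakpoint.

    Rises from 0 to 1 over [0, CB], then continues with the (much smaller)
    slope ``coverage_slope_after`` — covering more samples past the minimum
    still helps, but far less per sample.
    """
    cb = params.coverage_breakpoint
    if cov < cb:
        return cov / cb
    return 1.0 + params.coverage_slope_after * (cov - cb)


def rule_fitness(
    rule: Rule,
    values: np.ndarray,
    labels: np.ndarray,
    genes: list[str],
    params: LearnerParams,
) -> float:
    """Accuracy x coverage-term minus a per-predicate complexity penalty.

    Evaluated on the not-yet-covered examples of the current iteration:
    ``acc`` is the fraction of matched samples with the rule's class (0 if
    nothing matches), ``cov`` the fraction of examples matched.
    """
    if values.shape[0] == 0:
        raise ValueError("rule_fitness needs a non-empty example set")
    gi = {g: j for j, g in enumerate(genes)}
    m = rule_matches_matrix(rule, values, gi)
    n_match = int(m.sum())
    cov = n_match / values.shape[0]
    acc = float((labels[m] == rule.predicted_class).mean()) if n_match else 0.0
    return acc * coverage_term(cov, params) - params.complexity_weight * len(rule.predicates)


@dataclass
class RuleEnsemble:
    """Decision lists trained with distinct seeds; majority-vote predictor."""

    members: list[DecisionList]
    class_prevalence: dict[str, float]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    def predict(self, values: np.ndarray, genes: list[str]) -> np.ndarray:
        votes = np.stack([m.predict(values, genes) for m in self.members])
        out = np.empty(values.shape[0], dtype=object)
        for j in range(values.shape[0]):
            out[j] = _majority(votes[:, j], self.class_prevalence)
        return out


def _majority(votes: np.ndarray, prevalence: dict[str, float]) -> str:
    """Most-voted class; ties go to the higher training prevalence, then
    to the lexicographically first class name."""
    classes, counts = np.unique(votes.astype(str), return_counts=True)
    tied = sorted(classes[counts == counts.max()])
    tied.sort(key=lambda c: (-prevalence.get(c, 0.0), c))
    return tied[0]


def ensemble_predict(ensemble: RuleEnsemble, sample_values: dict[str, float]) -> str:
    """Majority vote of the members on a single sample."""
    votes = np.array([m.predict_sample(sample_values) for m in ensemble.members], dtype=object)
    return _majority(votes, ensemble.class_prevalence)
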