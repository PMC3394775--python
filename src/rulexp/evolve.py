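"""Evolutionary induction of interval-rule decision lists.

Two learners share the rule representation of :mod:`rulexp.rules`:

* :func:`biohel_learn` — iterative rule learning (separate-and-conquer): a
  generational genetic algorithm evolves the single best rule for the
  examples not yet covered, the covered examples are removed, and the loop
  repeats until everything is covered or no acceptable rule remains.  A
  majority-class default rule closes the list.
* :func:`gassist_learn` — Pittsburgh-style evolution: GA individuals are
  whole variable-length decision lists, scored by training accuracy minus
  a complexity penalty.

Both are pure functions of (data, params, seed).  Rule populations are held
as fixed-slot numpy arrays (gene index, lower bound, upper bound, active
flag per slot) so that fitness evaluation over the whole population is
vectorised across samples and individuals.
"""

from __future__ import annotations

import logging

import numpy as np

from .data import ExpressionDataset
from .rules import (
    DecisionList,
    IntervalPredicate,
    LearnerParams,
    Rule,
    RuleEnsemble,
    rule_matches_matrix,
)
from .selection import FeatureRanking, _ranked

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# array-backed rule population


class _RulePop:
    """Population of candidate rules in slot-array form.

    Slots hold (gene, lo, hi); inactive slots are ignored.  Active slots of
    one individual always reference distinct genes (repaired after
    crossover), so conversion to :class:`Rule` is direct.
    """

    def __init__(self, G: np.ndarray, LO: np.ndarray, HI: np.ndarray,
                 ACT: np.ndarray, CLS: np.ndarray):
        self.G, self.LO, self.HI, self.ACT, self.CLS = G, LO, HI, ACT, CLS

    @property
    def size(self) -> int:
        return self.G.shape[0]

    def take(self, idx: np.ndarray) -> "_RulePop":
        return _RulePop(self.G[idx].copy(), self.LO[idx].copy(),
                        self.HI[idx].copy(), self.ACT[idx].copy(), self.CLS[idx].copy())

    def rule(self, i: int, genes: list[str], classes: list[str]) -> Rule:
        preds = []
        for s in np.flatnonzero(self.ACT[i]):
            lo, hi = float(self.LO[i, s]), float(self.HI[i, s])
            preds.append(IntervalPredicate(genes[int(self.G[i, s])], min(lo, hi), max(lo, hi)))
        preds.sort(key=lambda p: p.gene)
        return Rule(predicates=tuple(preds), predicted_class=classes[int(self.CLS[i])])


def _init_pop(X: np.ndarray, yidx: np.ndarray, n: int, n_slots: int,
              params: LearnerParams, rng: np.random.Generator) -> _RulePop:
    """Seed each individual from a random example: intervals of width
    ``init_fraction`` of each gene's observed range, centred on the
    example's values, over a random subset of genes."""
    N, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    G = np.zeros((n, n_slots), dtype=np.intp)
    LO = np.zeros((n, n_slots))
    HI = np.zeros((n, n_slots))
    ACT = np.zeros((n, n_slots), dtype=bool)
    CLS = np.zeros(n, dtype=np.intp)
    for i in range(n):
        ex = rng.integers(N)
        m = int(rng.integers(1, min(params.max_init_predicates, p) + 1))
        gs = rng.choice(p, size=m, replace=False)
        half = params.init_fraction * span[gs] / 2.0
        G[i, :m] = gs
        LO[i, :m] = X[ex, gs] - half
        HI[i, :m] = X[ex, gs] + half
        ACT[i, :m] = True
        CLS[i] = yidx[ex]
    return _RulePop(G, LO, HI, ACT, CLS)


def _eval_pop(pop: _RulePop, X: np.ndarray, yidx: np.ndarray,
              params: LearnerParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fitness, accuracy, coverage) per individual, fully vectorised."""
    N = X.shape[0]
    vals = X[:, pop.G]                      # (N, P, K)
    ok = ~pop.ACT | ((vals >= pop.LO) & (vals <= pop.HI))
    matches = ok.all(axis=2)                # (N, P)
    ncov = matches.sum(axis=0)
    ncorrect = (matches & (yidx[:, None] == pop.CLS[None, :])).sum(axis=0)
    cov = ncov / N
    acc = np.where(ncov > 0, ncorrect / np.maximum(ncov, 1), 0.0)
    cb, w = params.coverage_breakpoint, params.coverage_slope_after
    ct = np.where(cov < cb, cov / cb, 1.0 + w * (cov - cb))
    fit = acc * ct - params.complexity_weight * pop.ACT.sum(axis=1)
    return fit, acc, cov


def _tournament(fit: np.ndarray, n: int, t: int, rng: np.random.Generator) -> np.ndarray:
    cand = rng.integers(fit.size, size=(n, min(t, fit.size)))
    return cand[np.arange(n), np.argmax(fit[cand], axis=1)]


def _repair(pop: _RulePop, i: int) -> None:
    """Deactivate later slots that duplicate an earlier active slot's gene."""
    seen: set[int] = set()
    for s in np.flatnonzero(pop.ACT[i]):
        g = int(pop.G[i, s])
        if g in seen:
            pop.ACT[i, s] = False
        else:
            seen.add(g)


def _mutate_rule(pop: _RulePop, i: int, X: np.ndarray, lo_obs: np.ndarray,
                 hi_obs: np.ndarray, params: LearnerParams,
                 rng: np.random.Generator) -> None:
    """One mutation event: perturb a bound, then possibly generalize
    (drop a predicate / widen a bound to the observed extreme) and/or
    specialize (add a predicate / narrow a bound)."""
    N, p = X.shape
    span = hi_obs - lo_obs
    active = np.flatnonzero(pop.ACT[i])
    if active.size:
        s = int(rng.choice(active))
        g = int(pop.G[i, s])
        delta = rng.normal(0.0, 0.1 * (span[g] or 1.0))
        if rng.random() < 0.5:
            pop.LO[i, s] = min(pop.LO[i, s] + delta, pop.HI[i, s])
        else:
            pop.HI[i, s] = max(pop.HI[i, s] + delta, pop.LO[i, s])
    if active.size and rng.random() < params.p_generalize:
        s = int(rng.choice(active))
        g = int(pop.G[i, s])
        if rng.random() < 0.5 and active.size > 1:
            pop.ACT[i, s] = False
        elif rng.random() < 0.5:
            pop.LO[i, s] = lo_obs[g]
        else:
            pop.HI[i, s] = hi_obs[g]
    if rng.random() < params.p_specialize:
        inactive = np.flatnonzero(~pop.ACT[i])
        used = {int(g) for g in pop.G[i, pop.ACT[i]]}
        free = [g for g in range(p) if g not in used]
        if inactive.size and free:
            s = int(inactive[0])
            g = int(rng.choice(np.asarray(free)))
            v = X[int(rng.integers(N)), g]
            half = params.init_fraction * (span[g] or 1.0) / 2.0
            pop.G[i, s], pop.LO[i, s], pop.HI[i, s] = g, v - half, v + half
            pop.ACT[i, s] = True
        else:
            active = np.flatnonzero(pop.ACT[i])
            if active.size:
                s = int(rng.choice(active))
                mid = (pop.LO[i, s] + pop.HI[i, s]) / 2.0
                pop.LO[i, s] = pop.LO[i, s] + 0.25 * (mid - pop.LO[i, s])
                pop.HI[i, s] = pop.HI[i, s] - 0.25 * (pop.HI[i, s] - mid)


def _evolve_rule_arrays(X: np.ndarray, yidx: np.ndarray, params: LearnerParams,
                        rng: np.random.Generator) -> tuple[_RulePop, int, float, float]:
    """Run the generational GA; return (population, best index, best
    accuracy, best coverage) with the best-ever individual stored at the
    returned index."""
    N, p = X.shape
    n_slots = min(p, params.max_init_predicates + 2)
    pop = _init_pop(X, yidx, params.population_size, n_slots, params, rng)
    fit, acc, cov = _eval_pop(pop, X, yidx, params)
    lo_obs, hi_obs = X.min(axis=0), X.max(axis=0)
    best = pop.take(np.array([int(np.argmax(fit))]))
    best_stats = (float(fit.max()), float(acc[np.argmax(fit)]), float(cov[np.argmax(fit)]))
    for _ in range(params.ga_generations):
        sel = _tournament(fit, pop.size, params.tournament_size, rng)
        child = pop.take(sel)
        for i in range(0, child.size - 1, 2):
            if rng.random() < params.crossover_prob and n_slots > 1:
                cut = int(rng.integers(1, n_slots))
                for arr in (child.G, child.LO, child.HI, child.ACT):
                    arr[i, cut:], arr[i + 1, cut:] = arr[i + 1, cut:].copy(), arr[i, cut:].copy()
                _repair(child, i)
                _repair(child, i + 1)
        for i in range(child.size):
            if rng.random() < params.mutation_prob:
                _mutate_rule(child, i, X, lo_obs, hi_obs, params, rng)
        # elitism: best-ever individual replaces slot 0
        for arr, barr in ((child.G, best.G), (child.LO, best.LO),
                          (child.HI, best.HI), (child.ACT, best.ACT),
                          (child.CLS, best.CLS)):
            arr[0] = barr[0]
        pop = child
        fit, acc, cov = _eval_pop(pop, X, yidx, params)
        j = int(np.argmax(fit))
        if fit[j] > best_stats[0]:
            best = pop.take(np.array([j]))
            best_stats = (float(fit[j]), float(acc[j]), float(cov[j]))
    return best, 0, best_stats[1], best_stats[2]


def evolve_rule(values: np.ndarray, labels: np.ndarray, genes: list[str],
                params: LearnerParams, rng: np.random.Generator) -> Rule:
    """Evolve the single best interval rule for the given examples.

    ``values`` is samples x genes, ``labels`` the per-sample class names.
    Returns the best rule found by :func:`rules.rule_fitness` after
    ``params.ga_generations`` generations; deterministic given ``rng``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] == 0:
        raise ValueError("evolve_rule needs at least one example")
    classes = sorted({str(c) for c in labels})
    yidx = np.array([classes.index(str(c)) for c in labels], dtype=np.intp)
    best, i, _, _ = _evolve_rule_arrays(values, yidx, params, rng)
    return best.rule(i, genes, classes)


# ---------------------------------------------------------------------------
# BioHEL: iterative rule learning


def biohel_learn(train: ExpressionDataset, params: LearnerParams | None = None,
                 seed: int = 0) -> DecisionList:
    """Separate-and-conquer decision-list induction.

    Each iteration evolves the best rule for the not-yet-covered examples,
    appends it, and removes the examples it covers.  The loop stops when the
    remaining examples are empty or single-class, when the best rule is
    unusable (accuracy below ``min_rule_accuracy`` or zero coverage), or
    when accepting the rule would push the list past
    ``max_genes_per_ruleset`` distinct genes.  A default rule predicting
    the majority class of the remaining examples closes the list.
    """
    params = params or LearnerParams()
    X = train.values
    classes = train.classes
    y = train.label_array().astype(str)
    if len(classes) < 2:
        log.warning("single-class training data: returning default-only list")
        return DecisionList([Rule((), classes[0])], seed=seed)
    yidx = np.array([classes.index(c) for c in y], dtype=np.intp)
    rng = np.random.default_rng(seed)
    remaining = np.arange(train.n_samples)
    rules: list[Rule] = []
    used_genes: set[str] = set()
    gi = {g: j for j, g in enumerate(train.genes)}
    while remaining.size and len(set(yidx[remaining])) > 1:
        best, bi, acc, cov = _evolve_rule_arrays(X[remaining], yidx[remaining], params, rng)
        rule = best.rule(bi, train.genes, classes)
        if cov == 0.0 or acc < params.min_rule_accuracy:
            break
        if len(used_genes | rule.genes) > params.max_genes_per_ruleset:
            break
        m = rule_matches_matrix(rule, X[remaining], gi)
        if not m.any():
            break
        rules.append(rule)
        used_genes |= rule.genes
        remaining = remaining[~m]
    default_class = _majority_class(yidx[remaining] if remaining.size else yidx, classes)
    return DecisionList(rules + [Rule((), default_class)], seed=seed)


def _majority_class(yidx: np.ndarray, classes: list[str]) -> str:
    counts = np.bincount(yidx, minlength=len(classes))
    # ties go to the lexicographically first class (classes are sorted)
    return classes[int(np.argmax(counts))]


# ---------------------------------------------------------------------------
# GAssist: Pittsburgh-style evolution of whole decision lists

# an individual is ([(genes, lo, hi, cls), ...], default_cls)
_Indiv = tuple[list[tuple[np.ndarray, np.ndarray, np.ndarray, int]], int]


def _seed_rule(X: np.ndarray, yidx: np.ndarray, params: LearnerParams,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    N, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    ex = int(rng.integers(N))
    m = int(rng.integers(1, min(params.max_init_predicates, p) + 1))
    gs = np.sort(rng.choice(p, size=m, replace=False))
    half = params.init_fraction * span[gs] / 2.0
    return gs, X[ex, gs] - half, X[ex, gs] + half, int(yidx[ex])


def _indiv_predict(ind: _Indiv, X: np.ndarray) -> np.ndarray:
    rules, default = ind
    pred = np.full(X.shape[0], default, dtype=np.intp)
    undecided = np.ones(X.shape[0], dtype=bool)
    for gs, lo, hi, cls in rules:
        if not undecided.any():
            break
        m = ((X[:, gs] >= lo) & (X[:, gs] <= hi)).all(axis=1) & undecided
        pred[m] = cls
        undecided &= ~m
    return pred


def _indiv_fitness(ind: _Indiv, X: np.ndarray, yidx: np.ndarray,
                   params: LearnerParams) -> float:
    acc = float((_indiv_predict(ind, X) == yidx).mean())
    n_pred = sum(len(gs) for gs, *_ in ind[0])
    return acc - params.complexity_weight * n_pred


def _mutate_indiv(ind: _Indiv, X: np.ndarray, yidx: np.ndarray,
                  params: LearnerParams, rng: np.random.Generator) -> _Indiv:
    rules = [(gs.copy(), lo.copy(), hi.copy(), cls) for gs, lo, hi, cls in ind[0]]
    default = ind[1]
    N, p = X.shape
    lo_obs, hi_obs = X.min(axis=0), X.max(axis=0)
    span = np.where(hi_obs > lo_obs, hi_obs - lo_obs, 1.0)
    op = rng.random()
    if op < 0.2 and len(rules) < params.max_rules:        # insert
        rules.insert(int(rng.integers(len(rules) + 1)), _seed_rule(X, yidx, params, rng))
    elif op < 0.4 and rules:                              # delete (may empty the list:
        rules.pop(int(rng.integers(len(rules))))          # default-only is a valid model)
    elif rules:                                           # edit one rule
        k = int(rng.integers(len(rules)))
        gs, lo, hi, cls = rules[k]
        r = rng.random()
        if r < 0.4 and gs.size:                           # perturb a bound
            s = int(rng.integers(gs.size))
            delta = rng.normal(0.0, 0.1 * span[gs[s]])
            if rng.random() < 0.5:
                lo[s] = min(lo[s] + delta, hi[s])
            else:
                hi[s] = max(hi[s] + delta, lo[s])
        elif r < 0.6 and gs.size > 1:                     # drop a predicate
            s = int(rng.integers(gs.size))
            keep = np.arange(gs.size) != s
            gs, lo, hi = gs[keep], lo[keep], hi[keep]
        elif r < 0.8 and gs.size < p:                     # add a predicate
            free = np.setdiff1d(np.arange(p), gs)
            g = int(rng.choice(free))
            v = X[int(rng.integers(N)), g]
            half = params.init_fraction * span[g] / 2.0
            gs = np.append(gs, g)
            lo = np.append(lo, v - half)
            hi = np.append(hi, v + half)
        elif gs.size:                                     # widen to extreme
            s = int(rng.integers(gs.size))
            if rng.random() < 0.5:
                lo[s] = lo_obs[gs[s]]
            else:
                hi[s] = hi_obs[gs[s]]
        rules[k] = (gs, lo, hi, cls)
    if rng.random() < 0.1:                                # flip default class
        default = 1 - default
    return rules, default


def gassist_learn(train: ExpressionDataset, params: LearnerParams | None = None,
                  seed: int = 0) -> DecisionList:
    """Evolve whole decision lists with a generational GA.

    Individuals are variable-length rule lists plus a default class,
    scored by training accuracy minus ``complexity_weight`` per predicate.
    Crossover splices contiguous rule blocks between parents; mutation
    edits, inserts, or deletes a rule.  Deterministic given ``seed``.
    """
    params = params or LearnerParams()
    classes = train.classes
    if len(classes) < 2:
        log.warning("single-class training data: returning default-only list")
        return DecisionList([Rule((), classes[0])], seed=seed)
    X = train.values
    y = train.label_array().astype(str)
    yidx = np.array([classes.index(c) for c in y], dtype=np.intp)
    rng = np.random.default_rng(seed)
    maj = int(np.argmax(np.bincount(yidx, minlength=2)))
    pop: list[_Indiv] = []
    for _ in range(params.population_size):
        n_rules = int(rng.integers(1, min(params.max_rules, 4) + 1))
        pop.append(([_seed_rule(X, yidx, params, rng) for _ in range(n_rules)], maj))
    fit = np.array([_indiv_fitness(ind, X, yidx, params) for ind in pop])
    best_ind, best_fit = pop[int(np.argmax(fit))], float(fit.max())
    for _ in range(params.ga_generations):
        sel = _tournament(fit, len(pop), params.tournament_size, rng)
        children: list[_Indiv] = [pop[int(s)] for s in sel]
        for i in range(0, len(children) - 1, 2):
            if rng.random() < params.crossover_prob:
                ra, da = children[i]
                rb, db = children[i + 1]
                ca = int(rng.integers(len(ra) + 1))
                cb = int(rng.integers(len(rb) + 1))
                na = (ra[:ca] + rb[cb:])[: params.max_rules]
                nb = (rb[:cb] + ra[ca:])[: params.max_rules]
                children[i] = (na, da)
                children[i + 1] = (nb, db)
        for i in range(len(children)):
            if rng.random() < params.mutation_prob:
                children[i] = _mutate_indiv(children[i], X, yidx, params, rng)
        children[0] = best_ind
        pop = children
        fit = np.array([_indiv_fitness(ind, X, yidx, params) for ind in pop])
        j = int(np.argmax(fit))
        if fit[j] > best_fit:
            best_ind, best_fit = pop[j], float(fit[j])
    rules = []
    for gs, lo, hi, cls in best_ind[0]:
        preds = tuple(
            IntervalPredicate(train.genes[int(g)], float(min(a, b)), float(max(a, b)))
            for g, a, b in zip(gs, lo, hi)
        )
        rules.append(Rule(preds, classes[cls]))
    rules.append(Rule((), classes[best_ind[1]]))
    return DecisionList(rules, seed=seed)


# ---------------------------------------------------------------------------
# ensembles and rule-frequency ranking

LEARNERS = {"biohel": biohel_learn, "gassist": gassist_learn}


def train_ensemble(train: ExpressionDataset, learner: str = "biohel",
                   params: LearnerParams | None = None, n_members: int = 100,
                   base_seed: int = 0) -> RuleEnsemble:
    """Train ``n_members`` decision lists with seeds base_seed..base_seed+n-1."""
    fn = LEARNERS[learner] if isinstance(learner, str) else learner
    members = [fn(train, params, seed=base_seed + i) for i in range(n_members)]
    y = train.label_array().astype(str)
    prevalence = {c: float((y == c).mean()) for c in train.classes}
    return RuleEnsemble(members=members, class_prevalence=prevalence)


def attribute_frequency(ensembles: list[RuleEnsemble]) -> FeatureRanking:
    """Rule-frequency gene ranking across ensembles (e.g. across CV cycles).

    A gene's score is 100 x (number of non-default rules with a predicate
    on it) / (total non-default rules over all members of all ensembles) —
    a percentage of rules mentioning the gene.
    """
    counts: dict[str, int] = {}
    total = 0
    for ens in ensembles:
        for dl in ens.members:
            for r in dl.specific_rules:
                total += 1
                for g in r.genes:
                    counts[g] = counts.get(g, 0) + 1
    if total == 0:
        log.warning("no non-default rules in any ensemble; empty ranking")
        return FeatureRanking(genes=[], scores=np.array([]), method="biohel_fr")
    genes = sorted(counts)
    scores = np.array([100.0 * counts[g] / total for g in genes])
    return _ranked(genes, scores, method="biohel_fr")
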