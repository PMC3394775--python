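# Methods

## Problem setting

The package targets supervised analysis of two-class expression matrices:
`n` samples (order 10²) by `p` genes (order 10²–10⁴), class labels such as
tumor/normal or luminal/non-luminal, possibly imbalanced. Models are
decision lists of per-gene expression-interval rules, chosen for
interpretability: each rule reads directly as "gene g within [lo, hi] (and
…) → class c", and the final predicate-free default rule guarantees every
sample a prediction (first-match semantics).

## Rule representation

A predicate is a closed interval `lo ≤ Exp(g) ≤ hi`; a rule is a
conjunction of predicates (at most one per gene) with a predicted class.
Closed bounds mean values exactly on a bound match. An empty-predicate
rule matches everything; only the final default rule has this form in a
valid list.

## Rule fitness

For a candidate rule evaluated on the current example set, with coverage
`cov` (fraction matched) and accuracy `acc` (fraction of matched examples
with the rule's class; 0 if none matched):

```
CT(cov) = cov / CB                    if cov < CB
          1 + w · (cov − CB)          otherwise
fitness = acc · CT(cov) − λ · (#predicates)
```

The breakpoint `CB` (default 0.25) encodes the requirement that a useful
rule must cover a minimum share of the examples: up to `CB` the coverage
reward climbs steeply (slope `1/CB`), beyond it the marginal reward drops
to slope `w` (default 0.1). `CT` is continuous at `CB`. The complexity
penalty `λ` (default 0.001) breaks ties toward shorter rules without
overriding accuracy differences. This concrete functional form is this
package's own reconstruction of the standard accuracy/coverage/complexity
desiderata of coverage-breakpoint rule learners; every constant is a
`LearnerParams` field.

## Iterative rule learning (`biohel_learn`)

Separate-and-conquer: evolve the best rule for the not-yet-covered
examples, append it, drop the examples it covers, repeat. Termination:
remaining examples empty or single-class, best rule unusable (accuracy
below `min_rule_accuracy = 0.5` — worse than a coin flip — or zero
coverage), or accepting the rule would exceed `max_genes_per_ruleset = 30`
distinct genes (the same budget as the external selectors, applied when
the learner runs on all genes). Each accepted rule covers at least one
example, so the loop runs at most `n` iterations. The default rule
predicts the majority class of the remaining examples (overall training
majority if none remain; ties go to the lexicographically first class).

The per-iteration GA is generational with tournament selection (size 4),
one-point crossover on predicate slots (0.6), mutation (0.6) that perturbs
a bound and then generalizes (drops a predicate or widens a bound to the
observed extreme, prob 0.5) and/or specializes (adds a predicate on an
unused gene or narrows a bound, prob 0.5), and elitism of one.
Individuals are seeded from random training examples: intervals of width
`init_fraction = 0.5` of each gene's observed range, centred on the
example's values, over at most `max_init_predicates = 3` random genes.
Populations are stored as fixed-slot numpy arrays, so fitness evaluation
of the whole population is vectorised over samples × individuals ×
predicate slots; slot repair after crossover keeps genes within an
individual distinct.

## Pittsburgh-style evolution (`gassist_learn`)

GA individuals are whole decision lists: 0–`max_rules` (default 10)
interval rules plus a default class, fitness = training accuracy − λ ×
total predicates. Crossover splices contiguous rule blocks
(`A[:i] + B[j:]`); mutation inserts a seeded rule, deletes a rule (the
list may become default-only — under a heavy complexity penalty the
learner correctly degenerates to the majority-class model), edits a rule
with the same bound/predicate operators as above, or occasionally flips
the default class. Elitism of one; same seeding and determinism contract.

Library defaults for both learners are 500 generations × population 500,
mirroring the scale such systems use on real cohorts. The test suite and
the acceptance script run a down-scaled configuration (30 generations ×
population 40) — on the reference synthetic conditions the search problem
is small enough that this reaches perfect training fit, and it keeps a
full 10×10-fold ensemble experiment in minutes on one CPU.

## Ensembles and rule-frequency ranking

GAs are stochastic, so `train_ensemble` trains `n_members` lists (default
100) with consecutive seeds and predicts by majority vote; exact vote ties
go to the class with higher training prevalence, then lexicographically.
`attribute_frequency` scores each gene by the percentage of non-default
rules (pooled over members and CV cycles) whose predicates mention it —
the rule-frequency ranking used for prioritization. The denominator is
the total number of non-default rules, so a gene appearing in every rule
scores 100.

## Feature selection

* **Univariate F ranking** (`plss_rank`): one-way ANOVA F per gene (equal
  to the squared pooled-variance t for two groups). A constant gene
  scores 0; zero within-group variance with non-zero between-group
  variance scores +inf and ranks first. Ties break on gene identifier.
  An optional `mode="pls"` ranks by |first-PLS-component weights|, which
  yields the same ordering for two-class data; the F route is the direct
  computation and the default, with the equivalence enforced by test.
* **CFS** (`cfs_select`): best-first search over subsets scored by
  `merit = k·r̄_cf / √(k + k(k−1)·r̄_ff)`. Because the inputs are
  continuous, feature–class correlation is the absolute point-biserial
  correlation against a 0/1 class code and feature–feature correlation is
  absolute Pearson (the original discretized symmetrical-uncertainty
  variant is not the default). The search stops after 5 consecutive
  non-improving expansions (the classic best-first stall rule), at
  `max_size = 30`, or at a 1000-expansion guard, and returns the best
  subset visited — often far fewer than 30 genes.
* **RFS** (`rfs_rank`): scikit-learn random forest (default 500 trees,
  √p candidate features per split, seeded) ranked by Gini importance. In
  CV pipelines the top-k cut is typically matched to the CFS subset size
  on the same fold, capped at 30.
* **Consensus** (`consensus_selection`): per method, genes are ranked by
  the number of CV folds selecting them and the top-k kept; genes backed
  by ≥ 2 methods form the consensus, annotated with their method count.

## Cross-validation harness

`external_cv` re-runs the selector inside every training fold and trains
the classifier on the selected columns of the training rows only; the API
hands both of them a training-only dataset, so a selector cannot observe
test samples even in principle (asserted by a canary test). 10-fold plans
are stratified and seeded; leave-one-out gives `n` singleton folds.
`nested_param_search` adds the second level: an inner stratified CV
(default 5-fold) over a parameter grid on the training fold, ties resolved
in declared grid order. Accuracy is summarised as mean and sample SD
(ddof 1) of per-fold percentages; LOOCV folds are 0/100, which is why
LOOCV SDs are in the 20–40 range even at high mean accuracy.

Method comparisons rank methods within each block (1 = highest accuracy,
mid-ranks for ties — validated against the published rank tables this
package bundles), average ranks over blocks, and report the tie-corrected
Friedman chi-square; a fully tied table yields statistic 0. Holm's
step-down procedure (via statsmodels) adjusts post-hoc pairwise p-values.

## Literature mining

With document counts `f(x) = count(x)/n_docs`,
`PMI(x,y) = log₂ f(x,y) / (f(x) f(y))` (symmetric; base 2 is cosmetic —
permutation p-values are base-invariant). If any involved frequency is 0
the PMI is undefined and returned as a −inf sentinel; a gene set's score
is the sum of *positive* PMIs (negative and undefined contribute 0, since
the magnitude of negative PMIs in sparse corpora is dominated by noise).
`permutation_pvalue` draws `n_perm = 100` matched-size gene sets uniformly
without replacement from the platform's gene universe and reports
`p = #{null > observed}/n_perm` — strict inequality, so p = 0.00 is
attainable and the p-grid has 1/100 granularity. No smoothing is applied
by default.

## Synthetic generators

`generate_expression` emulates the structure of two-class microarray
cohorts: Gaussian background (SD = `noise_sd`), `n_informative` genes with
a `+effect·noise_sd` mean shift in class 2, optional redundant blocks
correlated with an informative parent at ≈`block_rho` (specifically to
exercise CFS's redundancy penalty), and an optional perfectly separable
marker. Defaults — 50+50 samples, 200 genes, 10 informative at effect 2 —
are the package's reference conditions: large enough that selectors and
learners must find the signal among noise, small enough for complete
experiments in minutes. What it deliberately does *not* model: probe-level
artifacts, batch effects, heavy-tailed platform-specific distributions, or
correlated noise beyond the planted blocks — so passing tests demonstrate
correct method behaviour, not expected accuracy on real cohorts.

`generate_corpus` simulates documents directly: disease and gene terms
occur independently at `base_rate`, except planted genes whose conditional
occurrence probability given a disease document is `lift × base_rate`
(capped at 1 with a warning), with the off-disease rate adjusted to
preserve the marginal. Counts are exact document counts, so PMI inputs
have no approximation error.

Both generators are bit-reproducible from (spec, seed).

## Numerical and design choices

* Class names, never integer codes, flow through the API; the
  lexicographically first class is the reporting "positive" only.
* All tie-breaks are deterministic: gene identifier in rankings and top-k
  cuts, training prevalence then lexicographic for vote ties, first grid
  point for equal inner-CV scores, lexicographically first class for
  majority ties.
* Rule-set text files serialize bounds at `repr` precision, so
  write→read round trips reproduce decision lists exactly.
* Stratified folds require every class to have ≥ k members; otherwise a
  stratification error is raised rather than silently degrading.
* The bundled benchmark accuracy tables are integer percentages; rank
  reproduction is asserted after rounding average ranks to one decimal.
  One published selector-rank cell is internally inconsistent (its row of
  three average ranks sums to 6.1, not 6.0) and is excluded from
  reproduction checks.

## Known limitations

Two-class problems only. The GA learners are not parallelised. CFS
best-first search cost grows with p × subset size per expansion; on very
wide matrices (≫10⁴ genes) a univariate pre-cut is advisable. The
literature-mining module consumes pre-computed document counts — it does
not query or parse any literature database itself.
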