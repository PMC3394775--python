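"""Rule semantics, fitness shape, and the two evolutionary learners."""

import numpy as np
import pytest

from rulexp import (
    DecisionList,
    ExpressionSimSpec,
    IntervalPredicate,
    LearnerParams,
    Rule,
    attribute_frequency,
    biohel_learn,
    ensemble_predict,
    evolve_rule,
    gassist_learn,
    generate_expression,
    predict_decision_list,
    rule_matches,
    train_ensemble,
)
from rulexp.rules import RuleEnsemble, coverage_term, rule_fitness

FAST = LearnerParams(ga_generations=30, population_size=40)


class TestRuleMatching:
    def test_upper_bound_inclusive(self):
        r = Rule((IntervalPredicate("g", 0.2, 0.5),), "A")
        assert rule_matches(r, {"g": 0.5})
        assert rule_matches(r, {"g": 0.2})
        assert not rule_matches(r, {"g": 0.50001})

    def test_conjunction_requires_all_predicates(self):
        r = Rule((IntervalPredicate("g1", 0, 1), IntervalPredicate("g2", 0, 1)), "A")
        assert not rule_matches(r, {"g1": 0.5, "g2": 2.0})
        assert rule_matches(r, {"g1": 0.5, "g2": 0.5})

    def test_default_form_matches_anything(self):
        assert rule_matches(Rule((), "A"), {"g": 1e9})

    def test_missing_gene_named_in_error(self):
        r = Rule((IntervalPredicate("gZ", 0, 1),), "A")
        with pytest.raises(KeyError, match="gZ"):
            rule_matches(r, {"g1": 0.0})

    def test_duplicate_gene_predicates_rejected(self):
        with pytest.raises(ValueError):
            Rule((IntervalPredicate("g", 0, 1), IntervalPredicate("g", 2, 3)), "A")


class TestDecisionList:
    def test_first_match_wins(self):
        dl = DecisionList([
            Rule((IntervalPredicate("g", 0, 10),), "A"),
            Rule((IntervalPredicate("g", 0, 10),), "B"),
            Rule((), "C"),
        ])
        assert predict_decision_list(dl, {"g": 5}) == "A"

    def test_falls_through_to_default(self):
        dl = DecisionList([Rule((IntervalPredicate("g", 0, 1),), "A"), Rule((), "B")])
        assert predict_decision_list(dl, {"g": 5}) == "B"

    def test_default_only_list(self):
        dl = DecisionList([Rule((), "A")])
        assert predict_decision_list(dl, {"g": 123}) == "A"

    def test_default_must_be_last_and_unique(self):
        with pytest.raises(ValueError):
            DecisionList([Rule((), "A"), Rule((IntervalPredicate("g", 0, 1),), "B")])
        with pytest.raises(ValueError):
            DecisionList([Rule((IntervalPredicate("g", 0, 1),), "B")])

    def test_vectorised_predict_matches_scalar(self):
        rng = np.random.default_rng(0)
        dl = DecisionList([
            Rule((IntervalPredicate("g0", -0.5, 0.5),), "A"),
            Rule((IntervalPredicate("g1", 0.0, 2.0),), "B"),
            Rule((), "C"),
        ])
        X = rng.normal(size=(50, 2))
        vec = dl.predict(X, ["g0", "g1"])
        scal = [predict_decision_list(dl, {"g0": x[0], "g1": x[1]}) for x in X]
        assert list(vec) == scal


class TestRuleFitness:
    PARAMS = LearnerParams(complexity_weight=0.01)

    def test_matching_nothing_is_only_penalised(self):
        X = np.zeros((10, 1))
        y = np.array(["A"] * 10, dtype=object)
        r = Rule((IntervalPredicate("g0", 5, 6),), "A")
        fit = rule_fitness(r, X, y, ["g0"], self.PARAMS)
        assert fit == pytest.approx(-0.01)

    def test_extra_inert_predicate_costs_fitness(self):
        rng = np.random.default_rng(1)
        X = np.c_[rng.normal(size=20), rng.normal(size=20)]
        y = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        short = Rule((IntervalPredicate("g0", -10, 10),), "A")
        long = Rule((IntervalPredicate("g0", -10, 10),
                     IntervalPredicate("g1", -100, 100)), "A")
        f_short = rule_fitness(short, X, y, ["g0", "g1"], self.PARAMS)
        f_long = rule_fitness(long, X, y, ["g0", "g1"], self.PARAMS)
        assert f_short > f_long

    def test_reward_flattens_past_breakpoint(self):
        p = LearnerParams(coverage_breakpoint=0.25, coverage_slope_after=0.1,
                          complexity_weight=0.0)
        at_cb = coverage_term(0.25, p)
        at_2cb = coverage_term(0.50, p)
        assert at_cb == pytest.approx(1.0)
        assert at_2cb == pytest.approx(1.0 + 0.1 * 0.25)
        # pre-breakpoint slope is 1/CB = 4; post slope is 0.1: 40x flatter
        assert (at_2cb - at_cb) / 0.25 < 1.0 / p.coverage_breakpoint

    def test_coverage_term_continuous_at_breakpoint(self):
        p = LearnerParams()
        eps = 1e-9
        below = coverage_term(p.coverage_breakpoint - eps, p)
        above = coverage_term(p.coverage_breakpoint + eps, p)
        assert abs(above - below) < 1e-6

    def test_empty_example_set_rejected(self):
        with pytest.raises(ValueError):
            rule_fitness(Rule((), "A"), np.empty((0, 1)),
                         np.array([], dtype=object), ["g0"], self.PARAMS)


class TestEvolveRule:
    def test_recovers_separable_rule(self):
        successes = 0
        for seed in range(20):
            ds, _ = generate_expression(
                ExpressionSimSpec(n_per_class=(15, 15), n_genes=10, n_informative=1,
                                  separable=True, seed=500 + seed))
            rng = np.random.default_rng(seed)
            rule = evolve_rule(ds.values, ds.label_array(), ds.genes, FAST, rng)
            y = ds.label_array().astype(str)
            gi = {g: j for j, g in enumerate(ds.genes)}
            from rulexp.rules import rule_matches_matrix
            m = rule_matches_matrix(rule, ds.values, gi)
            if m.sum() > 0:
                acc = (y[m] == rule.predicted_class).mean()
                cov = m.mean()
                if acc == 1.0 and cov >= FAST.coverage_breakpoint:
                    successes += 1
        assert successes >= 19

    def test_single_class_examples_yield_that_class(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        y = np.array(["B"] * 12, dtype=object)
        rule = evolve_rule(X, y, ["g0", "g1", "g2"], FAST, np.random.default_rng(1))
        assert rule.predicted_class == "B"

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        y = np.array(["A"] * 15 + ["B"] * 15, dtype=object)
        r1 = evolve_rule(X, y, [f"g{i}" for i in range(5)], FAST,
                         np.random.default_rng(7))
        r2 = evolve_rule(X, y, [f"g{i}" for i in range(5)], FAST,
                         np.random.default_rng(7))
        assert r1 == r2


class TestBioHEL:
    def test_perfect_on_separable_data(self, separable_dataset):
        dl = biohel_learn(separable_dataset, FAST, seed=0)
        pred = dl.predict(separable_dataset.values, separable_dataset.genes)
        assert (pred == separable_dataset.label_array()).mean() == 1.0

    def test_single_class_gives_default_only(self):
        from rulexp import ExpressionDataset

        rng = np.random.default_rng(0)
        ds = ExpressionDataset(genes=["g0"], samples=["a", "b", "c"],
                               values=rng.normal(size=(3, 1)),
                               labels=["A", "A", "A"])
        dl = biohel_learn(ds, FAST, seed=0)
        assert len(dl.rules) == 1 and dl.default_class == "A"

    def test_every_training_sample_is_covered(self, planted_dataset):
        ds, _ = planted_dataset
        dl = biohel_learn(ds, FAST, seed=3)
        pred = dl.predict(ds.values, ds.genes)
        assert all(p is not None for p in pred)  # totality via default rule

    def test_terminates_within_n_iterations(self, planted_dataset):
        # each accepted rule covers >= 1 example, so <= n specific rules
        ds, _ = planted_dataset
        dl = biohel_learn(ds, FAST, seed=5)
        assert len(dl.specific_rules) <= ds.n_samples

    def test_gene_budget_respected(self, planted_dataset):
        ds, _ = planted_dataset
        params = LearnerParams(ga_generations=20, population_size=30,
                               max_genes_per_ruleset=4)
        dl = biohel_learn(ds, params, seed=1)
        assert len(dl.genes) <= 4

    def test_deterministic_given_seed(self, separable_dataset):
        a = biohel_learn(separable_dataset, FAST, seed=11)
        b = biohel_learn(separable_dataset, FAST, seed=11)
        assert a.rules == b.rules


class TestGAssist:
    def test_perfect_on_separable_data(self, separable_dataset):
        params = LearnerParams(ga_generations=60, population_size=50)
        dl = gassist_learn(separable_dataset, params, seed=0)
        pred = dl.predict(separable_dataset.values, separable_dataset.genes)
        assert (pred == separable_dataset.label_array()).mean() == 1.0

    def test_heavy_complexity_penalty_degenerates_to_default(self):
        ds, _ = generate_expression(
            ExpressionSimSpec(n_per_class=(20, 10), n_genes=10, n_informative=2,
                              effect=1.0, seed=4))
        params = LearnerParams(ga_generations=40, population_size=40,
                               complexity_weight=10.0)
        dl = gassist_learn(ds, params, seed=0)
        pred = dl.predict(ds.values, ds.genes)
        majority_acc = 20 / 30
        assert (pred == ds.label_array()).mean() <= majority_acc + 1e-9

    def test_beats_random_search_baseline(self):
        ds, _ = generate_expression(
            ExpressionSimSpec(n_per_class=(10, 10), n_genes=10, n_informative=3,
                              effect=2.0, seed=6))
        params = LearnerParams(ga_generations=50, population_size=50)
        dl = gassist_learn(ds, params, seed=2)
        y = ds.label_array()
        evolved_acc = (dl.predict(ds.values, ds.genes) == y).mean()
        evolved_fit = evolved_acc - params.complexity_weight * sum(
            len(r.predicates) for r in dl.specific_rules)
        # random-search oracle over the same representation
        from rulexp.evolve import _indiv_fitness, _seed_rule

        rng = np.random.default_rng(99)
        classes = ds.classes
        yidx = np.array([classes.index(c) for c in y.astype(str)])
        best_random = -np.inf
        for _ in range(1000):
            n_rules = int(rng.integers(1, 5))
            ind = ([_seed_rule(ds.values, yidx, params, rng) for _ in range(n_rules)],
                   int(rng.integers(2)))
            best_random = max(best_random, _indiv_fitness(ind, ds.values, yidx, params))
        assert evolved_fit >= best_random - 1e-9


class TestEnsembles:
    def test_singleton_ensemble_equals_member(self, separable_dataset):
        ens = train_ensemble(separable_dataset, "biohel", FAST, n_members=1, base_seed=0)
        single = biohel_learn(separable_dataset, FAST, seed=0)
        X, genes = separable_dataset.values, separable_dataset.genes
        np.testing.assert_array_equal(ens.predict(X, genes), single.predict(X, genes))

    def test_same_base_seed_reproduces_ensemble(self, separable_dataset):
        a = train_ensemble(separable_dataset, "biohel", FAST, n_members=3, base_seed=5)
        b = train_ensemble(separable_dataset, "biohel", FAST, n_members=3, base_seed=5)
        assert all(x.rules == y.rules for x, y in zip(a.members, b.members))

    def test_vote_tie_broken_by_prevalence(self):
        members = [DecisionList([Rule((), "A")]), DecisionList([Rule((), "B")])]
        ens = RuleEnsemble(members=members, class_prevalence={"A": 0.4, "B": 0.6})
        assert ensemble_predict(ens, {"g": 0.0}) == "B"
        ens2 = RuleEnsemble(members=members, class_prevalence={"A": 0.5, "B": 0.5})
        assert ensemble_predict(ens2, {"g": 0.0}) == "A"  # lexicographic fallback

    def test_clear_majority_wins(self):
        members = ([DecisionList([Rule((), "A")])] * 51
                   + [DecisionList([Rule((), "B")])] * 49)
        ens = RuleEnsemble(members=members, class_prevalence={"A": 0.5, "B": 0.5})
        assert ensemble_predict(ens, {}) == "A"

    def test_ensemble_not_worse_than_median_member(self):
        wins = 0
        for rep in range(8):
            ds, _ = generate_expression(
                ExpressionSimSpec(n_per_class=(25, 25), n_genes=50, n_informative=5,
                                  effect=1.5, seed=700 + rep))
            ens = train_ensemble(ds, "biohel",
                                 LearnerParams(ga_generations=15, population_size=25),
                                 n_members=7, base_seed=rep)
            y = ds.label_array()
            ens_acc = (ens.predict(ds.values, ds.genes) == y).mean()
            member_accs = [(m.predict(ds.values, ds.genes) == y).mean()
                           for m in ens.members]
            wins += ens_acc >= np.median(member_accs)
        assert wins >= 7


class TestAttributeFrequency:
    def test_single_rule_single_gene(self):
        dl = DecisionList([Rule((IntervalPredicate("gQ", 0, 1),), "A"), Rule((), "B")])
        ens = RuleEnsemble(members=[dl], class_prevalence={"A": 0.5, "B": 0.5})
        rk = attribute_frequency([ens])
        assert rk.genes == ["gQ"]
        assert rk.scores[0] == 100.0

    def test_unused_gene_absent_from_ranking(self, separable_dataset):
        ens = train_ensemble(separable_dataset, "biohel", FAST, n_members=3, base_seed=0)
        rk = attribute_frequency([ens])
        assert set(rk.genes) <= set(separable_dataset.genes)
        assert np.all(rk.scores > 0)

    def test_matches_recount_from_serialized_rulesets(self, tmp_path, separable_dataset):
        from rulexp.io import read_ruleset, write_ruleset

        ens = train_ensemble(separable_dataset, "biohel", FAST, n_members=4, base_seed=2)
        rk = attribute_frequency([ens])
        # independent re-count from the text serialization
        counts: dict[str, int] = {}
        total = 0
        for i, dl in enumerate(ens.members):
            p = tmp_path / f"m{i}.txt"
            write_ruleset(dl, p)
            back = read_ruleset(p)
            for r in back.specific_rules:
                total += 1
                for g in r.genes:
                    counts[g] = counts.get(g, 0) + 1
        for g, s in zip(rk.genes, rk.scores):
            assert s == pytest.approx(100.0 * counts[g] / total)
        mean_preds = total and sum(counts.values()) / total
        assert rk.scores.sum() <= 100.0 * mean_preds + 1e-9
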