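"""Hypergeometric selection, ensemble aggregation, fine-tuning, agreement."""

import itertools
import math
import random

import numpy as np
import pytest

from ontorules.consensus import (
    build_consensus,
    expected_count,
    fine_tune,
    jaccard,
    run_ensemble,
    weight_agreement,
)
from ontorules.ontology import Feature, OntologyGraph
from ontorules.rule_model import CrispRule, CrispRuleSet
from ontorules.training import TrainConfig

FLAT = OntologyGraph([Feature(id=f"x{i}") for i in range(6)])


def rs(*conjs, intercept=0.0, weights=None):
    weights = weights or [1.0] * len(conjs)
    return CrispRuleSet([CrispRule(frozenset(c), w)
                         for c, w in zip(conjs, weights)], intercept)


# ----------------------------------------------------------------------
# expected_count


def test_expected_count_forced_draw():
    assert expected_count(3, 3, 3, runs=10, rules_per_model=2.0) == pytest.approx(20.0)


@pytest.mark.parametrize("k,m,n,p", [
    (2, 2, 5, 1 / 10),
    (1, 1, 4, 1 / 4),
    (2, 3, 6, 1 / 5),
])
def test_expected_count_small_cases(k, m, n, p):
    assert expected_count(k, m, n, runs=1) == pytest.approx(p)


def test_expected_count_matches_subset_enumeration():
    """P(fixed k-set ⊆ random m-subset of n) by exhaustive enumeration."""
    rng = random.Random(0)
    for n in (5, 8, 12):
        for m in (1, 3, n // 2):
            for k in range(1, m + 1):
                fixed = set(range(k))
                subsets = list(itertools.combinations(range(n), m))
                hit = sum(fixed <= set(sub) for sub in subsets)
                assert expected_count(k, m, n, runs=1) == pytest.approx(
                    hit / len(subsets)), (k, m, n)


def test_expected_count_rejects_bad_arguments():
    with pytest.raises(ValueError):
        expected_count(3, 2, 5, runs=1)
    with pytest.raises(ValueError):
        expected_count(1, 6, 5, runs=1)


def test_expected_count_fractional_m_floored():
    # m = 2.7 floors to 2 in the combinatorial formula
    assert expected_count(2, 2.7, 5, runs=1) == pytest.approx(1 / 10)
    with pytest.raises(ValueError):  # k > m is outside the null's support
        expected_count(3, 2.9, 5, runs=1)


# ----------------------------------------------------------------------
# build_consensus


def models_with_support(conj, n_present, n_total, filler="x5"):
    """n_total models; ``conj`` appears in the first n_present of them."""
    out = []
    for i in range(n_total):
        rules = [({"x0"},), ({"x1"},)]  # common singletons keep m stable
        base = rs({"x0"}, {"x1"}, weights=[1.0, -1.0])
        if i < n_present:
            base.rules.append(CrispRule(frozenset(conj), 2.0))
        else:
            base.rules.append(CrispRule(frozenset({filler, f"x{i % 3}"}), 2.0))
        out.append(base)
    return out


def test_build_consensus_strict_inequality_boundary():
    models = models_with_support({"x2", "x3"}, n_present=14, n_total=20)
    cons = build_consensus(models, FLAT, n_literals=6, selection_factor=1.3)
    expected = {s.conjunction: s.expected for s in cons.stats}
    # retention is exactly support > 1.3 × expected, recomputed independently
    for mdl_conj in ({"x2", "x3"},):
        conj = frozenset(mdl_conj)
        support = sum(conj in m.lhs_set() for m in models)
        k = len(conj)
        exp = expected_count(k, cons.mean_rule_length, 6, cons.runs,
                             cons.rules_per_model) if k <= cons.mean_rule_length else 0.0
        kept = conj in {r.conjunction for r in cons.rules}
        assert kept == (support > 1.3 * exp)


def test_build_consensus_order_invariant():
    models = models_with_support({"x2", "x3"}, 10, 16)
    a = build_consensus(models, FLAT, n_literals=6)
    b = build_consensus(list(reversed(models)), FLAT, n_literals=6)
    assert {r.conjunction for r in a.rules} == {r.conjunction for r in b.rules}
    assert a.ruleset.intercept == pytest.approx(b.ruleset.intercept)


def test_build_consensus_singleton_seeding_toggle():
    # a singleton appearing once: kept with seeding, subject to the
    # criterion (and the support floor) without it
    models = [rs({"x0"})] + [rs({"x1"})] * 9
    with_seed = build_consensus(models, FLAT, n_literals=6,
                                keep_supported_singletons=True)
    assert frozenset({"x0"}) in {r.conjunction for r in with_seed.rules}
    without = build_consensus(models, FLAT, n_literals=6,
                              keep_supported_singletons=False)
    # expected = 10·ρ·P = 10·(1/6) ≈ 1.67; support 1 < max(1.3·1.67, 2)
    assert frozenset({"x0"}) not in {r.conjunction for r in without.rules}


def test_build_consensus_needs_two_models():
    with pytest.raises(ValueError):
        build_consensus([rs({"x0"})], FLAT, n_literals=6)


# ----------------------------------------------------------------------
# jaccard / weight agreement


def test_jaccard_hand_cases():
    a = rs({"nurse", "patch"}, {"nurse"}, weights=[0.8, 1.5])
    b = rs({"nurse"})
    assert jaccard(a, a) == 1.0
    assert jaccard(a, b) == pytest.approx(0.5)
    assert jaccard(rs({"nurse"}), rs({"patch"})) == 0.0
    assert jaccard(rs(), rs()) == 1.0


def test_weight_agreement_mean_sd_population():
    models = [rs({"x0"}, weights=[0.8]), rs({"x0"}, weights=[1.2]),
              rs({"x1"}, weights=[3.0])]
    stats = {tuple(sorted(s.conjunction)): s for s in weight_agreement(models)}
    s0 = stats[("x0",)]
    assert s0.mean_weight == pytest.approx(1.0)
    assert s0.sd_weight == pytest.approx(0.2)  # population convention
    assert not s0.low_support
    s1 = stats[("x1",)]
    assert s1.support == 1 and s1.sd_weight == 0.0 and s1.low_support


def test_weight_agreement_sign_disagreement_surfaces():
    models = [rs({"x0"}, weights=[0.8]), rs({"x0"}, weights=[-0.8])]
    (s,) = weight_agreement(models)
    assert abs(s.mean_weight) < 1e-12 and s.sd_weight == pytest.approx(0.8)


# ----------------------------------------------------------------------
# fine_tune


def always_on_table():
    import pandas as pd
    from ontorules.arm_table import ArmTable
    df = pd.DataFrame({
        "study_id": ["s1", "s2", "s3", "s4"],
        "arm_id": ["a"] * 4,
        "outcome": [10.0, 20.0, 30.0, 40.0],
        "x0": [1.0] * 4,
    })
    return ArmTable(df, {"x0": "presence"})


def test_fine_tune_single_always_on_rule_hits_grand_mean():
    models = [rs({"x0"}), rs({"x0"})]
    cons = build_consensus(models, FLAT, n_literals=1)
    tuned = fine_tune(cons, always_on_table())
    pred = tuned.ruleset.predict(always_on_table())
    np.testing.assert_allclose(pred, 25.0, atol=1e-8)  # grand mean
    assert tuned.fine_tuned and tuned.train_mae == pytest.approx(10.0)


def test_fine_tune_recovers_planted_weights_noiseless(planted_problem):
    graph = planted_problem["graph"]
    table = planted_problem["table"].subset(
        np.ones(planted_problem["table"].n_arms, dtype=bool))
    # rebuild a noiseless outcome from the planted truth
    table.df["outcome"] = np.asarray(planted_problem["truth"]["linpred"])
    models = [
        CrispRuleSet(list(planted_problem["rules"]), 0.0),
        CrispRuleSet(list(planted_problem["rules"]), 0.0),
    ]
    cons = build_consensus(models, graph,
                           n_literals=len(table.feature_columns))
    tuned = fine_tune(cons, table)
    got = {tuple(sorted(r.conjunction)): r.weight for r in tuned.rules}
    for rule in planted_problem["rules"]:
        assert got[tuple(sorted(rule.conjunction))] == pytest.approx(
            rule.weight, abs=1e-6)
    assert tuned.ruleset.intercept == pytest.approx(12.0, abs=1e-6)
    assert tuned.train_mae == pytest.approx(0.0, abs=1e-8)


def test_fine_tune_does_not_worsen_training_mae(planted_problem):
    table = planted_problem["table"]
    graph = planted_problem["graph"]
    models = [CrispRuleSet(list(planted_problem["rules"]), 10.0)] * 2
    cons = build_consensus(models, graph, n_literals=len(table.feature_columns))
    pre = np.mean(np.abs(cons.ruleset.predict(table) - table.outcomes()))
    tuned = fine_tune(cons, table)
    assert tuned.train_mae <= pre + 1e-9


def test_fine_tune_empty_consensus_rejected():
    cons = build_consensus([rs(), rs()], FLAT, n_literals=6)
    with pytest.raises(ValueError):
        fine_tune(cons, always_on_table())


# ----------------------------------------------------------------------
# run_ensemble (small end-to-end)


def test_run_ensemble_requires_two_runs(planted_problem):
    with pytest.raises(ValueError):
        run_ensemble(planted_problem["table"], planted_problem["graph"],
                     TrainConfig(n_rules=40), runs=1)


def test_consensus_of_consensus_increases_agreement(planted_problem):
    """Aggregation increases agreement: mean pairwise Jaccard between
    independently built consensus models ≥ that between raw models.

    Uses deliberately short training runs so the raw models genuinely
    disagree (fully converged runs on planted data already agree almost
    perfectly, leaving the aggregation step nothing to demonstrate).
    """
    table, graph = planted_problem["table"], planted_problem["graph"]
    cfg = dict(n_rules=40, min_epochs=40, max_epochs=60, patience=15,
               learning_rate=0.03)
    batches = []
    all_models = []
    for batch in range(2):
        models = run_ensemble(table, graph,
                              TrainConfig(seed=500 + 10 * batch, **cfg),
                              runs=6)
        all_models.extend(models)
        # criterion-only selection: singleton seeding would re-admit one-off
        # noise rules and obscure the aggregation effect under test
        batches.append(build_consensus(
            models, graph, n_literals=len(table.feature_columns),
            keep_supported_singletons=False).ruleset)
    raw_pairs = [jaccard(a, b) for i, a in enumerate(all_models)
                 for b in all_models[i + 1:]]
    cons_pairs = [jaccard(batches[0], batches[1])]
    assert np.mean(cons_pairs) >= np.mean(raw_pairs) - 1e-12, (
        cons_pairs, float(np.mean(raw_pairs)))


def test_run_ensemble_planted_support_dominates(planted_problem):
    """Planted conjunctions recur across runs more than spurious ones."""
    table, graph = planted_problem["table"], planted_problem["graph"]
    cfg = TrainConfig(n_rules=40, min_epochs=120, max_epochs=200, patience=20,
                      learning_rate=0.03, seed=100)
    models = run_ensemble(table, graph, cfg, runs=5)
    assert len(models) == 5
    support: dict[frozenset, int] = {}
    for m in models:
        for c in m.lhs_set():
            support[c] = support.get(c, 0) + 1
    planted = {r.conjunction for r in planted_problem["rules"]}
    for conj in planted:
        by_len = [s for c, s in support.items()
                  if len(c) == len(conj) and c not in planted]
        if by_len:
            assert support.get(conj, 0) >= max(by_len)

    cons = build_consensus(models, graph, n_literals=len(table.feature_columns))
    kept = {r.conjunction for r in cons.rules}
    assert planted <= kept
    spurious3 = [c for c in support if len(c) >= 3 and c not in planted]
    kept3 = [c for c in spurious3 if c in kept]
    if spurious3:
        assert len(kept3) / len(spurious3) <= 0.1
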