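"""Binarization operators, literal expansion, pruning, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontorules.arm_table import ArmTable
from ontorules.featurization import (
    BinarizerSpec,
    aggregate_by_hierarchy,
    apply_binarizer,
    binarize_cluster,
    binarize_fixed_width,
    binarize_quantile,
    binarize_semantic,
    expand_literals,
    flag_exact,
    prepare_table,
    prune_rare,
)
from ontorules.ontology import Feature, OntologyGraph

CIGS = BinarizerSpec("cigs_per_day", "fixed_width",
                     thresholds=list(range(5, 55, 5)))
AGE = BinarizerSpec("mean_age", "semantic",
                    categories=[("child", 18.0), ("young adult", 40.0),
                                ("older adult", 65.0), ("elderly", np.inf)])


# ----------------------------------------------------------------------
# fixed width


@pytest.mark.parametrize("value,low,high", [
    (6, ["cigs_per_day < 5"], ["cigs_per_day < 10", "cigs_per_day < 50"]),
    (46, ["cigs_per_day < 45", "cigs_per_day < 5"], ["cigs_per_day < 50"]),
    (2, [], ["cigs_per_day < 5", "cigs_per_day < 50"]),
])
def test_fixed_width_ordering_examples(value, low, high):
    m = dict(zip(CIGS.column_names(), binarize_fixed_width(value, CIGS)))
    for col in low:
        assert m[col] < 0.2, col
    for col in high:
        assert m[col] > 0.8, col


@given(st.floats(min_value=-10, max_value=100, allow_nan=False))
@settings(deadline=None, max_examples=100)
def test_fixed_width_memberships_nondecreasing_in_threshold(value):
    m = binarize_fixed_width(value, CIGS)
    assert np.all(np.diff(m) >= -1e-12)
    assert np.all((m >= 0) & (m <= 1))


def test_fixed_width_missing_value_all_zero():
    assert np.all(binarize_fixed_width(np.nan, CIGS) == 0.0)


# ----------------------------------------------------------------------
# semantic


def test_semantic_interior_point():
    m = dict(zip(AGE.column_names(), binarize_semantic(30.0, AGE)))
    assert m["mean_age: young adult"] > 0.95
    assert m["mean_age: child"] < 0.05 and m["mean_age: older adult"] < 0.05


def test_semantic_boundary_symmetry():
    m = dict(zip(AGE.column_names(), binarize_semantic(40.0, AGE)))
    assert m["mean_age: young adult"] == pytest.approx(0.5, abs=1e-3)
    assert m["mean_age: older adult"] == pytest.approx(0.5, abs=1e-3)


def test_semantic_sweep_unimodal_and_crossings():
    grid = np.linspace(0, 100, 2001)
    M = binarize_semantic(grid, AGE)
    assert M.shape == (2001, 4)
    assert np.all(M.sum(axis=1) > 0) and np.all(M.sum(axis=1) <= 2 + 1e-9)
    for j in range(4):
        col = M[:, j]
        peak = col.argmax()
        assert np.all(np.diff(col[: peak + 1]) >= -1e-9)
        assert np.all(np.diff(col[peak:]) <= 1e-9)
    for b in (18, 40, 65):
        at = M[np.argmin(np.abs(grid - b))]
        assert np.sort(at)[-2:] == pytest.approx([0.5, 0.5], abs=0.01)


# ----------------------------------------------------------------------
# quantile


def test_quantile_thresholds_order_statistics():
    spec = binarize_quantile(np.arange(1, 101), q=4, source_feature="x")
    assert spec.thresholds == pytest.approx([25.75, 50.5, 75.25])
    assert spec.method == "quantile"


def test_quantile_degenerate_cases():
    with pytest.raises(ValueError, match="exact_value"):
        binarize_quantile([5.0] * 50, q=4)
    assert binarize_quantile([1, 2, 3], q=1).thresholds == []


# ----------------------------------------------------------------------
# exact flags


@pytest.mark.parametrize("value,expected", [
    (100.0, 1.0),
    (99.4, 0.0),
    (100.0 * (1 + 4e-10), 1.0),  # inside the relative tolerance
])
def test_flag_exact(value, expected):
    spec = BinarizerSpec("pct_female", "exact_value", target_value=100.0)
    assert flag_exact(value, spec) == expected


# ----------------------------------------------------------------------
# cluster


def test_cluster_splits_at_gap():
    spec = binarize_cluster([1, 2, 3, 50, 51, 52], k_max=4, source_feature="x")
    uppers = [u for _, u in spec.categories]
    assert len(spec.categories) == 2
    assert 3 < uppers[0] < 50 and uppers[1] == np.inf


def test_cluster_single_tight_cluster():
    spec = binarize_cluster([10.0, 10.1, 10.2, 9.9], k_max=4)
    assert len(spec.categories) == 1


def test_cluster_permutation_invariant():
    rng = np.random.default_rng(0)
    vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(20, 1, 30)])
    a = binarize_cluster(vals, k_max=3)
    b = binarize_cluster(rng.permutation(vals), k_max=3)
    assert a.categories == b.categories


def test_cluster_degenerate_error():
    with pytest.raises(ValueError):
        binarize_cluster([7.0, 7.0, 7.0], k_max=3)


# ----------------------------------------------------------------------
# literal expansion / pruning / aggregation


def test_expand_literals_complements(tiny_table):
    out = expand_literals(tiny_table)
    assert out.df["not nurse"].tolist() == [0, 1, 0, 1, 1, 0]
    pair_sum = out.df["nurse"] + out.df["not nurse"]
    assert np.allclose(pair_sum, 1.0)


def test_expand_literals_fuzzy_and_kinds(tiny_table):
    t = tiny_table
    t.df["nurse"] = [0.7, 0.0, 1.0, 0.3, 0.0, 1.0]
    t.df["fup < 26"] = 1.0
    t.column_kinds["fup < 26"] = "range"
    out = expand_literals(ArmTable(t.df, t.column_kinds))
    assert out.df["not nurse"].iloc[0] == pytest.approx(0.3)
    assert "not fup < 26" not in out.df.columns  # range literals: no complement


def make_presence_table(counts: dict[str, int], n: int = 60) -> ArmTable:
    df = pd.DataFrame({
        "study_id": [f"s{i}" for i in range(n)],
        "arm_id": ["a"] * n,
        "outcome": 10.0,
    })
    for col, c in counts.items():
        df[col] = [1.0] * c + [0.0] * (n - c)
    return ArmTable(df, {c: "presence" for c in counts})


def test_prune_rare_boundary():
    t = make_presence_table({"rare": 29, "boundary": 30, "common": 50})
    pruned, removed = prune_rare(t, min_count=30)
    assert removed == ["rare"]
    assert set(pruned.feature_columns) == {"boundary", "common"}
    _, none_removed = prune_rare(make_presence_table({"common": 40}), 30)
    assert none_removed == []


def test_aggregate_by_hierarchy_max():
    g = OntologyGraph([Feature(id="child_a", parent_id="parent"),
                       Feature(id="child_b", parent_id="parent"),
                       Feature(id="parent"), Feature(id="orphan")])
    t = make_presence_table({"child_a": 5, "child_b": 10, "orphan": 3}, n=20)
    t.df["parent"] = 0.0
    t.column_kinds["parent"] = "presence"
    out = aggregate_by_hierarchy(ArmTable(t.df, t.column_kinds), g,
                                 removed=["child_a", "child_b", "orphan"])
    # parent = max over the two removed siblings, arm-wise
    assert out.df["parent"].tolist() == [1.0] * 10 + [0.0] * 10
    for gone in ("child_a", "child_b", "orphan"):
        assert gone not in out.df.columns


def test_aggregate_absent_child_leaves_parent():
    g = OntologyGraph([Feature(id="kid", parent_id="parent"), Feature(id="parent")])
    t = make_presence_table({"kid": 0}, n=10)
    t.df["parent"] = [1.0] * 4 + [0.0] * 6
    t.column_kinds["parent"] = "presence"
    out = aggregate_by_hierarchy(ArmTable(t.df, t.column_kinds), g, removed=["kid"])
    assert out.df["parent"].tolist() == [1.0] * 4 + [0.0] * 6


# ----------------------------------------------------------------------
# pipeline


def test_prepare_table_end_to_end(toy_graph):
    rng = np.random.default_rng(5)
    n = 120
    raw = pd.DataFrame({
        "study_id": [f"s{i // 2}" for i in range(n)],
        "arm_id": [f"a{i % 2}" for i in range(n)],
        "outcome": rng.uniform(0, 40, n),
        "NRT": (rng.random(n) < 0.5).astype(float),
        "nurse": (rng.random(n) < 0.6).astype(float),
        "mean_age": np.where(rng.random(n) < 0.1, np.nan, rng.uniform(20, 70, n)),
    })
    table = prepare_table(raw, binarizers={"mean_age": AGE}, graph=toy_graph,
                          min_count=5)
    vals = table.memberships()
    assert vals.min() >= 0 and vals.max() <= 1
    assert "not nurse" in table.feature_columns
    assert "mean_age (reported)" in table.feature_columns
    assert "not mean_age: child" not in table.feature_columns
    # hierarchy completed: parents at least as on as children
    assert (table.df["pharmacological_support"] >= table.df["NRT"] - 1e-12).all()
    # deterministic
    again = prepare_table(raw, binarizers={"mean_age": AGE}, graph=toy_graph,
                          min_count=5)
    pd.testing.assert_frame_equal(table.df, again.df)


def test_prepare_table_row_filters(toy_graph):
    raw = pd.DataFrame({
        "study_id": ["s1", "s1", "s2", "s3"],
        "arm_id": ["a", "b", "a", "a"],
        "outcome": [10, 20, 30, 40],
        "nurse": [1.0, 0.0, 1.0, 0.0],
    })
    table = prepare_table(raw, min_count=0, exclude_studies=["s2"],
                          exclude_arms=[("s1", "b")])
    assert table.n_arms == 2
    assert set(table.df["study_id"]) == {"s1", "s3"}
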