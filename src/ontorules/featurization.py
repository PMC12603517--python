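"""Binarization of mixed-type arm features into fuzzy literal columns.

The rule learner requires every input to be a literal with a membership in
[0, 1].  Five binarization approaches cover the different meanings numeric
features can carry:

1. ``semantic``    — named categories with fuzzy boundaries (mean age →
   child / young adult / older adult / elderly).
2. ``fixed_width`` — ordered ``value < t`` thresholds at fixed spacing
   (cigarettes per day → <5, <10, ..., <50); membership is non-decreasing
   in t, so a value of 6 turns on <10 through <50 but not <5.
3. ``quantile``    — ``value < t`` thresholds at data quantiles.
4. ``exact_value`` — a crisp flag for a single meaningful value
   (100% female).
5. ``cluster``     — data-driven 1-D clustering into value ranges.

Fuzzy memberships use a logistic operator: membership(value < t) =
1 / (1 + exp((value − t) / τ)), with temperature τ defaulting to 10% of the
bin width; τ → 0 recovers crisp thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .arm_table import ArmTable, META_COLUMNS

__all__ = [
    "BinarizerSpec",
    "binarize_fixed_width",
    "binarize_semantic",
    "binarize_quantile",
    "flag_exact",
    "binarize_cluster",
    "apply_binarizer",
    "expand_literals",
    "prune_rare",
    "aggregate_by_hierarchy",
    "prepare_table",
]

log = logging.getLogger(__name__)

EXACT_RTOL = 1e-9  # exact_value flags are semantic markers, not measurements


@dataclass
class BinarizerSpec:
    """How one numeric source feature becomes literal columns."""

    source_feature: str
    method: str  # semantic | fixed_width | quantile | exact_value | cluster
    thresholds: Sequence[float] = ()            # fixed_width / quantile
    categories: Sequence[tuple[str, float]] = ()  # semantic/cluster: (label, upper breakpoint); last has +inf
    target_value: float | None = None           # exact_value
    temperature: float | None = None            # None → 10% of bin width

    def __post_init__(self) -> None:
        if self.method not in ("semantic", "fixed_width", "quantile", "exact_value", "cluster"):
            raise ValueError(f"unknown binarization method {self.method!r}")
        th = list(self.thresholds)
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.temperature is not None and self.temperature <= 0:
            raise ValueError("temperature must be positive")

    # ------------------------------------------------------------------
    def default_temperature(self) -> float:
        if self.temperature is not None:
            return self.temperature
        pts = [t for _, t in self.categories if np.isfinite(t)] or list(self.thresholds)
        if len(pts) >= 2:
            width = float(np.min(np.diff(sorted(pts))))
        elif pts:
            width = abs(pts[0]) or 1.0
        else:
            width = 1.0
        return 0.1 * width

    def column_names(self) -> list[str]:
        f = self.source_feature
        if self.method in ("fixed_width", "quantile"):
            return [f"{f} < {t:g}" for t in self.thresholds]
        if self.method in ("semantic", "cluster"):
            return [f"{f}: {label}" for label, _ in self.categories]
        return [f"{f} = {self.target_value:g}"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))


def binarize_fixed_width(value, spec: BinarizerSpec) -> np.ndarray:
    """Fuzzy memberships of ``value < t`` for each threshold t.

    Returns an array of shape ``(n_values, n_thresholds)`` (or
    ``(n_thresholds,)`` for a scalar).  Memberships are non-decreasing in t
    for every value; missing values give all-zero rows (callers emit a
    reported-flag literal alongside).
    """
    if spec.method not in ("fixed_width", "quantile"):
        raise ValueError("spec method must be fixed_width or quantile")
    v = np.atleast_1d(np.asarray(value, dtype=float))
    tau = spec.default_temperature()
    th = np.asarray(spec.thresholds, dtype=float)
    out = _sigmoid((v[:, None] - th[None, :]) / tau)
    out[np.isnan(v)] = 0.0
    return out[0] if np.isscalar(value) or np.asarray(value).ndim == 0 else out


def binarize_semantic(value, spec: BinarizerSpec) -> np.ndarray:
    """Fuzzy memberships of named categories with soft breakpoints.

    Category j spans (b_{j−1}, b_j]; its membership is the product of a
    rising logistic at the lower breakpoint and a falling one at the upper.
    At a breakpoint the two adjacent categories are each ≈ 0.5; far from
    boundaries exactly one category ≈ 1.
    """
    if spec.method not in ("semantic", "cluster"):
        raise ValueError("spec method must be semantic or cluster")
    if not spec.categories:
        raise ValueError("semantic spec needs categories")
    v = np.atleast_1d(np.asarray(value, dtype=float))
    tau = spec.default_temperature()
    uppers = [t for _, t in spec.categories]
    lowers = [-np.inf] + uppers[:-1]
    cols = []
    for lo, hi in zip(lowers, uppers):
        m = np.ones_like(v)
        if np.isfinite(lo):
            m = m * _sigmoid((lo - v) / tau)  # rising at lo
        if np.isfinite(hi):
            m = m * _sigmoid((v - hi) / tau)  # falling at hi
        cols.append(m)
    out = np.stack(cols, axis=-1)
    out[np.isnan(v)] = 0.0
    return out[0] if np.isscalar(value) or np.asarray(value).ndim == 0 else out


def binarize_quantile(values: Sequence[float], q: int, source_feature: str = "x",
                      temperature: float | None = None) -> BinarizerSpec:
    """Build a fixed-width-style spec with thresholds at q-quantile bounds.

    Uses linear interpolation of order statistics.  ``q = 1`` degenerates to
    an empty threshold set; fewer than ``q`` distinct finite values is an
    error (an exact_value flag is the right tool there).
    """
    if q < 1:
        raise ValueError("q must be ≥ 1")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(np.unique(v)) < q:
        raise ValueError(
            f"{source_feature}: fewer than {q} distinct values; "
            "consider an exact_value flag instead"
        )
    if q == 1:
        th: list[float] = []
    else:
        probs = np.arange(1, q) / q
        th = list(np.quantile(v, probs, method="linear"))
        th = sorted(set(th))
    return BinarizerSpec(source_feature, "quantile", thresholds=th,
                         temperature=temperature)


def flag_exact(value, spec: BinarizerSpec) -> np.ndarray:
    """Crisp flag: 1 iff value equals the target within tolerance."""
    if spec.method != "exact_value":
        raise ValueError("spec method must be exact_value")
    v = np.atleast_1d(np.asarray(value, dtype=float))
    t = float(spec.target_value)
    tol = EXACT_RTOL * max(abs(t), 1.0)
    out = (np.abs(v - t) <= tol).astype(float)
    out[np.isnan(v)] = 0.0
    return out[0] if np.isscalar(value) or np.asarray(value).ndim == 0 else out


# ----------------------------------------------------------------------
# 1-D clustering: exhaustive segmentation minimising within-segment variance.


def _segment_cost(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    # within-segment sum of squares for sorted values v[i:j]
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / n


def _best_segmentation(v: np.ndarray, k: int) -> tuple[float, list[int]]:
    """Optimal split of sorted v into k contiguous segments (dynamic program)."""
    n = len(v)
    prefix = np.concatenate([[0.0], np.cumsum(v)])
    prefix2 = np.concatenate([[0.0], np.cumsum(v * v)])
    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            for i in range(kk - 1, j):
                if cost[kk - 1, i] == INF:
                    continue
                c = cost[kk - 1, i] + _segment_cost(prefix, prefix2, i, j)
                if c < cost[kk, j] - 1e-15:
                    cost[kk, j] = c
                    back[kk, j] = i
    bounds = [n]
    j = n
    for kk in range(k, 0, -1):
        j = back[kk, j]
        bounds.append(j)
    return cost[k, n], sorted(bounds)


def binarize_cluster(values: Sequence[float], k_max: int = 4,
                     source_feature: str = "x",
                     temperature: float | None = None) -> BinarizerSpec:
    """Cluster a 1-D sample into value ranges and emit a semantic-style spec.

    Exhaustive contiguous segmentation of the sorted sample minimising
    within-segment variance (dynamic programming).  The segment count
    k ≤ k_max is the largest one whose optimal segmentation splits only at
    genuine gaps — every boundary gap must exceed 3× the median spacing of
    consecutive sorted values — so a single tight cluster stays one range
    regardless of its absolute scale.  Breakpoints sit at boundary
    midpoints; the spec is invariant to input ordering.
    """
    v = np.sort(np.asarray(values, dtype=float))
    v = v[np.isfinite(v)]
    if len(np.unique(v)) < 2:
        raise ValueError(f"{source_feature}: need ≥ 2 distinct values to cluster")
    k_max = min(k_max, len(np.unique(v)))
    diffs = np.diff(v)
    min_gap = 3.0 * float(np.median(diffs[diffs > 0]))
    k_star = 1
    for k in range(k_max, 1, -1):
        _, bounds = _best_segmentation(v, k)
        gaps = [v[b] - v[b - 1] for b in bounds[1:-1]]
        if all(gap >= min_gap for gap in gaps):
            k_star = k
            break
    _, bounds = _best_segmentation(v, k_star)
    categories = []
    for idx in range(k_star):
        lo, hi = bounds[idx], bounds[idx + 1]
        if idx < k_star - 1:
            upper = 0.5 * (v[hi - 1] + v[hi])  # midpoint of the gap
        else:
            upper = np.inf
        categories.append((f"range{idx + 1}", float(upper)))
    return BinarizerSpec(source_feature, "cluster", categories=categories,
                         temperature=temperature)


# ----------------------------------------------------------------------


def apply_binarizer(values, spec: BinarizerSpec) -> np.ndarray:
    """Dispatch to the right membership function; shape (n, n_columns)."""
    v = np.atleast_1d(np.asarray(values, dtype=float))
    if spec.method in ("fixed_width", "quantile"):
        return np.atleast_2d(binarize_fixed_width(v, spec))
    if spec.method in ("semantic", "cluster"):
        return np.atleast_2d(binarize_semantic(v, spec))
    return np.atleast_2d(flag_exact(v, spec)).reshape(-1, 1)


def expand_literals(table: ArmTable) -> ArmTable:
    """Add a ``not <feature>`` complement column for every presence feature.

    The rule language includes known absence ("not nurse"), so each
    presence literal gets a complement with membership 1 − x.  Range
    literals and reported-flags get no complement.
    """
    df = table.df.copy()
    kinds = dict(table.column_kinds)
    for col in table.feature_columns:
        if table.kind(col) != "presence":
            continue
        neg = f"not {col}"
        if neg in df.columns:
            continue
        df[neg] = 1.0 - df[col].astype(float)
        kinds[neg] = "negated"
    return ArmTable(df, kinds)


def prune_rare(table: ArmTable, min_count: int = 30) -> tuple[ArmTable, list[str]]:
    """Remove literal columns present (membership > 0.5) in < min_count arms.

    Applied before literal expansion; a feature present in exactly
    ``min_count`` arms is retained ("fewer than" is strict).  Returns the
    pruned table and the removed column names.
    """
    removed = []
    for col in table.feature_columns:
        if table.kind(col) == "negated":
            continue
        n_present = int((table.df[col].astype(float) > 0.5).sum())
        if n_present < min_count:
            removed.append(col)
    df = table.df.drop(columns=removed)
    kinds = {c: k for c, k in table.column_kinds.items() if c not in removed}
    return ArmTable(df, kinds), removed


def aggregate_by_hierarchy(table: ArmTable, graph, removed: Sequence[str]) -> ArmTable:
    """Fold removed rare features into their ontology parents.

    ``table`` must still contain the removed columns.  For each removed
    feature with a parent in the graph the parent column becomes the max of
    itself and the child; the child column is dropped.  Removed features
    without a parent are dropped with a warning (their information is lost).
    """
    df = table.df.copy()
    kinds = dict(table.column_kinds)
    for col in removed:
        if col not in df.columns:
            continue
        parent = graph.parent(col) if col in getattr(graph, "features", {}) else None
        if parent is None:
            log.warning("rare feature %r has no parent; dropped without aggregation", col)
        else:
            if parent not in df.columns:
                df[parent] = 0.0
                kinds[parent] = kinds.get(col, "presence")
            df[parent] = np.maximum(df[parent].astype(float), df[col].astype(float))
        df = df.drop(columns=[col])
        kinds.pop(col, None)
    return ArmTable(df, kinds)


# ----------------------------------------------------------------------


def prepare_table(
    raw: pd.DataFrame,
    binarizers: dict[str, BinarizerSpec] | None = None,
    graph=None,
    min_count: int = 30,
    exclude_arms: Sequence[tuple[str, str]] = (),
    exclude_studies: Sequence[str] = (),
) -> ArmTable:
    """Full featurization pipeline: raw mixed table → training-ready literals.

    Steps: declarative row filters (by study/arm id), binarization of
    numeric features per spec (with reported-flags for missing values),
    rarity pruning with hierarchy aggregation of the removed features,
    hierarchy completion, then literal expansion.  Deterministic given its
    inputs.
    """
    from .ontology import complete_hierarchy

    df = raw.copy()
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table missing required columns {missing}")
    if exclude_studies:
        df = df[~df["study_id"].isin(set(exclude_studies))]
    if exclude_arms:
        bad = set(map(tuple, exclude_arms))
        keep = [tuple(x) not in bad for x in df[["study_id", "arm_id"]].itertuples(index=False)]
        df = df[keep]
    df = df.reset_index(drop=True)

    binarizers = binarizers or {}
    out = df[list(META_COLUMNS)].copy()
    kinds: dict[str, str] = {}
    for col in df.columns:
        if col in META_COLUMNS:
            continue
        if col in binarizers:
            spec = binarizers[col]
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            mat = apply_binarizer(vals, spec)
            for name, column in zip(spec.column_names(), mat.T):
                out[name] = column
                kinds[name] = "flag" if spec.method == "exact_value" else "range"
            rep = f"{col} (reported)"
            out[rep] = np.isfinite(vals).astype(float)
            kinds[rep] = "flag"
        else:
            vals = pd.to_numeric(df[col], errors="coerce").fillna(0.0)
            out[col] = vals.clip(0.0, 1.0)
            kinds[col] = "presence"

    table = ArmTable(out, kinds)
    table, removed = prune_rare(table, min_count=min_count)
    if removed and graph is not None:
        # fold the removed columns (still in the pre-prune frame) into parents
        pre = ArmTable(out, kinds)
        table = aggregate_by_hierarchy(pre, graph, removed)
        keep = [c for c in table.feature_columns if c not in removed]
        table = ArmTable(table.df[list(META_COLUMNS) + keep],
                         {c: table.column_kinds[c] for c in keep})
    if graph is not None:
        known = set(graph.features)
        if any(c in known for c in table.feature_columns):
            table = complete_hierarchy(table, graph)
    return expand_literals(table)
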