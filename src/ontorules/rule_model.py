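"""The soft-rule regression model.

A model is a set of *soft conjunction rules*.  Each rule r carries a
selection weight s_{r,l} ∈ [0,1] for every literal l in the schema and a
signed rule weight w_r in percentage points.  The rule's fit on an arm with
memberships x is the weighted product t-norm

    fit_r(x) = Π_l (1 − s_{r,l} · (1 − x_l)),

which exactly interpolates a crisp conjunction: s = 1 demands the literal,
s = 0 makes it irrelevant.  The prediction is linear in the fits,

    ŷ(x) = intercept + Σ_r w_r · fit_r(x).

Interpretability is enforced by three penalties on the selections — rule
length Σ s, crispness Σ s(1−s), and a semantic penalty punishing co-selected
literal pairs that the ontology marks disjoint or redundant — after which
thresholding the selections ("crispifying") yields ordinary boolean rules.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .ontology import Literal, OntologyGraph

__all__ = [
    "SoftRuleSet",
    "CrispRule",
    "CrispRuleSet",
    "rule_fit",
    "soft_fits",
    "predict",
    "penalty_length",
    "penalty_crispness",
    "penalty_semantic",
    "semantic_pair_matrix",
    "crispify",
]

log = logging.getLogger(__name__)

#: default penalty coefficients, relative to the outcome-variance scale:
#: semantic violations must dominate, crispness next, sparsity gentlest.
DEFAULT_LAMBDA_LEN = 1e-3
DEFAULT_LAMBDA_CRISP = 1e-2
DEFAULT_LAMBDA_SEM = 1e-1
DEFAULT_CRISP_THRESHOLD = 0.5


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _logit(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


@dataclass(frozen=True)
class CrispRule:
    """A boolean conjunction with an additive weight in percentage points."""

    conjunction: frozenset[str]
    weight: float

    def fit(self, memberships: dict[str, float]) -> float:
        out = 1.0
        for tok in self.conjunction:
            out *= float(memberships[tok])
        return out

    def __str__(self) -> str:  # pragma: no cover
        lhs = " ∧ ".join(sorted(self.conjunction)) or "⊤"
        return f"{lhs} → {self.weight:+.3g}"


@dataclass
class CrispRuleSet:
    """A crisp model: conjunctions → weights, plus an intercept."""

    rules: list[CrispRule]
    intercept: float = 0.0

    def lhs_set(self) -> set[frozenset[str]]:
        return {r.conjunction for r in self.rules}

    def predict_row(self, memberships: dict[str, float]) -> float:
        return self.intercept + sum(r.weight * r.fit(memberships) for r in self.rules)

    def predict(self, table) -> np.ndarray:
        cols = {c: table.df[c].to_numpy(dtype=float) for c in table.feature_columns}
        out = np.full(table.n_arms, self.intercept, dtype=float)
        for r in self.rules:
            fit = np.ones(table.n_arms)
            for tok in r.conjunction:
                fit = fit * cols[tok]
            out += r.weight * fit
        return out

    def mean_rule_length(self) -> float:
        if not self.rules:
            return 0.0
        return float(np.mean([len(r.conjunction) for r in self.rules]))

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "rules": [
                {"conjunction": sorted(r.conjunction), "weight": r.weight}
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrispRuleSet":
        return cls(
            rules=[
                CrispRule(frozenset(r["conjunction"]), float(r["weight"]))
                for r in d.get("rules", [])
            ],
            intercept=float(d.get("intercept", 0.0)),
        )

    def save(self, path: str | Path, provenance: dict | None = None) -> None:
        d = self.to_dict()
        if provenance:
            d["provenance"] = provenance
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CrispRuleSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SoftRuleSet:
    """Trainable model: per-rule selection logits and rule weights.

    Selections are stored as unconstrained logits ``theta``; the selection
    matrix is ``sigmoid(theta)``, so gradient steps cannot leave [0, 1].
    Penalty coefficients are relative and multiplied by ``penalty_scale``
    (the training-outcome variance) inside the loss, which keeps their
    meaning independent of the outcome units.
    """

    schema: list[str]
    theta: np.ndarray  # (R, L) selection logits
    weights: np.ndarray  # (R,)
    intercept: float = 0.0
    lambda_len: float = DEFAULT_LAMBDA_LEN
    lambda_crisp: float = DEFAULT_LAMBDA_CRISP
    lambda_sem: float = DEFAULT_LAMBDA_SEM
    crisp_threshold: float = DEFAULT_CRISP_THRESHOLD
    penalty_scale: float = 1.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[0] != len(self.weights):
            raise ValueError("theta must be (n_rules, n_literals) matching weights")
        if self.theta.shape[1] != len(self.schema):
            raise ValueError("theta width must equal schema length")
        if self.theta.shape[0] < 1:
            raise ValueError("a rule set needs at least one rule")
        if min(self.lambda_len, self.lambda_crisp, self.lambda_sem) < 0:
            raise ValueError("penalty coefficients must be non-negative")
        if not (0 < self.crisp_threshold < 1):
            raise ValueError("crisp_threshold must lie in (0, 1)")

    @property
    def n_rules(self) -> int:
        return self.theta.shape[0]

    @property
    def selection(self) -> np.ndarray:
        """The (R, L) selection matrix s = sigmoid(theta)."""
        return _sigmoid(self.theta)

    def copy(self) -> "SoftRuleSet":
        return SoftRuleSet(
            list(self.schema), self.theta.copy(), self.weights.copy(),
            self.intercept, self.lambda_len, self.lambda_crisp,
            self.lambda_sem, self.crisp_threshold, self.penalty_scale,
        )


# ----------------------------------------------------------------------
# Forward evaluation.


def rule_fit(selection: np.ndarray, memberships: np.ndarray) -> float:
    """Fit of one rule on one arm: Π_l (1 − s_l (1 − x_l))."""
    x = np.asarray(memberships, dtype=float)
    if x.size and (x.min() < -1e-9 or x.max() > 1 + 1e-9):
        raise ValueError("memberships must lie in [0, 1]")
    s = np.asarray(selection, dtype=float)
    return float(np.prod(1.0 - s * (1.0 - x)))

def soft_fits(model: SoftRuleSet, X: np.ndarray) -> np.ndarray:
    """Fits of every rule on every arm; shape (n_arms, n_rules)."""
    X = np.asarray(X, dtype=float)
    if X.size and (X.min() < -1e-9 or X.max() > 1 + 1e-9):
        raise ValueError("memberships must lie in [0, 1]")
    s = model.selection  # (R, L)
    g = 1.0 - s[None, :, :] * (1.0 - X[:, None, :])  # (N, R, L)
    return g.prod(axis=2)


def predict(model: SoftRuleSet, X: np.ndarray, clip: bool = False) -> np.ndarray:
    """Predicted outcome percentage for each arm.

    The raw linear combination is returned by default; ``clip=True`` maps
    it into [0, 100] for presentation (training always uses raw values).
    """
    out = model.intercept + soft_fits(model, X) @ model.weights
    return np.clip(out, 0.0, 100.0) if clip else out


# ----------------------------------------------------------------------
# Penalties.


def penalty_length(model: SoftRuleSet) -> float:
    """Soft rule length: λ_len · Σ_r Σ_l s_{r,l} (times the penalty scale)."""
    return float(model.lambda_len * model.penalty_scale * model.selection.sum())


def penalty_crispness(model: SoftRuleSet) -> float:
    """λ_crisp · Σ s(1−s); zero iff every selection is exactly 0 or 1."""
    s = model.selection
    return float(model.lambda_crisp * model.penalty_scale * (s * (1.0 - s)).sum())


def semantic_pair_matrix(graph: OntologyGraph, schema: Sequence[str]) -> np.ndarray:
    """Symmetric (L, L) 0/1 matrix of semantically penalised literal pairs.

    A pair is penalised when the two literals contradict under the ontology
    closure (disjointness, complements) or when either entails the other
    (a redundant implied literal — an asserted ancestor of an asserted
    feature, a negated descendant of a negated feature, or a literal forced
    by a disjointness axiom).  Schema tokens whose feature is unknown to
    the graph are ignored.
    """
    L = len(schema)
    lits: list[Literal | None] = []
    for tok in schema:
        lit = Literal.parse(tok)
        lits.append(lit if lit.feature_id in graph.features else None)
    M = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            a, b = lits[i], lits[j]
            if a is None or b is None:
                continue
            bad = (graph.pair_contradicts(a, b)
                   or graph.entails(a, b) or graph.entails(b, a))
            if bad:
                M[i, j] = M[j, i] = 1.0
    return M


def penalty_semantic(model: SoftRuleSet, graph: OntologyGraph,
                     pair_matrix: np.ndarray | None = None) -> float:
    """λ_sem · Σ_r Σ_{penalised pairs (a,b)} s_{r,a} · s_{r,b}."""
    M = pair_matrix if pair_matrix is not None else semantic_pair_matrix(graph, model.schema)
    s = model.selection
    per_rule = 0.5 * np.einsum("rl,lk,rk->r", s, M, s)
    return float(model.lambda_sem * model.penalty_scale * per_rule.sum())


# ----------------------------------------------------------------------
# Crispification.


#: rules whose |weight| falls below this many percentage points are treated
#: as noise and dropped at crispification; half a point is far below any
#: practically relevant intervention effect.
DEFAULT_MIN_RULE_WEIGHT = 0.5


def crispify(model: SoftRuleSet, graph: OntologyGraph,
             min_weight: float = DEFAULT_MIN_RULE_WEIGHT) -> CrispRuleSet:
    """Threshold the selections into boolean rules and simplify them.

    Per rule: keep literals with s ≥ crisp_threshold, simplify the
    conjunction under the ontology (implied literals dropped), drop rules
    whose conjunction is contradictory (with a warning), and fold empty
    conjunctions into the intercept (an empty conjunction fits every arm).
    Rules sharing a conjunction after simplification are merged by summing
    weights; merged rules with |weight| < min_weight are dropped as a
    reporting floor (set min_weight=0 to keep everything).
    """
    s = model.selection
    intercept = float(model.intercept)
    merged: dict[frozenset[str], float] = {}
    for r in range(model.n_rules):
        chosen = [model.schema[l] for l in np.nonzero(s[r] >= model.crisp_threshold)[0]]
        lits = [Literal.parse(tok) for tok in chosen]
        known = all(l.feature_id in graph.features for l in lits)
        if known and graph.contradicts(lits):
            log.warning("dropping contradictory crispified rule %s", chosen)
            continue
        if known:
            conj = frozenset(l.token for l in graph.simplify_conjunction(lits))
        else:
            conj = frozenset(chosen)
        w = float(model.weights[r])
        if not conj:
            intercept += w
        else:
            merged[conj] = merged.get(conj, 0.0) + w
    rules = [CrispRule(c, w) for c, w in sorted(merged.items(), key=lambda t: sorted(t[0]))
             if abs(w) >= min_weight]
    return CrispRuleSet(rules, intercept)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
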