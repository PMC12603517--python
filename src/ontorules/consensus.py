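"""Consensus aggregation of many independently trained rule sets.

Training is stochastic and the data under-constrain the rules, so repeated
runs produce different but equally predictive rule sets.  The consensus
procedure trains R independent models, counts in how many models each
conjunction appears, and keeps the conjunctions that appear more often than
a hypergeometric null expects: if rules drew their literals at random, a
fixed k-literal conjunction would be contained in an m-literal rule with
probability

    P = C(n−k, m−k) / C(n, m)

(k = conjunction length, m = mean rule length over all models, floored;
n = number of literals in the schema).  A conjunction is retained when its
support exceeds ``selection_factor`` (default 1.3) times its expected
appearance count.  The surviving conjunctions are frozen and their weights
re-fitted on all the data ("fine-tuning").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import comb

from .arm_table import ArmTable
from .ontology import OntologyGraph
from .rule_model import CrispRule, CrispRuleSet, crispify
from .training import TrainConfig, train

__all__ = [
    "ConjunctionStats",
    "ConsensusModel",
    "run_ensemble",
    "expected_count",
    "build_consensus",
    "fine_tune",
    "jaccard",
    "weight_agreement",
]

log = logging.getLogger(__name__)


@dataclass
class ConjunctionStats:
    """Cross-model bookkeeping for one conjunction."""

    conjunction: frozenset[str]
    support: int
    expected: float
    weights: list[float]
    mean_weight: float
    sd_weight: float  # population standard deviation
    low_support: bool = False


@dataclass
class ConsensusModel:
    """Crisp consensus rule set with its selection audit trail."""

    ruleset: CrispRuleSet
    stats: list[ConjunctionStats]
    selection_factor: float
    mean_rule_length: float  # m of the hypergeometric null
    n_literals: int          # n of the hypergeometric null
    runs: int                # R, number of models aggregated
    rules_per_model: float   # ρ, mean rule count per model
    fine_tuned: bool = False
    train_mae: float | None = None

    @property
    def rules(self) -> list[CrispRule]:
        return self.ruleset.rules

    def to_dict(self) -> dict:
        stat_by_lhs = {s.conjunction: s for s in self.stats}
        rules = []
        for r in self.ruleset.rules:
            s = stat_by_lhs.get(r.conjunction)
            rules.append({
                "conjunction": sorted(r.conjunction),
                "weight": r.weight,
                "support": s.support if s else None,
                "expected": s.expected if s else None,
                "mean_weight": s.mean_weight if s else None,
                "sd_weight": s.sd_weight if s else None,
            })
        return {
            "intercept": self.ruleset.intercept,
            "rules": rules,
            "consensus": {
                "selection_factor": self.selection_factor,
                "mean_rule_length": self.mean_rule_length,
                "n_literals": self.n_literals,
                "runs": self.runs,
                "rules_per_model": self.rules_per_model,
                "fine_tuned": self.fine_tuned,
                "train_mae": self.train_mae,
            },
        }


# ----------------------------------------------------------------------


def run_ensemble(
    table: ArmTable,
    graph: OntologyGraph,
    config: TrainConfig,
    runs: int,
) -> list[CrispRuleSet]:
    """Train and crispify ``runs`` independent models (seeds seed+0..runs−1).

    Left-hand sides are deduplicated within each model by crispify (weights
    of duplicate conjunctions merge by summation).  Individual run failures
    are logged and skipped; fewer than 2 surviving runs is an error.
    """
    if runs < 2:
        raise ValueError("consensus needs at least 2 runs")
    models: list[CrispRuleSet] = []
    for i in range(runs):
        cfg = TrainConfig(**{**config.to_dict(), "seed": config.seed + i})
        try:
            result = train(table, graph, cfg)
            models.append(crispify(result.model, graph))
        except Exception:  # pragma: no cover - defensive
            log.exception("training run %d failed; skipping", i)
    if len(models) < 2:
        raise RuntimeError(f"only {len(models)} of {runs} runs survived")
    return models


def expected_count(k: int, m: float, n: int, runs: int,
                   rules_per_model: float = 1.0) -> float:
    """Expected appearances of a fixed k-literal conjunction across runs.

    P(contained) = C(n−k, ⌊m⌋−k) / C(n, ⌊m⌋); expected = runs · ρ · P with
    ρ the mean number of rules per model.  k must satisfy 0 < k ≤ m ≤ n.
    """
    m_int = int(np.floor(m))
    if not (0 < k <= m and m <= n):
        raise ValueError(f"need 0 < k ≤ m ≤ n, got k={k}, m={m}, n={n}")
    if k > m_int:
        return 0.0
    p = comb(n - k, m_int - k, exact=True) / comb(n, m_int, exact=True)
    return runs * rules_per_model * float(p)


def _collect_stats(models: Sequence[CrispRuleSet]) -> dict[frozenset[str], list[float]]:
    weights: dict[frozenset[str], list[float]] = {}
    for model in models:
        for rule in model.rules:
            weights.setdefault(rule.conjunction, []).append(rule.weight)
    return weights


def weight_agreement(models: Sequence[CrispRuleSet],
                     expected: dict[frozenset[str], float] | None = None
                     ) -> list[ConjunctionStats]:
    """Per-conjunction mean and population SD of weights across models.

    A conjunction present in a single model gets sd 0 and is flagged
    low-support; a large sd relative to |mean| signals sign disagreement
    between models.
    """
    if len(models) < 2:
        raise ValueError("weight agreement needs ≥ 2 models")
    stats = []
    for conj, ws in sorted(_collect_stats(models).items(), key=lambda t: sorted(t[0])):
        arr = np.asarray(ws)
        stats.append(ConjunctionStats(
            conjunction=conj,
            support=len(ws),
            expected=(expected or {}).get(conj, float("nan")),
            weights=list(ws),
            mean_weight=float(arr.mean()),
            sd_weight=float(arr.std()),  # population convention
            low_support=len(ws) < 2,
        ))
    return stats


def build_consensus(
    models: Sequence[CrispRuleSet],
    graph: OntologyGraph,
    n_literals: int,
    selection_factor: float = 1.3,
    keep_supported_singletons: bool = True,
    min_support: int = 2,
) -> ConsensusModel:
    """Select conjunctions appearing more often than the hypergeometric null.

    Support counts one appearance per model; the null expectation scales by
    the mean rule count per model ρ.  Retention requires
    support > selection_factor · expected (strict) and support ≥
    min_support — a conjunction seen in a single model trivially beats a
    near-zero null expectation but is not a consensus.  Singletons with any
    support are always eligible when ``keep_supported_singletons`` (the
    deployed model's per-feature baseline rules); set it False to subject
    singletons to the same criterion.  Output is invariant to model order.
    """
    if len(models) < 2:
        raise ValueError("consensus needs ≥ 2 models")
    runs = len(models)
    all_lengths = [len(r.conjunction) for mdl in models for r in mdl.rules]
    mean_len = float(np.mean(all_lengths)) if all_lengths else 0.0
    rho = len(all_lengths) / runs

    weights = _collect_stats(models)
    expected_by_conj: dict[frozenset[str], float] = {}
    kept: list[ConjunctionStats] = []
    for conj, ws in weights.items():
        k = len(conj)
        if mean_len >= 1 and k <= n_literals:
            exp = expected_count(k, max(mean_len, k), n_literals, runs, rho) \
                if k <= mean_len else 0.0
        else:
            exp = 0.0
        expected_by_conj[conj] = exp
        support = len(ws)
        keep = support > selection_factor * exp and support >= min_support
        if keep_supported_singletons and k == 1 and support > 0:
            keep = True
        if keep:
            arr = np.asarray(ws)
            kept.append(ConjunctionStats(
                conjunction=conj, support=support, expected=exp,
                weights=list(ws), mean_weight=float(arr.mean()),
                sd_weight=float(arr.std()), low_support=support < 2,
            ))

    kept.sort(key=lambda s: sorted(s.conjunction))
    rules = [CrispRule(s.conjunction, s.mean_weight) for s in kept]
    intercept = float(np.mean([m.intercept for m in models]))
    return ConsensusModel(
        ruleset=CrispRuleSet(rules, intercept),
        stats=kept,
        selection_factor=selection_factor,
        mean_rule_length=mean_len,
        n_literals=n_literals,
        runs=runs,
        rules_per_model=rho,
    )


def fine_tune(consensus: ConsensusModel, table: ArmTable) -> ConsensusModel:
    """Re-fit the consensus weights on all data, conjunctions frozen.

    Closed-form least squares on the crisp fit matrix (columns: 1 and each
    rule's fit), solved by minimum-norm lstsq so a rank-deficient matrix
    (always the case when a rule fires on every arm, which aliases the
    intercept) is handled deterministically; predictions are the contract.
    """
    if not consensus.rules:
        raise ValueError("cannot fine-tune an empty consensus")
    data = table.with_outcomes_only()
    cols = {c: data.df[c].to_numpy(dtype=float) for c in data.feature_columns}
    n = data.n_arms
    F = np.ones((n, len(consensus.rules) + 1))
    for j, rule in enumerate(consensus.rules, start=1):
        fit = np.ones(n)
        for tok in rule.conjunction:
            fit = fit * cols[tok]
        F[:, j] = fit
    y = data.outcomes()
    coef, _, rank, _ = np.linalg.lstsq(F, y, rcond=None)
    if rank < F.shape[1]:
        log.info("fine-tune fit matrix rank-deficient (%d < %d); minimum-norm "
                 "least squares used", rank, F.shape[1])
    new_rules = [CrispRule(r.conjunction, float(w))
                 for r, w in zip(consensus.rules, coef[1:])]
    ruleset = CrispRuleSet(new_rules, float(coef[0]))
    mae = float(np.mean(np.abs(F @ coef - y)))
    return ConsensusModel(
        ruleset=ruleset,
        stats=consensus.stats,
        selection_factor=consensus.selection_factor,
        mean_rule_length=consensus.mean_rule_length,
        n_literals=consensus.n_literals,
        runs=consensus.runs,
        rules_per_model=consensus.rules_per_model,
        fine_tuned=True,
        train_mae=mae,
    )


def jaccard(model_a: CrispRuleSet | Sequence[CrispRule],
            model_b: CrispRuleSet | Sequence[CrispRule]) -> float:
    """Jaccard similarity of the models' left-hand-side sets; 1 if both empty."""

    def lhs(m):
        rules = m.rules if isinstance(m, CrispRuleSet) else m
        return {r.conjunction for r in rules}

    a, b = lhs(model_a), lhs(model_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
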