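"""Scenario prediction with rule-level explanations.

A *scenario* describes a hypothetical intervention setting: population
values (mean age, cigarettes per day, percent female, ...), a set of
intervention features, and methodology settings (follow-up, verification,
abstinence definition).  The model produces two predictions — a control
prediction with the intervention content switched off and the ``control``
outcome feature on, and an intervention prediction with the intervention
features on — each explained by its active rules ranked by absolute
impact (weight × fit).  The displayed impacts plus the intercept
reconstruct the raw prediction exactly; clipping to [0, 100] happens only
at render time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arm_table import ArmTable
from .featurization import BinarizerSpec, apply_binarizer, expand_literals
from .ontology import Literal, OntologyGraph, complete_hierarchy
from .rule_model import CrispRuleSet

__all__ = ["Scenario", "RuleImpact", "ScenarioPrediction", "predict_scenario"]

CONTROL_FEATURE = "control"


@dataclass
class Scenario:
    """A prediction scenario: population, intervention, methodology."""

    population: dict[str, float] = field(default_factory=dict)
    intervention: set[str] = field(default_factory=set)
    methodology: dict[str, object] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            population=dict(d.get("population", {})),
            intervention=set(d.get("intervention", []) or []),
            methodology=dict(d.get("methodology", {})),
        )


@dataclass
class RuleImpact:
    conjunction: list[str]
    weight: float
    fit: float

    @property
    def impact(self) -> float:
        return self.weight * self.fit

    def to_dict(self) -> dict:
        return {"conjunction": self.conjunction, "weight": self.weight,
                "fit": self.fit, "impact": self.impact}


@dataclass
class ScenarioPrediction:
    control_raw: float
    intervention_raw: float
    intercept: float
    control_rules: list[RuleImpact]
    intervention_rules: list[RuleImpact]

    @property
    def control(self) -> float:
        return float(np.clip(self.control_raw, 0.0, 100.0))

    @property
    def intervention(self) -> float:
        return float(np.clip(self.intervention_raw, 0.0, 100.0))

    def to_dict(self) -> dict:
        return {
            "control": {
                "value": self.control, "raw_value": self.control_raw,
                "rules": [r.to_dict() for r in self.control_rules],
            },
            "intervention": {
                "value": self.intervention, "raw_value": self.intervention_raw,
                "rules": [r.to_dict() for r in self.intervention_rules],
            },
            "intercept": self.intercept,
        }


def _scenario_memberships(
    asserted: dict[str, float],
    schema: list[str],
    column_kinds: dict[str, str],
    graph: OntologyGraph | None,
) -> dict[str, float]:
    """One arm's memberships over the full literal schema.

    Unmentioned presence features are treated as known-absent (their
    negated literal is on); asserted features are hierarchy-completed first
    so parents light up with their children.
    """
    base_cols = [c for c in schema if not c.startswith("not ")]
    row = {c: float(asserted.get(c, 0.0)) for c in base_cols}
    df = pd.DataFrame([{"study_id": "scenario", "arm_id": "a0",
                        "outcome": np.nan, **row}])
    kinds = {c: column_kinds.get(c, "presence") for c in base_cols}
    table = ArmTable(df, kinds)
    if graph is not None:
        table = complete_hierarchy(table, graph)
        keep = ["study_id", "arm_id", "outcome"] + base_cols
        table = ArmTable(table.df[keep], kinds)
    table = expand_literals(table)
    out = {}
    for c in schema:
        out[c] = float(table.df[c].iloc[0]) if c in table.df.columns else 0.0
    return out


def _evaluate(model: CrispRuleSet, memberships: dict[str, float]
              ) -> tuple[float, list[RuleImpact]]:
    active = []
    total = model.intercept
    for rule in model.rules:
        fit = rule.fit(memberships)
        total += rule.weight * fit
        if fit > 0:
            active.append(RuleImpact(sorted(rule.conjunction), rule.weight, fit))
    active.sort(key=lambda r: abs(r.impact), reverse=True)
    return float(total), active


def predict_scenario(
    model: CrispRuleSet,
    scenario: Scenario,
    schema: list[str],
    column_kinds: dict[str, str] | None = None,
    binarizers: dict[str, BinarizerSpec] | None = None,
    graph: OntologyGraph | None = None,
    control_feature: str = CONTROL_FEATURE,
) -> ScenarioPrediction:
    """Evaluate a scenario under a crisp (consensus) model.

    The scenario is binarized exactly as training data, hierarchy-completed,
    and evaluated twice: the control variant drops all intervention features
    and asserts the control outcome feature; the intervention variant keeps
    them and de-asserts control.  Unknown feature tokens are rejected with
    the list of valid tokens.
    """
    column_kinds = column_kinds or {}
    binarizers = binarizers or {}
    base_features = {c for c in schema if not c.startswith("not ")}

    asserted: dict[str, float] = {}
    for source, value in {**scenario.population, **scenario.methodology}.items():
        if source in binarizers:
            spec = binarizers[source]
            vals = apply_binarizer(float(value), spec)[0]
            for name, v in zip(spec.column_names(), np.atleast_1d(vals)):
                if name in base_features:
                    asserted[name] = float(v)
            rep = f"{source} (reported)"
            if rep in base_features:
                asserted[rep] = 1.0
        elif source in base_features:
            asserted[source] = float(bool(value)) if isinstance(value, bool) else float(value)
        else:
            raise ValueError(
                f"unknown scenario feature {source!r}; valid tokens: "
                f"{sorted(base_features | set(binarizers))}"
            )
    for tok in scenario.intervention:
        if tok not in base_features:
            raise ValueError(
                f"unknown intervention feature {tok!r}; valid tokens: "
                f"{sorted(base_features)}"
            )

    interv = dict(asserted)
    for tok in scenario.intervention:
        interv[tok] = 1.0
    if control_feature in base_features:
        interv[control_feature] = 0.0
    control = dict(asserted)
    if control_feature in base_features:
        control[control_feature] = 1.0

    m_ctl = _scenario_memberships(control, schema, column_kinds, graph)
    m_int = _scenario_memberships(interv, schema, column_kinds, graph)
    ctl_val, ctl_rules = _evaluate(model, m_ctl)
    int_val, int_rules = _evaluate(model, m_int)
    return ScenarioPrediction(
        control_raw=ctl_val, intervention_raw=int_val,
        intercept=model.intercept,
        control_rules=ctl_rules, intervention_rules=int_rules,
    )
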