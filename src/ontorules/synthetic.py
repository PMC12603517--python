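"""Synthetic arm tables with planted rule structure.

Every other module is testable against data whose generating process is
known exactly: a random feature hierarchy with disjoint siblings, per-arm
feature draws completed up the hierarchy, and outcomes produced by a small
set of planted crisp rules plus Gaussian noise (clipped to [0, 100], the
range of a percentage outcome).

The ``smoking-like`` preset mirrors the shape of the real training corpus:
roughly 400 studies with 1–4 arms each (~1000 arms), ~100 literal columns
after expansion, and outcome mass concentrated below 30%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .arm_table import ArmTable, META_COLUMNS
from .featurization import expand_literals
from .ontology import Feature, Literal, OntologyGraph, complete_hierarchy
from .rule_model import CrispRule

__all__ = [
    "PlantedModel",
    "generate_schema",
    "generate_table",
    "recovery_score",
    "smoking_like_model",
]


@dataclass
class PlantedModel:
    """The full generating process for one synthetic dataset."""

    ontology: OntologyGraph
    rules: list[CrispRule]
    prevalence: dict[str, float]
    intercept: float = 10.0
    noise_sd: float = 2.0
    n_studies: int = 100
    arms_per_study: tuple[int, int] = (1, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        for r in self.rules:
            lits = [Literal.parse(t) for t in r.conjunction]
            if self.ontology.contradicts(lits):
                raise ValueError(f"planted rule {sorted(r.conjunction)} is contradictory")
            simp = {l.token for l in self.ontology.simplify_conjunction(lits)}
            if simp != set(r.conjunction):
                raise ValueError(
                    f"planted rule {sorted(r.conjunction)} is not simplified "
                    f"(→ {sorted(simp)})"
                )


def generate_schema(
    n_features: int,
    n_parents: int,
    n_disjoint_pairs: int = 0,
    seed: int = 0,
) -> tuple[OntologyGraph, dict[str, float]]:
    """Random forest-shaped hierarchy plus sibling disjointness.

    ``n_parents`` features act as top-level parents; the remaining features
    are each attached to a random parent or left as roots.  Disjointness
    pairs are drawn among asserted sibling literals.  Prevalences are drawn
    per feature from U(0.15, 0.6) (parents inherit presence from children
    via completion on top of their own draw).
    """
    if n_parents >= n_features:
        raise ValueError("n_parents must be < n_features")
    rng = np.random.default_rng(seed)
    names = [f"f{i:02d}" for i in range(n_features)]
    parents = names[:n_parents]
    features = [Feature(id=p) for p in parents]
    children_of: dict[str, list[str]] = {p: [] for p in parents}
    attached: dict[str, str | None] = {}
    for name in names[n_parents:]:
        if n_parents and rng.random() < 0.7:
            p = parents[rng.integers(n_parents)]
            attached[name] = p
            children_of[p].append(name)
        else:
            attached[name] = None

    def n_sib_pairs() -> int:
        return sum(len(c) * (len(c) - 1) // 2 for c in children_of.values())

    # requested disjointness needs sibling pairs; attach loose features to the
    # fullest parent until enough exist (or none are left to attach)
    loose = [n for n, p in attached.items() if p is None]
    while n_parents and n_sib_pairs() < n_disjoint_pairs and loose:
        name = loose.pop()
        p = max(parents, key=lambda q: len(children_of[q]))
        attached[name] = p
        children_of[p].append(name)
    features += [Feature(id=n, parent_id=p) for n, p in attached.items()]

    sib_pairs = [
        (a, b)
        for p in parents
        for i, a in enumerate(children_of[p])
        for b in children_of[p][i + 1 :]
    ]
    rng.shuffle(sib_pairs)
    if n_disjoint_pairs > len(sib_pairs):
        raise ValueError(
            f"requested {n_disjoint_pairs} disjoint pairs but only "
            f"{len(sib_pairs)} sibling pairs exist"
        )
    disjoint = sib_pairs[:n_disjoint_pairs]

    graph = OntologyGraph(features, disjointness=disjoint)
    prevalence = {n: float(rng.uniform(0.15, 0.6)) for n in names}
    return graph, prevalence


def generate_table(model: PlantedModel) -> tuple[ArmTable, dict]:
    """Draw a table from the planted process, plus its truth record.

    Features are drawn independently by prevalence; for each declared
    disjoint pair with both sides on, one side is switched off at random;
    memberships are then completed up the hierarchy.  The outcome is

        intercept + Σ_rules w · [conjunction satisfied] + N(0, noise_sd),

    clipped to [0, 100].  The truth record stores the noiseless linear
    predictor and the clip events per arm.
    """
    rng = np.random.default_rng(model.seed)
    graph = model.ontology
    names = list(graph.features)
    rows = []
    study_sizes = rng.integers(model.arms_per_study[0],
                               model.arms_per_study[1] + 1,
                               size=model.n_studies)
    for s_idx, n_arms in enumerate(study_sizes):
        for a_idx in range(n_arms):
            draw = {n: float(rng.random() < model.prevalence[n]) for n in names}
            for pair in graph.disjointness:
                a, b = tuple(pair)
                if not a.negated and not b.negated:
                    if draw.get(a.feature_id, 0) > 0.5 and draw.get(b.feature_id, 0) > 0.5:
                        drop = a.feature_id if rng.random() < 0.5 else b.feature_id
                        draw[drop] = 0.0
            rows.append({"study_id": f"S{s_idx:04d}", "arm_id": f"a{a_idx}", **draw})

    df = pd.DataFrame(rows)
    df.insert(2, "outcome", np.nan)
    base = ArmTable(df, {n: "presence" for n in names})
    base = complete_hierarchy(base, graph)
    expanded = expand_literals(base)

    cols = {c: expanded.df[c].to_numpy(dtype=float) for c in expanded.feature_columns}
    n = expanded.n_arms
    linpred = np.full(n, model.intercept)
    for rule in model.rules:
        sat = np.ones(n)
        for tok in rule.conjunction:
            sat = sat * cols[tok]
        linpred = linpred + rule.weight * sat
    noise = rng.normal(0.0, model.noise_sd, size=n)
    raw = linpred + noise
    outcome = np.clip(raw, 0.0, 100.0)

    out_df = expanded.df.copy()
    out_df["outcome"] = outcome
    table = ArmTable(out_df, dict(expanded.column_kinds))
    truth = {
        "linpred": linpred.tolist(),
        "noise_sd": model.noise_sd,
        "clipped": (raw != outcome).tolist(),
        "rules": [{"conjunction": sorted(r.conjunction), "weight": r.weight}
                  for r in model.rules],
        "intercept": model.intercept,
        "seed": model.seed,
    }
    return table, truth


def recovery_score(
    learned: Sequence[CrispRule],
    planted: Sequence[CrispRule],
    graph: OntologyGraph | None = None,
) -> tuple[float, float]:
    """Exact-set precision/recall of learned vs planted conjunctions.

    Both sides are ontology-simplified first when a graph is given.  An
    empty learned set reports (0, 0) by convention.
    """

    def lhs(rules):
        out = set()
        for r in rules:
            lits = [Literal.parse(t) for t in r.conjunction]
            if graph is not None and all(l.feature_id in graph.features for l in lits):
                out.add(frozenset(l.token for l in graph.simplify_conjunction(lits)))
            else:
                out.add(frozenset(r.conjunction))
        return out

    got, want = lhs(learned), lhs(planted)
    if not got:
        return 0.0, 0.0
    hit = len(got & want)
    precision = hit / len(got)
    recall = hit / len(want) if want else 1.0
    return precision, recall


def smoking_like_model(seed: int = 0, n_studies: int = 400,
                       noise_sd: float = 6.0) -> PlantedModel:
    """The smoking-like preset: corpus-shaped synthetic data.

    ~400 studies of 1–4 arms (≈1000 arms), 50 presence features (≈100
    literals after expansion), a low intercept and mostly moderate rule
    weights so outcome mass concentrates below 30%, and a noise floor of
    6 percentage points standing in for trial sampling error.
    """
    graph, prevalence = generate_schema(
        n_features=50, n_parents=8, n_disjoint_pairs=5, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    names = list(graph.features)
    # sparser prevalences than the generic schema: most features are rare-ish
    prevalence = {n: float(rng.uniform(0.05, 0.45)) for n in names}

    rules: list[CrispRule] = []
    used: set[frozenset[str]] = set()
    # singleton effects on a handful of features
    singles = [str(f) for f in rng.choice(names, size=8, replace=False)]
    for f in singles:
        w = float(rng.normal(0.0, 4.0))
        rules.append(CrispRule(frozenset([f]), w))
        used.add(frozenset([f]))
    # a few pairwise interactions, ontology-consistent
    tries = 0
    while sum(len(r.conjunction) == 2 for r in rules) < 4 and tries < 200:
        tries += 1
        a, b = rng.choice(names, size=2, replace=False)
        conj = frozenset([str(a), str(b)])
        lits = [Literal.parse(t) for t in conj]
        if conj in used or graph.contradicts(lits):
            continue
        if {l.token for l in graph.simplify_conjunction(lits)} != set(conj):
            continue
        rules.append(CrispRule(conj, float(rng.normal(0.0, 6.0))))
        used.add(conj)

    return PlantedModel(
        ontology=graph,
        rules=rules,
        prevalence=prevalence,
        intercept=9.0,
        noise_sd=noise_sd,
        n_studies=n_studies,
        arms_per_study=(1, 4),
        seed=seed,
    )
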