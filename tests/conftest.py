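"""Shared fixtures: the toy ontology and small planted datasets."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ontorules.arm_table import ArmTable
from ontorules.ontology import OntologyGraph, load_ontology
from ontorules.rule_model import CrispRule
from ontorules.synthetic import PlantedModel, generate_schema, generate_table

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_graph() -> OntologyGraph:
    """Smoking-flavoured toy ontology: drugs, delivery modes, sources."""
    return load_ontology(DATA_DIR / "toy_ontology.tsv")


@pytest.fixture(scope="session")
def planted_problem():
    """A small planted-rule dataset shared by training/consensus tests.

    20 features (flat-ish hierarchy, 2 disjoint sibling pairs), three
    planted rules including a pairwise interaction and a negated literal,
    noise sd 2.
    """
    graph, prev = generate_schema(20, 4, 2, seed=7)
    rules = [
        CrispRule(frozenset(["f10"]), 8.0),
        CrispRule(frozenset(["f12", "f15"]), 10.0),
        CrispRule(frozenset(["f08", "not f18"]), -6.0),
    ]
    model = PlantedModel(graph, rules, prev, intercept=12.0, noise_sd=2.0,
                         n_studies=160, arms_per_study=(2, 4), seed=3)
    table, truth = generate_table(model)
    return {"graph": graph, "rules": rules, "model": model,
            "table": table, "truth": truth}


@pytest.fixture()
def tiny_table() -> ArmTable:
    """A handmade six-arm table over three presence features."""
    df = pd.DataFrame({
        "study_id": ["s1", "s1", "s2", "s2", "s3", "s3"],
        "arm_id": ["a", "b", "a", "b", "a", "b"],
        "outcome": [10.0, 20.0, 12.0, 22.0, 8.0, 18.0],
        "nurse": [1.0, 0.0, 1.0, 0.0, 0.0, 1.0],
        "patch": [0.0, 1.0, 1.0, 0.0, 1.0, 0.0],
        "control": [0.0, 0.0, 0.0, 1.0, 0.0, 1.0],
    })
    return ArmTable(df, {c: "presence" for c in ["nurse", "patch", "control"]})
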