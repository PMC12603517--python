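"""Feature ontology: subsumption hierarchy, disjointness axioms, and the
semantic operations built on them.

The ontology plays three roles in the prediction system:

* **Data completion** — if a child feature (e.g. ``NRT``) is on in an arm,
  the subsuming parent (``pharmacological support``) must be on too.
* **Rule simplification** — a conjunction containing both a feature and an
  ancestor it implies can drop the ancestor without changing its meaning.
* **Contradiction detection** — disjointness axioms (``bupropion`` vs
  ``not pill``) mark conjunctions that can never be satisfied.

Only subsumption closure and pairwise disjointness are supported; this is
deliberately far short of a description-logic reasoner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "Feature",
    "Literal",
    "OntologyGraph",
    "OntologyError",
    "load_ontology",
    "save_ontology",
    "complete_hierarchy",
]

VALUE_KINDS = ("presence", "numeric", "categorical", "percentage")


class OntologyError(ValueError):
    """Raised for invalid ontologies or references to unknown features."""


@dataclass(frozen=True)
class Feature:
    """A named feature (ontology class) usable in rules.

    ``value_kind`` distinguishes presence/absence features (which admit
    negated literals) from numeric, categorical and percentage features
    (which are binarized into range literals instead).
    """

    id: str
    label: str = ""
    value_kind: str = "presence"
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise OntologyError(
                f"feature {self.id!r}: unknown value_kind {self.value_kind!r}"
            )


@dataclass(frozen=True, order=True)
class Literal:
    """An atomic rule condition: a feature asserted or negated.

    The textual token of a negated literal is ``"not <feature>"``.
    """

    feature_id: str
    negated: bool = False

    @property
    def token(self) -> str:
        return f"not {self.feature_id}" if self.negated else self.feature_id

    @property
    def polarity(self) -> str:
        return "negated" if self.negated else "asserted"

    def complement(self) -> "Literal":
        return Literal(self.feature_id, not self.negated)

    @classmethod
    def parse(cls, token: str) -> "Literal":
        token = token.strip()
        if token.startswith("not "):
            return cls(token[4:].strip(), True)
        if token.startswith("!"):
            return cls(token[1:].strip(), True)
        return cls(token, False)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


def _as_literal(x: "Literal | str") -> Literal:
    return x if isinstance(x, Literal) else Literal.parse(x)


class OntologyGraph:
    """Features plus subsumption edges and disjointness axioms.

    Subsumption edges run child → parent and must be acyclic.  Disjointness
    is a symmetric relation between *literals*, so both sibling-class
    conflicts (``bupropion`` vs ``varenicline``) and presence/absence
    conflicts (``bupropion`` vs ``not pill``) are expressible.
    """

    def __init__(
        self,
        features: Iterable[Feature],
        subsumption: Iterable[tuple[str, str]] = (),
        disjointness: Iterable[tuple[Literal | str, Literal | str]] = (),
    ) -> None:
        self.features: dict[str, Feature] = {}
        for f in features:
            if f.id in self.features:
                raise OntologyError(f"duplicate feature id {f.id!r}")
            self.features[f.id] = f

        self._dag = nx.DiGraph()
        self._dag.add_nodes_from(self.features)
        edges = set(subsumption)
        for f in self.features.values():
            if f.parent_id is not None:
                edges.add((f.id, f.parent_id))
        for child, parent in edges:
            for node in (child, parent):
                if node not in self.features:
                    raise OntologyError(
                        f"subsumption edge ({child!r}, {parent!r}) references "
                        f"unknown feature {node!r}"
                    )
            self._dag.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self._dag):
            cycle = nx.find_cycle(self._dag)
            raise OntologyError(f"cycle in subsumption: {cycle}")

        self.disjointness: set[frozenset[Literal]] = set()
        for a, b in disjointness:
            la, lb = _as_literal(a), _as_literal(b)
            for lit in (la, lb):
                self._check_feature(lit.feature_id)
                if lit.negated and self.features[lit.feature_id].value_kind != "presence":
                    raise OntologyError(
                        f"negated literal {lit.token!r} on non-presence feature"
                    )
            if la == lb:
                raise OntologyError(f"literal {la.token!r} declared disjoint with itself")
            self.disjointness.add(frozenset((la, lb)))

        self._implied_cache: dict[Literal, frozenset[Literal]] = {}

    # ------------------------------------------------------------------
    def _check_feature(self, feature_id: str) -> None:
        if feature_id not in self.features:
            raise OntologyError(f"unknown feature {feature_id!r}")

    @property
    def subsumption(self) -> set[tuple[str, str]]:
        """Direct (child, parent) pairs."""
        return set(self._dag.edges())

    def parent(self, feature_id: str) -> str | None:
        """The direct parent, or None (first parent if several)."""
        self._check_feature(feature_id)
        succ = list(self._dag.successors(feature_id))
        return succ[0] if succ else None

    def ancestors(self, feature_id: str) -> set[str]:
        """All features reachable via subsumption, excluding the feature."""
        self._check_feature(feature_id)
        return nx.descendants(self._dag, feature_id)

    def descendants(self, feature_id: str) -> set[str]:
        """All features subsumed by ``feature_id``, excluding itself."""
        self._check_feature(feature_id)
        return nx.ancestors(self._dag, feature_id)

    def subsumption_closure(self) -> set[tuple[str, str]]:
        """All (descendant, ancestor) pairs in the transitive closure."""
        return {
            (f, a) for f in self.features for a in self.ancestors(f)
        }

    # ------------------------------------------------------------------
    def implied(self, literal: Literal | str) -> frozenset[Literal]:
        """Literals entailed by ``literal``, including itself.

        An asserted feature implies all its ancestors asserted; a negated
        feature implies all its descendants negated (contrapositive of
        child-implies-parent).
        """
        lit = _as_literal(literal)
        if lit in self._implied_cache:
            return self._implied_cache[lit]
        self._check_feature(lit.feature_id)
        if lit.negated:
            out = frozenset(
                Literal(f, True) for f in self.descendants(lit.feature_id) | {lit.feature_id}
            )
        else:
            out = frozenset(
                Literal(f, False) for f in self.ancestors(lit.feature_id) | {lit.feature_id}
            )
        self._implied_cache[lit] = out
        return out

    def implies(self, a: Literal | str, b: Literal | str) -> bool:
        """True iff literal ``a`` entails literal ``b`` under subsumption."""
        return _as_literal(b) in self.implied(a)

    def entails(self, a: Literal | str, b: Literal | str) -> bool:
        """Full literal entailment: subsumption plus disjointness-derived.

        ``a`` entails ``b`` when ``b`` is in a's subsumption-implied set, or
        when ``a`` contradicts the complement of ``b`` (e.g. a feature
        disjoint with ``pill``'s absence entails ``pill``; a feature
        disjoint with ``f`` entails ``not f``).
        """
        la, lb = _as_literal(a), _as_literal(b)
        if lb in self.implied(la):
            return True
        if not lb.negated and self.features[lb.feature_id].value_kind != "presence":
            return False  # complement undefined for non-presence assertions
        return self.pair_contradicts(la, lb.complement())

    def pair_contradicts(self, a: Literal | str, b: Literal | str) -> bool:
        """True iff literals ``a`` and ``b`` cannot jointly hold.

        Checks declared disjointness over the implied sets of both literals
        (so a literal disjoint with a parent is disjoint with each child),
        plus the built-in complement conflict (f vs not-f).
        """
        ia, ib = self.implied(a), self.implied(b)
        for x in ia:
            for y in ib:
                if x == y.complement():
                    return True
                if frozenset((x, y)) in self.disjointness:
                    return True
        return False

    def contradicts(self, conjunction: Iterable[Literal | str]) -> bool:
        """True iff some pair in the conjunction is disjoint under closure."""
        lits = [_as_literal(l) for l in conjunction]
        for i, a in enumerate(lits):
            for b in lits[i + 1 :]:
                if self.pair_contradicts(a, b):
                    return True
        return False

    def simplify_conjunction(
        self, conjunction: Iterable[Literal | str]
    ) -> frozenset[Literal]:
        """Drop every literal entailed by another literal of the conjunction.

        The result is logically equivalent under the ontology: an asserted
        ancestor of an asserted feature is redundant, as is a negated
        descendant of a negated feature, as is a literal forced by a
        disjointness axiom (``bupropion`` makes ``pill`` redundant).  With
        mutually entailing literals the lexicographically smaller token is
        kept.  Contradictory input is rejected.
        """
        lits = {_as_literal(l) for l in conjunction}
        if self.contradicts(lits):
            raise OntologyError("cannot simplify a contradictory conjunction")
        return frozenset(
            l for l in lits
            if not any(
                o != l and self.entails(o, l)
                and (not self.entails(l, o) or o.token < l.token)
                for o in lits
            )
        )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "features": [
                {
                    "id": f.id,
                    "label": f.label,
                    "value_kind": f.value_kind,
                    "parent": f.parent_id,
                }
                for f in self.features.values()
            ],
            "subsumption": sorted(self._dag.edges()),
            "disjointness": sorted(
                sorted(l.token for l in pair) for pair in self.disjointness
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OntologyGraph":
        features = [
            Feature(
                id=f["id"],
                label=f.get("label", ""),
                value_kind=f.get("value_kind", "presence"),
                parent_id=f.get("parent"),
            )
            for f in d.get("features", [])
        ]
        known = {f.id for f in features}
        extra: list[str] = []
        for c, p in d.get("subsumption", []):
            extra += [x for x in (c, p) if x not in known]
        for f in sorted(set(extra)):
            features.append(Feature(id=f))
        return cls(
            features,
            subsumption=[tuple(e) for e in d.get("subsumption", [])],
            disjointness=[tuple(pair) for pair in d.get("disjointness", [])],
        )


# ----------------------------------------------------------------------
# File formats: TSV edge list and JSON.


def load_ontology(path: str | Path) -> OntologyGraph:
    """Load an ontology from a TSV edge list or a JSON file.

    The TSV dialect has three columns ``child<TAB>relation<TAB>parent`` with
    relation ``subClassOf`` or ``disjointWith``; a ``!`` prefix marks a
    negated literal in disjointWith rows.  The JSON dialect is the
    dictionary produced by :meth:`OntologyGraph.to_dict`.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        return OntologyGraph.from_dict(json.loads(text))

    feature_ids: list[str] = []
    seen: set[str] = set()
    subsumption: list[tuple[str, str]] = []
    disjointness: list[tuple[str, str]] = []

    def note(token: str) -> None:
        fid = Literal.parse(token).feature_id
        if fid not in seen:
            seen.add(fid)
            feature_ids.append(fid)

    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:  # bare feature declaration
            note(parts[0])
            continue
        if len(parts) != 3:
            raise OntologyError(f"{path}:{lineno}: expected 3 tab-separated fields")
        child, relation, parent = (p.strip() for p in parts)
        note(child)
        note(parent)
        if relation == "subClassOf":
            if child.startswith("!") or parent.startswith("!"):
                raise OntologyError(
                    f"{path}:{lineno}: negation not allowed in subClassOf"
                )
            subsumption.append((child, parent))
        elif relation == "disjointWith":
            disjointness.append((child, parent))
        else:
            raise OntologyError(f"{path}:{lineno}: unknown relation {relation!r}")

    return OntologyGraph(
        [Feature(id=f) for f in feature_ids],
        subsumption=subsumption,
        disjointness=disjointness,
    )


def save_ontology(graph: OntologyGraph, path: str | Path) -> None:
    """Write an ontology back out (JSON for .json paths, else TSV)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(graph.to_dict(), indent=2) + "\n")
        return
    lines = []
    in_axiom = set()
    for c, p in sorted(graph.subsumption):
        lines.append(f"{c}\tsubClassOf\t{p}")
        in_axiom |= {c, p}
    for pair in sorted(graph.disjointness, key=lambda q: sorted(l.token for l in q)):
        a, b = sorted(pair, key=lambda l: l.token)
        atok = ("!" + a.feature_id) if a.negated else a.feature_id
        btok = ("!" + b.feature_id) if b.negated else b.feature_id
        lines.append(f"{atok}\tdisjointWith\t{btok}")
        in_axiom |= {a.feature_id, b.feature_id}
    for f in graph.features:
        if f not in in_axiom:
            lines.append(f)
    path.write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------


def complete_hierarchy(table, graph: OntologyGraph):
    """Propagate memberships up the hierarchy: parent ≥ each child.

    For every subsumption pair the parent's membership becomes
    ``max(own, children...)``, applied to fixpoint (children are processed
    before parents).  Missing parent columns are added.  Fuzzy (graded)
    memberships propagate by max, so [0,1] values stay valid.  Returns a
    new table; the input is not modified.
    """
    from .arm_table import ArmTable  # local import avoids a cycle

    if not isinstance(table, ArmTable):
        raise TypeError("complete_hierarchy expects an ArmTable")
    df = table.df.copy()
    kinds = dict(table.column_kinds)
    for feat in nx.topological_sort(graph._dag):
        # children come before parents (edges run child→parent)
        if feat not in df.columns:
            continue
        for parent in graph._dag.successors(feat):
            if parent not in df.columns:
                df[parent] = 0.0
                kinds[parent] = kinds.get(feat, "presence")
            df[parent] = df[parent].astype(float).combine(
                df[feat].astype(float), max
            )
    return ArmTable(df, column_kinds=kinds)
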