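"""Mechanism-based synergy detection on a curated pathway model.

Two ingredients are called synergistic when their target sets jointly
engage a directed, pathway-labelled signalling model through one of four
topological patterns:

``same_pathway``
    Distinct targets on one labelled cascade, one upstream of the other,
    with the cascade continuing past the downstream target — the pair
    throttles a single route at two points.
``crosstalk_convergence``
    Distinct targets on differently-labelled pathways whose directed
    routes converge on a common downstream node.
``feedback_loop``
    The pair engages a declared feedback complex at two distinct
    subunits, corroborated by direct drive into the complex from a
    non-complex target of either partner.
``compensation``
    Distinct targets on differently-labelled, non-convergent pathways
    whose direct downstream effectors are distinct but functionally
    related (same complex, or shared pathway membership) — blocking one
    route alone would be compensated by the other.

Reachability is along simple directed paths *within one pathway label*;
crossing labels is what distinguishes cross-talk. Edge weight in the
synergy network is the number of distinct mechanism kinds (max 4), per
the convention that line width tracks the number of mechanisms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayModel",
    "MechanismRecord",
    "SynergyNetwork",
    "load_pathway_model",
    "pathway_model_from_edges",
    "detect_mechanisms",
    "build_synergy_network",
]

MECHANISM_KINDS = (
    "same_pathway",
    "crosstalk_convergence",
    "feedback_loop",
    "compensation",
)


@dataclass(frozen=True)
class PathwayModel:
    """Directed, pathway-labelled signalling graph with declared loops."""

    graph: nx.DiGraph  # edge attr "labels": frozenset of pathway names
    feedback_loops: tuple[frozenset[str], ...] = ()
    sinks: frozenset[str] = frozenset()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def labels(self) -> set[str]:
        out: set[str] = set()
        for _, _, data in self.graph.edges(data=True):
            out |= data["labels"]
        return out

    def edges_on(self, label: str) -> list[tuple[str, str]]:
        return [
            (u, v)
            for u, v, data in self.graph.edges(data=True)
            if label in data["labels"]
        ]

    def nodes_on(self, label: str) -> set[str]:
        out: set[str] = set()
        for u, v in self.edges_on(label):
            out.add(u)
            out.add(v)
        return out

    def node_labels(self, node: str) -> set[str]:
        out: set[str] = set()
        for u, v, data in self.graph.edges(data=True):
            if node in (u, v):
                out |= data["labels"]
        return out

    def downstream(self, node: str, label: str) -> set[str]:
        """Strict descendants of ``node`` along edges carrying ``label``."""
        sub = nx.DiGraph(self.edges_on(label))
        if node not in sub:
            return set()
        return set(nx.descendants(sub, node))

    def direct_successors(self, node: str, label: str | None = None) -> set[str]:
        out = set()
        for _, v, data in self.graph.out_edges(node, data=True):
            if label is None or label in data["labels"]:
                out.add(v)
        return out


def pathway_model_from_edges(
    edges: Iterable[tuple[str, str, str]],
    feedback_loops: Iterable[Iterable[str]] = (),
    sinks: Iterable[str] = (),
) -> PathwayModel:
    """Validate and build a model from (source, target, label) triples."""
    graph = nx.DiGraph()
    for src, tgt, label in edges:
        src, tgt, label = src.upper(), tgt.upper(), label.strip()
        if not label:
            raise ValueError(f"unlabeled pathway edge: {src}->{tgt}")
        if graph.has_edge(src, tgt):
            graph[src][tgt]["labels"] = graph[src][tgt]["labels"] | {label}
        else:
            graph.add_edge(src, tgt, labels=frozenset({label}))
    loops = []
    for loop in feedback_loops:
        members = frozenset(m.upper() for m in loop)
        if len(members) < 2:
            raise ValueError("feedback loop needs at least 2 members")
        dangling = members - set(graph.nodes)
        if dangling:
            raise ValueError(
                f"feedback loop member(s) absent from model: {sorted(dangling)}"
            )
        loops.append(members)
    sink_set = frozenset(s.upper() for s in sinks)
    dangling = sink_set - set(graph.nodes)
    if dangling:
        raise ValueError(f"sink node(s) absent from model: {sorted(dangling)}")
    return PathwayModel(
        graph=graph, feedback_loops=tuple(loops), sinks=sink_set
    )


def load_pathway_model(path: str | Path) -> PathwayModel:
    """Read a pathway TSV: edge lines ``source target label``.

    Directive lines declare complexes and effectors:
    ``!loop A B C D`` and ``!sink X Y``.
    """
    edges: list[tuple[str, str, str]] = []
    loops: list[list[str]] = []
    sinks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "!loop":
                loops.append(parts[1:])
            elif parts[0] == "!sink":
                sinks.extend(parts[1:])
            elif len(parts) >= 3:
                edges.append((parts[0], parts[1], parts[2]))
            else:
                raise ValueError(f"unlabeled pathway edge line: {line!r}")
    return pathway_model_from_edges(edges, loops, sinks)


@dataclass(frozen=True)
class MechanismRecord:
    """One detected synergy mechanism for an ingredient pair."""

    pair: tuple[str, str]
    kind: str
    evidence: tuple[tuple[str, str], ...]  # sorted (key, value) pairs

    @property
    def evidence_dict(self) -> dict[str, str]:
        return dict(self.evidence)


def _record(pair, kind, **evidence) -> MechanismRecord:
    items = tuple(sorted((k, str(v)) for k, v in evidence.items()))
    return MechanismRecord(pair=pair, kind=kind, evidence=items)


def detect_mechanisms(
    a_targets: Iterable[str],
    b_targets: Iterable[str],
    model: PathwayModel,
    pair: tuple[str, str] = ("a", "b"),
) -> list[MechanismRecord]:
    """Enumerate synergy mechanisms for one ingredient pair.

    Records are deduplicated by (kind, evidence). If neither target set
    intersects the model an empty list is returned with a warning.
    """
    ta = {t.upper() for t in a_targets} & model.nodes
    tb = {t.upper() for t in b_targets} & model.nodes
    if not ta and not tb:
        warnings.warn(f"neither ingredient of pair {pair} hits the pathway model")
        return []
    records: set[MechanismRecord] = set()
    labels = sorted(model.labels)
    down = {
        (n, p): model.downstream(n, p)
        for n in ta | tb
        for p in labels
    }
    on = {p: model.nodes_on(p) for p in labels}

    # same_pathway: distinct targets on one cascade that continues past them
    for p in labels:
        for u in sorted(ta & on[p]):
            for v in sorted(tb & on[p]):
                if u == v:
                    continue
                for up, dn in ((u, v), (v, u)):
                    if dn in down[(up, p)] and down[(dn, p)]:
                        records.add(
                            _record(
                                pair,
                                "same_pathway",
                                pathway=p,
                                upstream=up,
                                downstream=dn,
                                regulates=",".join(sorted(down[(dn, p)])),
                            )
                        )

    # crosstalk_convergence: differently-labelled routes meeting downstream
    for p in labels:
        for q in labels:
            if p == q:
                continue
            for u in sorted(ta & on[p]):
                for v in sorted(tb & on[q]):
                    if u == v:
                        continue
                    conv = down[(u, p)] & down[(v, q)]
                    for node in sorted(conv):
                        records.add(
                            _record(
                                pair,
                                "crosstalk_convergence",
                                pathways=",".join(sorted((p, q))),
                                targets=",".join(sorted((u, v))),
                                convergence=node,
                            )
                        )

    # feedback_loop: distinct complex subunits + direct drive into the complex
    for loop in model.feedback_loops:
        drivers = sorted(
            w
            for w in (ta | tb) - loop
            if model.direct_successors(w) & loop
        )
        if not drivers:
            continue
        for x in sorted(ta & loop):
            for y in sorted(tb & loop):
                if x == y:
                    continue
                records.add(
                    _record(
                        pair,
                        "feedback_loop",
                        loop=",".join(sorted(loop)),
                        members=",".join(sorted((x, y))),
                        driver=drivers[0],
                    )
                )

    # compensation: non-convergent related pathways, distinct direct effectors
    loops_by_node: dict[str, frozenset[str]] = {}
    for loop in model.feedback_loops:
        for m in loop:
            loops_by_node[m] = loop

    def related(x: str, y: str) -> bool:
        if loops_by_node.get(x) is not None and loops_by_node.get(x) == loops_by_node.get(y):
            return True
        return bool(model.node_labels(x) & model.node_labels(y))

    for p in labels:
        for q in labels:
            if p == q:
                continue
            for u in sorted(ta & on[p]):
                for v in sorted(tb & on[q]):
                    if u == v or (down[(u, p)] & down[(v, q)]):
                        continue
                    for x in sorted(model.direct_successors(u, p)):
                        for y in sorted(model.direct_successors(v, q)):
                            if (
                                x != y
                                and x not in ta | tb
                                and y not in ta | tb
                                and x not in down[(v, q)] | {v}
                                and y not in down[(u, p)] | {u}
                                and related(x, y)
                            ):
                                records.add(
                                    _record(
                                        pair,
                                        "compensation",
                                        pathways=",".join(sorted((p, q))),
                                        targets=",".join(sorted((u, v))),
                                        regulated=",".join(sorted((x, y))),
                                    )
                                )
    return sorted(records, key=lambda r: (r.kind, r.evidence))


@dataclass(frozen=True)
class SynergyNetwork:
    """Ingredient pairs with mechanism-kind weights."""

    graph: nx.Graph  # edge attrs: weight, kinds, records
    records: tuple[MechanismRecord, ...] = field(default=())

    @property
    def pairs(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def weight(self, a: str, b: str) -> int:
        return self.graph[a][b]["weight"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b))
            rows.append(
                {
                    "ingredient_a": a,
                    "ingredient_b": b,
                    "weight": data["weight"],
                    "mechanisms": ",".join(data["kinds"]),
                }
            )
        return pd.DataFrame(
            rows, columns=["ingredient_a", "ingredient_b", "weight", "mechanisms"]
        ).sort_values(["ingredient_a", "ingredient_b"]).reset_index(drop=True)


def build_synergy_network(
    ingredient_targets: Mapping[str, Iterable[str]], model: PathwayModel
) -> SynergyNetwork:
    """All-pairs mechanism detection over a set of ingredients."""
    ids = sorted(ingredient_targets)
    if len(ids) < 2:
        raise ValueError("at least 2 ingredients are required")
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    all_records: list[MechanismRecord] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                recs = detect_mechanisms(
                    ingredient_targets[a], ingredient_targets[b], model, pair=(a, b)
                )
            if recs:
                kinds = tuple(sorted({r.kind for r in recs}))
                graph.add_edge(a, b, weight=len(kinds), kinds=kinds, records=recs)
                all_records.extend(recs)
    return SynergyNetwork(graph=graph, records=tuple(all_records))
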