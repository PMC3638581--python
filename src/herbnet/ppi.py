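"""Protein-interaction "target space": network loading and closeness.

The closeness of a candidate gene to a reference drug's target set is a
Gaussian kernel of unweighted shortest-path distance summed over the
drug's targets, Φ(g, T) = Σ_{t∈T} exp(−d(g,t)²). Unreachable pairs (and
genes absent from the network) contribute 0 — disconnection is "no
evidence". An exponential kernel exp(−d) is available as an alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "ClosenessVector",
    "load_network",
    "network_from_edges",
    "closeness",
    "closeness_vector",
    "closeness_matrix",
]

_KERNELS = {
    "gaussian": lambda d: math.exp(-(d * d)),
    "exponential": lambda d: math.exp(-d),
}


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected, unweighted gene/protein interaction graph.

    Node symbols are uppercase; no self-loops or duplicate edges. The
    graph is kept whole (no largest-component restriction) so isolated
    seeds survive into downstream reports.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


def network_from_edges(pairs: Iterable[tuple[str, str]]) -> InteractionNetwork:
    """Build a cleaned network from symbol pairs.

    Symbols are uppercased; self-loops and duplicate edges are dropped
    with logged counts. Fewer than 2 surviving nodes is a hard error.
    """
    graph = nx.Graph()
    n_self, n_dup = 0, 0
    for a, b in pairs:
        a, b = a.strip().upper(), b.strip().upper()
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)
    if n_self or n_dup:
        logger.info("dropped %d self-loop(s), %d duplicate edge(s)", n_self, n_dup)
    if graph.number_of_nodes() < 2:
        raise ValueError("interaction network has fewer than 2 nodes after cleaning")
    logger.info(
        "network: %d nodes, %d edges",
        graph.number_of_nodes(),
        graph.number_of_edges(),
    )
    return InteractionNetwork(graph=graph)


def load_network(path: str | Path) -> InteractionNetwork:
    """Read a SIF ("A pp B") or 2-column TSV edge list."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) >= 3:  # SIF: source relation target [targets...]
                for tgt in parts[2:]:
                    pairs.append((parts[0], tgt))
            elif len(parts) == 2:
                pairs.append((parts[0], parts[1]))
            else:  # single token: SIF isolated-node line is ignored
                pairs.append((parts[0], parts[0]))
    return network_from_edges(pairs)


@dataclass(frozen=True)
class ClosenessVector:
    """Closeness of one gene to each reference drug's target set."""

    gene: str
    reference_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if len(values) != len(self.reference_ids):
            raise ValueError("values and reference_ids differ in length")
        object.__setattr__(self, "values", values)


def closeness(
    gene: str,
    target_set: Iterable[str],
    network: InteractionNetwork,
    kernel: str = "gaussian",
) -> float:
    """Φ(gene, targets) = Σ_t k(d(gene, t)); unreachable terms contribute 0."""
    targets = {t.upper() for t in target_set}
    if not targets:
        raise ValueError("empty target set")
    kern = _KERNELS[kernel]
    gene = gene.upper()
    if gene not in network:
        return 0.0
    dists = nx.single_source_shortest_path_length(network.graph, gene)
    return float(sum(kern(dists[t]) for t in targets if t in dists))


def closeness_vector(
    gene: str,
    reference_targets: Mapping[str, Iterable[str]],
    network: InteractionNetwork,
    kernel: str = "gaussian",
) -> ClosenessVector:
    """One closeness value per reference drug, in mapping order."""
    for drug, targets in reference_targets.items():
        if not set(targets):
            raise ValueError(f"reference drug {drug!r} has an empty target set")
    values = np.array(
        [closeness(gene, t, network, kernel) for t in reference_targets.values()]
    )
    return ClosenessVector(
        gene=gene.upper(),
        reference_ids=tuple(reference_targets),
        values=values,
    )


def closeness_matrix(
    genes: Sequence[str],
    reference_targets: Mapping[str, Iterable[str]],
    network: InteractionNetwork,
    kernel: str = "gaussian",
) -> pd.DataFrame:
    """Gene × reference closeness matrix (vectorized BFS via scipy).

    Distances are computed once per distinct target node with unweighted
    Dijkstra on the sparse adjacency matrix, then kernel-summed per drug.
    """
    for drug, targets in reference_targets.items():
        if not set(targets):
            raise ValueError(f"reference drug {drug!r} has an empty target set")
    genes = [g.upper() for g in genes]
    node_list = list(network.graph.nodes)
    node_index = {n: i for i, n in enumerate(node_list)}

    all_targets = sorted(
        {t.upper() for ts in reference_targets.values() for t in ts}
    )
    present = [t for t in all_targets if t in node_index]
    if present:
        adj = nx.to_scipy_sparse_array(network.graph, nodelist=node_list, format="csr")
        dmat = shortest_path(
            adj, method="D", unweighted=True,
            indices=[node_index[t] for t in present],
        )
        kern = _KERNELS[kernel]
        with np.errstate(over="ignore"):
            if kernel == "gaussian":
                kmat = np.where(np.isinf(dmat), 0.0, np.exp(-np.square(dmat)))
            else:
                kmat = np.where(np.isinf(dmat), 0.0, np.exp(-dmat))
    target_row = {t: i for i, t in enumerate(present)}

    out = np.zeros((len(genes), len(reference_targets)))
    gene_cols = np.array([node_index.get(g, -1) for g in genes])
    inside = gene_cols >= 0
    for j, targets in enumerate(reference_targets.values()):
        rows = [target_row[t.upper()] for t in targets if t.upper() in target_row]
        if not rows:
            continue
        col_sums = kmat[rows][:, gene_cols[inside]].sum(axis=0)
        out[inside, j] = col_sums
    return pd.DataFrame(out, index=genes, columns=list(reference_targets))
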