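"""Disease-specific network construction and herb target mapping.

Five-step network-target analysis: (1) compile seed genes from three
provenance classes (known disease genes, predicted disease genes,
targets of approved drugs for the disease); (2) expand seeds by their
first interaction partners into the disease-specific network; (3) map
each herb's predicted profile genes into that network; (4) hand the herb
networks to functional enrichment; (5) interpret the combination,
including off-target (adverse-effect) genes and the herbs that
counter-act them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .cipher import TargetProfile
from .ppi import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSet",
    "DiseaseNetwork",
    "HerbTargetNetwork",
    "assemble_seeds",
    "read_seed_list",
    "expand_to_disease_network",
    "map_herb_targets",
    "flag_off_targets",
    "write_network_sif",
]

PROVENANCE_LABELS = ("known", "predicted", "drug_target")


@dataclass(frozen=True)
class SeedSet:
    """Seed genes with multi-label provenance."""

    genes: dict[str, frozenset[str]]  # symbol -> labels

    def __len__(self) -> int:
        return len(self.genes)

    def symbols(self) -> set[str]:
        return set(self.genes)


@dataclass(frozen=True)
class DiseaseNetwork:
    """Seeds plus one-hop expansion with induced edges.

    ``expansion_layer`` is 0 for seeds and 1 for fished neighbours; seeds
    absent from the parent network are retained as isolated layer-0
    nodes so their provenance stays visible in reports.
    """

    network: InteractionNetwork
    seed_flags: dict[str, frozenset[str]]
    expansion_layer: dict[str, int]

    @property
    def nodes(self) -> set[str]:
        return set(self.expansion_layer)


@dataclass(frozen=True)
class HerbTargetNetwork:
    """A herb's profile genes mapped into the disease network."""

    herb: str
    network: InteractionNetwork | None
    mapped_targets: frozenset[str]
    contributors: dict[str, frozenset[str]]  # gene -> contributing ingredients
    off_target_flags: frozenset[str] = frozenset()
    counter_acting_herbs: dict[str, frozenset[str]] = field(default_factory=dict)


def read_seed_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def assemble_seeds(
    known: Iterable[str] = (),
    predicted: Iterable[str] = (),
    drug_targets: Iterable[str] = (),
) -> SeedSet:
    """Union of the three provenance lists; duplicates merge labels."""
    genes: dict[str, set[str]] = {}
    for label, symbols in zip(PROVENANCE_LABELS, (known, predicted, drug_targets)):
        for s in symbols:
            genes.setdefault(s.strip().upper(), set()).add(label)
    if not genes:
        raise ValueError("all seed lists are empty")
    return SeedSet(genes={g: frozenset(ls) for g, ls in genes.items()})


def expand_to_disease_network(
    seeds: SeedSet, ppi: InteractionNetwork, depth: int = 1
) -> DiseaseNetwork:
    """Seeds plus their ``depth``-hop interaction partners, induced edges.

    Default depth is a single fishing step. Seeds missing from the PPI
    are kept as isolated nodes (logged).
    """
    seed_symbols = seeds.symbols()
    absent = seed_symbols - ppi.nodes
    if absent:
        logger.warning(
            "%d seed(s) absent from the interaction network: %s",
            len(absent), sorted(absent)[:5],
        )
    frontier = seed_symbols & ppi.nodes
    layer = {g: 0 for g in seed_symbols}
    for d in range(1, depth + 1):
        neighbours = {
            n for g in frontier for n in ppi.graph.neighbors(g)
        } - set(layer)
        for n in neighbours:
            layer[n] = d
        frontier = neighbours
    sub = nx.Graph(ppi.graph.subgraph(set(layer) & ppi.nodes).copy())
    sub.add_nodes_from(absent)  # isolated seeds survive
    return DiseaseNetwork(
        network=InteractionNetwork(graph=sub),
        seed_flags=dict(seeds.genes),
        expansion_layer=layer,
    )


def map_herb_targets(
    herb: str,
    herb_profiles: Mapping[str, TargetProfile],
    disease_net: DiseaseNetwork,
    bridge: bool = False,
) -> HerbTargetNetwork:
    """Intersect a herb's profile genes with the disease network.

    The herb network is the induced subgraph on the mapped targets; with
    ``bridge=True`` one-hop connector genes of the disease network are
    added as well (the mapped set itself is unchanged).
    """
    profile_genes: dict[str, set[str]] = {}
    for iid, profile in herb_profiles.items():
        for g in profile.genes:
            profile_genes.setdefault(g, set()).add(iid)
    mapped = set(profile_genes) & disease_net.nodes
    if not mapped:
        logger.warning("herb %r: no profile gene maps into the disease network", herb)
        return HerbTargetNetwork(
            herb=herb, network=None, mapped_targets=frozenset(), contributors={}
        )
    node_set = set(mapped)
    if bridge:
        g = disease_net.network.graph
        node_set |= {
            n
            for n in disease_net.nodes - mapped
            if n in g and sum(1 for x in g.neighbors(n) if x in mapped) >= 2
        }
    parent = disease_net.network.graph
    sub = nx.Graph(parent.subgraph(node_set & set(parent.nodes)).copy())
    sub.add_nodes_from(node_set - set(sub.nodes))
    return HerbTargetNetwork(
        herb=herb,
        network=InteractionNetwork(graph=sub),
        mapped_targets=frozenset(mapped),
        contributors={g: frozenset(profile_genes[g]) for g in mapped},
    )


def flag_off_targets(
    herb_net: HerbTargetNetwork,
    adverse_genes: Iterable[str],
    other_herb_nets: Mapping[str, HerbTargetNetwork] | None = None,
) -> HerbTargetNetwork:
    """Flag adverse-effect genes among the herb's mapped targets.

    ``other_herb_nets`` lets the report name counter-acting herbs: herbs
    whose mapped targets also hit a flagged gene (the formula-design
    reading of one herb "neutralizing" another's off-target effect).
    """
    adverse = {g.strip().upper() for g in adverse_genes}
    flags = frozenset(herb_net.mapped_targets & adverse)
    outside = adverse - herb_net.mapped_targets
    if outside:
        logger.info(
            "adverse gene(s) not among %s mapped targets: %s",
            herb_net.herb, sorted(outside),
        )
    counter: dict[str, frozenset[str]] = {}
    if other_herb_nets:
        for gene in flags:
            hitters = frozenset(
                h for h, net in other_herb_nets.items()
                if h != herb_net.herb and gene in net.mapped_targets
            )
            if hitters:
                counter[gene] = hitters
    return HerbTargetNetwork(
        herb=herb_net.herb,
        network=herb_net.network,
        mapped_targets=herb_net.mapped_targets,
        contributors=herb_net.contributors,
        off_target_flags=flags,
        counter_acting_herbs=counter,
    )


def write_network_sif(
    net: DiseaseNetwork | HerbTargetNetwork, prefix: str | Path
) -> None:
    """Write SIF edges plus a node-attribute TSV next to them."""
    prefix = Path(prefix)
    graph = net.network.graph if net.network is not None else nx.Graph()
    with open(prefix.with_suffix(".sif"), "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\tpp\t{b}\n")
    rows = []
    if isinstance(net, DiseaseNetwork):
        for node in sorted(net.nodes):
            rows.append(
                {
                    "node": node,
                    "layer": net.expansion_layer[node],
                    "provenance": ",".join(sorted(net.seed_flags.get(node, ()))),
                }
            )
    else:
        for node in sorted(net.mapped_targets):
            rows.append(
                {
                    "node": node,
                    "herb": net.herb,
                    "ingredients": ",".join(sorted(net.contributors.get(node, ()))),
                    "off_target": int(node in net.off_target_flags),
                }
            )
    pd.DataFrame(rows).to_csv(
        prefix.with_suffix(".nodes.tsv"), sep="\t", index=False
    )
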