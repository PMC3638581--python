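"""Gene-set over-representation analysis of target networks.

One-sided Fisher's exact test (hypergeometric upper tail) of a query
gene set against each term of a GMT collection, with Benjamini-Hochberg
adjustment and an FDR < 0.05 reporting rule. The background defaults to
the nodes of the interaction network the analysis ran on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .disease import HerbTargetNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "fisher_enrichment",
    "benjamini_hochberg",
    "GeneSetEnricher",
    "enrich_network",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Term-id → (name, category, genes), with an explicit background.

    Term genes outside the background are dropped at construction;
    empty terms are rejected.
    """

    sets: dict[str, tuple[str, str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        cleaned = {}
        for tid, (name, cat, genes) in self.sets.items():
            inside = frozenset(g for g in genes if g in self.background)
            if not inside:
                raise ValueError(f"term {tid!r} has no genes in the background")
            cleaned[tid] = (name, cat, inside)
        object.__setattr__(self, "sets", cleaned)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    category: str
    overlap: int
    term_size: int
    query_size: int
    background_size: int
    p_raw: float
    p_adjusted: float


def read_gmt(
    path: str | Path, background: Iterable[str] | None = None
) -> GeneSetCollection:
    """Read a GMT file (term, description, genes...).

    The description field carries the category label. If no background
    is given, the union of all term genes is used.
    """
    sets: dict[str, tuple[str, str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            tid, desc = parts[0], parts[1]
            genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            sets[tid] = (tid, desc, genes)
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    if background is None:
        bg = frozenset(g for _, _, gs in sets.values() for g in gs)
    else:
        bg = frozenset(g.strip().upper() for g in background)
    return GeneSetCollection(sets=sets, background=bg)


def fisher_enrichment(
    query: Iterable[str], term: Iterable[str], background: Iterable[str]
) -> float:
    """One-sided over-representation p-value P(X ≥ overlap).

    Hypergeometric upper tail with population = background, successes =
    term, draws = query. Query genes outside the background are dropped
    with a warning; an empty background is a hard error.
    """
    bg = {g.upper() for g in background}
    if not bg:
        raise ValueError("empty background")
    term_set = {g.upper() for g in term} & bg
    query_set = {g.upper() for g in query}
    outside = query_set - bg
    if outside:
        logger.warning(
            "%d query gene(s) outside the background dropped: %s",
            len(outside), sorted(outside)[:5],
        )
        query_set &= bg
    overlap = len(query_set & term_set)
    return float(
        hypergeom.sf(overlap - 1, len(bg), len(term_set), len(query_set))
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted p-values, original order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class GeneSetEnricher(BaseEstimator):
    """Over-representation tester fitted on a gene-set collection.

    Parameters: ``alpha`` — BH-adjusted significance cut-off for the
    default report. After :meth:`fit`, ``collection_`` holds the cleaned
    collection; :meth:`transform` tests a query gene set and returns a
    Table-1-style DataFrame (category, term id, term name, overlap,
    p_raw, p_adjusted), ascending by adjusted p.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, collection: GeneSetCollection, y=None) -> "GeneSetEnricher":
        self.collection_ = collection
        return self

    def transform(
        self, query: Iterable[str], all_terms: bool = False
    ) -> pd.DataFrame:
        coll = self.collection_
        query_set = {g.upper() for g in query} & coll.background
        if not query_set:
            raise ValueError("query has no genes in the background")
        results = []
        for tid, (name, cat, genes) in coll.sets.items():
            overlap = len(query_set & genes)
            p = float(
                hypergeom.sf(
                    overlap - 1, len(coll.background), len(genes), len(query_set)
                )
            )
            results.append((tid, name, cat, overlap, len(genes), p))
        p_adj = benjamini_hochberg([r[5] for r in results])
        df = pd.DataFrame(
            [
                EnrichmentResult(
                    term_id=tid,
                    term_name=name,
                    category=cat,
                    overlap=overlap,
                    term_size=size,
                    query_size=len(query_set),
                    background_size=len(coll.background),
                    p_raw=p,
                    p_adjusted=float(q),
                ).__dict__
                for (tid, name, cat, overlap, size, p), q in zip(results, p_adj)
            ]
        ).sort_values(["p_adjusted", "p_raw", "term_id"], kind="mergesort")
        if not all_terms:
            df = df[df["p_adjusted"] < self.alpha]
        return df.reset_index(drop=True)


def enrich_network(
    target_net: HerbTargetNetwork | Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    all_terms: bool = False,
) -> pd.DataFrame:
    """Enrich a herb target network (or a bare gene set) against a collection."""
    if isinstance(target_net, HerbTargetNetwork):
        query: Iterable[str] = target_net.mapped_targets
    else:
        query = target_net
    return GeneSetEnricher(alpha=alpha).fit(collection).transform(
        query, all_terms=all_terms
    )
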