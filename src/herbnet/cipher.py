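"""Chemical-similarity / network-closeness concordance target inference.

A candidate gene is scored for a query compound by the correlation
between (i) the query's chemical-similarity vector to a panel of
reference drugs and (ii) the gene's network-closeness vector to those
drugs' target sets. Under the "like attracts like" assumption —
structurally similar drugs bind network-proximal target modules — genes
of the module matching the query's chemistry correlate positively.

The ranked gene list truncated at ``k`` (default 100) is the compound's
*target profile*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .compounds import Compound, SimilarityVector, tanimoto
from .ppi import ClosenessVector, InteractionNetwork, closeness_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "TargetScore",
    "TargetProfile",
    "concordance_score",
    "DrugCipherCS",
    "rank_targets",
    "top_k_profile",
    "formula_profiles",
    "write_profiles",
]


@dataclass(frozen=True)
class TargetScore:
    """Concordance score of one (ingredient, gene) pair.

    ``degenerate`` marks zero-variance vectors, which score exactly 0 and
    rank after every scored gene: no evidence, not negative evidence.
    """

    ingredient_id: str
    gene: str
    score: float
    degenerate: bool = False


@dataclass(frozen=True)
class TargetProfile:
    """Top-k genes for one ingredient, ordered by (−score, gene)."""

    ingredient_id: str
    entries: tuple[tuple[str, float], ...]
    k: int

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    if x.std() == 0.0 or y.std() == 0.0:
        return 0.0, True
    return float(np.corrcoef(x, y)[0, 1]), False


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    if x.std() == 0.0 or y.std() == 0.0:
        return 0.0, True
    rho = stats.spearmanr(x, y).statistic
    return float(rho), False


_CORRELATIONS = {"pearson": _pearson, "spearman": _spearman}


def concordance_score(
    sim: SimilarityVector, clo: ClosenessVector, correlation: str = "pearson"
) -> float:
    """Correlation of aligned similarity and closeness vectors.

    Vectors must share the reference ordering and have length ≥ 3.
    Returns 0.0 for degenerate (zero-variance) input.
    """
    if sim.reference_ids != clo.reference_ids:
        raise ValueError("similarity and closeness vectors are not aligned")
    if len(sim.values) < 3:
        raise ValueError("at least 3 references are required for correlation")
    score, _ = _CORRELATIONS[correlation](sim.values, clo.values)
    return score


class DrugCipherCS(BaseEstimator):
    """Target-profile predictor over a fixed reference drug space.

    Parameters
    ----------
    k : int, default 100
        Profile size (number of top-ranked genes retained).
    correlation : {"pearson", "spearman"}
        Concordance statistic between similarity and closeness vectors.
    kernel : {"gaussian", "exponential"}
        Shortest-path kernel used for network closeness.
    gene_universe : sequence of str, optional
        Candidate genes to score; defaults to all network nodes.

    Attributes (after :meth:`fit`)
    ------------------------------
    reference_ids_ : tuple of str
        Reference drug order shared by all vectors.
    closeness_ : pandas.DataFrame
        Gene × reference closeness matrix.
    gene_universe_ : tuple of str
        Scored gene universe, sorted.
    """

    def __init__(
        self,
        k: int = 100,
        correlation: str = "pearson",
        kernel: str = "gaussian",
        gene_universe: Sequence[str] | None = None,
    ):
        self.k = k
        self.correlation = correlation
        self.kernel = kernel
        self.gene_universe = gene_universe

    def fit(
        self,
        references: Sequence[Compound] | Mapping[str, np.ndarray],
        reference_targets: Mapping[str, Iterable[str]],
        network: InteractionNetwork,
    ) -> "DrugCipherCS":
        if self.k <= 0:
            raise ValueError("k must be positive")
        if isinstance(references, Mapping):
            ref_fps = {rid: np.asarray(fp) for rid, fp in references.items()}
        else:
            ref_fps = {c.id: c.fingerprint for c in references}
        if len(ref_fps) < 3:
            raise ValueError("at least 3 reference drugs are required")
        missing = set(ref_fps) - set(reference_targets)
        if missing:
            raise ValueError(f"references without target sets: {sorted(missing)}")

        self.reference_ids_ = tuple(ref_fps)
        self.reference_fps_ = ref_fps
        ordered_targets = {rid: reference_targets[rid] for rid in self.reference_ids_}
        if self.gene_universe is None:
            universe = sorted(network.nodes)
        else:
            universe = sorted({g.upper() for g in self.gene_universe})
            outside = set(universe) - (
                network.nodes
                | {t.upper() for ts in ordered_targets.values() for t in ts}
            )
            if outside:
                raise ValueError(
                    "gene universe members outside network and reference targets: "
                    f"{sorted(outside)[:5]}..."
                )
        self.gene_universe_ = tuple(universe)
        self.closeness_ = closeness_matrix(
            universe, ordered_targets, network, kernel=self.kernel
        )
        self.network_ = network
        return self

    def _similarity(self, query: Compound) -> np.ndarray:
        return np.array(
            [tanimoto(query.fingerprint, fp) for fp in self.reference_fps_.values()]
        )

    def score_targets(self, query: Compound) -> list[TargetScore]:
        """One TargetScore per universe gene, ranked deterministically.

        Sort key: non-degenerate first, then descending score, then gene
        symbol — profiles are bit-reproducible across runs and input
        orderings.
        """
        sim = self._similarity(query)
        C = self.closeness_.to_numpy()
        sim_std = sim.std()
        clo_std = C.std(axis=1)
        degenerate = (clo_std == 0.0) | (sim_std == 0.0)
        scores = np.zeros(len(C))
        ok = ~degenerate
        if ok.any() and self.correlation == "pearson":
            cc = C[ok] - C[ok].mean(axis=1, keepdims=True)
            sc = sim - sim.mean()
            scores[ok] = (cc @ sc) / (
                np.sqrt((cc * cc).sum(axis=1)) * np.sqrt((sc * sc).sum())
            )
        elif ok.any():
            for i in np.flatnonzero(ok):
                scores[i], _ = _CORRELATIONS[self.correlation](sim, C[i])
        ranked = sorted(
            (
                TargetScore(query.id, g, float(s), bool(d))
                for g, s, d in zip(self.closeness_.index, scores, degenerate)
            ),
            key=lambda t: (t.degenerate, -t.score, t.gene),
        )
        return ranked

    def predict(self, queries: Sequence[Compound]) -> dict[str, TargetProfile]:
        """Top-k target profile for each query compound."""
        if len(queries) == 0:
            warnings.warn("empty ingredient collection: returning empty map")
            return {}
        return {
            q.id: top_k_profile(self.score_targets(q), self.k) for q in queries
        }


def rank_targets(
    query: Compound,
    references: Sequence[Compound],
    reference_targets: Mapping[str, Iterable[str]],
    network: InteractionNetwork,
    gene_universe: Sequence[str] | None = None,
    correlation: str = "pearson",
    kernel: str = "gaussian",
) -> list[TargetScore]:
    """Functional form of :meth:`DrugCipherCS.score_targets`."""
    model = DrugCipherCS(
        correlation=correlation, kernel=kernel, gene_universe=gene_universe
    ).fit(references, reference_targets, network)
    return model.score_targets(query)


def top_k_profile(scores: Sequence[TargetScore], k: int = 100) -> TargetProfile:
    """Truncate a ranked score list to its top min(k, |scores|) entries."""
    if k <= 0:
        raise ValueError("k must be positive")
    if not scores:
        raise ValueError("empty score list")
    entries = tuple((t.gene, t.score) for t in scores[:k])
    return TargetProfile(
        ingredient_id=scores[0].ingredient_id, entries=entries, k=k
    )


def formula_profiles(
    ingredients: Sequence[Compound],
    references: Sequence[Compound],
    reference_targets: Mapping[str, Iterable[str]],
    network: InteractionNetwork,
    k: int = 100,
    correlation: str = "pearson",
    kernel: str = "gaussian",
) -> dict[str, TargetProfile]:
    """Per-ingredient profiles for a whole formula.

    The union of profile genes with per-herb provenance (the formula's
    integrative target set) is available via :func:`integrative_targets`.
    """
    model = DrugCipherCS(k=k, correlation=correlation, kernel=kernel).fit(
        references, reference_targets, network
    )
    return model.predict(ingredients)


def integrative_targets(
    profiles: Mapping[str, TargetProfile], herbs: Mapping[str, str]
) -> pd.DataFrame:
    """Union of profile genes with the herbs contributing each gene."""
    gene_herbs: dict[str, set[str]] = {}
    gene_ingredients: dict[str, set[str]] = {}
    for iid, profile in profiles.items():
        herb = herbs.get(iid, "unknown")
        for gene in profile.genes:
            gene_herbs.setdefault(gene, set()).add(herb)
            gene_ingredients.setdefault(gene, set()).add(iid)
    rows = [
        {
            "gene": g,
            "herbs": ",".join(sorted(gene_herbs[g])),
            "ingredients": ",".join(sorted(gene_ingredients[g])),
            "n_ingredients": len(gene_ingredients[g]),
        }
        for g in sorted(gene_herbs)
    ]
    return pd.DataFrame(rows)


def write_profiles(
    profiles: Mapping[str, TargetProfile], path: str | Path
) -> None:
    """Write profiles as TSV: ingredient, rank, gene, score."""
    rows = []
    for iid, profile in profiles.items():
        for rank, (gene, score) in enumerate(profile.entries, start=1):
            rows.append((iid, rank, gene, score))
    pd.DataFrame(
        rows, columns=["ingredient", "rank", "gene", "score"]
    ).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> dict[str, TargetProfile]:
    """Read profiles written by :func:`write_profiles`."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, TargetProfile] = {}
    for iid, grp in df.groupby("ingredient", sort=False):
        grp = grp.sort_values("rank")
        entries = tuple(zip(grp["gene"], grp["score"].astype(float)))
        out[str(iid)] = TargetProfile(str(iid), entries, k=len(entries))
    return out
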