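"""Profile analytics: PCA of ingredient target profiles and grouping.

Each ingredient is a row of a profile matrix over the union of profile
genes — binary top-k membership by default, raw concordance scores as an
option. PCA (column-mean centred, no variance scaling: binary columns
share a scale) projects ingredients into a low-dimensional space where
chemically coherent ingredient groups separate; k-means on the leading
two components recovers the groups, scored by purity against supplied
chemical-class labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .cipher import TargetProfile

__all__ = [
    "ProfileMatrix",
    "PcaResult",
    "GroupingReport",
    "build_profile_matrix",
    "ProfilePCA",
    "run_pca",
    "assign_groups",
]


@dataclass(frozen=True)
class ProfileMatrix:
    """Ingredients × genes matrix with a declared encoding."""

    ingredient_ids: tuple[str, ...]
    gene_columns: tuple[str, ...]
    values: np.ndarray
    encoding: str  # "binary" | "score"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.ingredient_ids, columns=self.gene_columns
        )


@dataclass(frozen=True)
class PcaResult:
    """Orthonormal loadings, per-ingredient scores, variance ratios."""

    ingredient_ids: tuple[str, ...]
    gene_columns: tuple[str, ...]
    loadings: np.ndarray  # (n_components, n_genes), rows unit-norm
    scores: np.ndarray  # (n_ingredients, n_components)
    explained_variance_ratio: np.ndarray
    column_means: np.ndarray


@dataclass(frozen=True)
class GroupingReport:
    """Cluster assignments vs chemical-class labels."""

    cluster_labels: dict[str, int]
    contingency: pd.DataFrame  # clusters × classes
    purity: float


def build_profile_matrix(
    profiles: Mapping[str, TargetProfile], encoding: str = "binary"
) -> ProfileMatrix:
    """Assemble the profile matrix over the sorted union of profile genes.

    Binary encoding: 1 iff the gene is in the ingredient's top-k profile.
    Score encoding: the concordance score where present, else 0. Columns
    that are all zero after encoding are dropped.
    """
    if len(profiles) < 2:
        raise ValueError("at least 2 profiles are required")
    if encoding not in ("binary", "score"):
        raise ValueError(f"unknown encoding: {encoding!r}")
    genes = sorted({g for p in profiles.values() for g in p.genes})
    ids = tuple(profiles)
    col = {g: j for j, g in enumerate(genes)}
    values = np.zeros((len(ids), len(genes)))
    for i, iid in enumerate(ids):
        for gene, score in profiles[iid].entries:
            values[i, col[gene]] = 1.0 if encoding == "binary" else score
    keep = np.flatnonzero(np.abs(values).sum(axis=0) > 0)
    return ProfileMatrix(
        ingredient_ids=ids,
        gene_columns=tuple(genes[j] for j in keep),
        values=values[:, keep],
        encoding=encoding,
    )


class ProfilePCA(BaseEstimator, TransformerMixin):
    """PCA of a profile matrix with a deterministic sign convention.

    Columns are mean-centred (no unit-variance scaling). Loadings are the
    orthonormal principal axes, each sign-fixed so its largest-magnitude
    element is positive; scores are the centred data projected on them.

    Attributes after fit: ``loadings_``, ``explained_variance_ratio_``,
    ``column_means_``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: np.ndarray | ProfileMatrix, y=None) -> "ProfilePCA":
        values = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, float)
        n, m = values.shape
        if self.n_components > min(n - 1, m):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(rows-1, cols)"
                f"={min(n - 1, m)}"
            )
        if np.allclose(values.var(axis=0), 0.0):
            raise ValueError("profile matrix has zero total variance")
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        self._pca.fit(values)
        loadings = self._pca.components_.copy()
        # sign convention: largest-magnitude element of each axis positive
        for i, row in enumerate(loadings):
            j = int(np.argmax(np.abs(row)))
            if row[j] < 0:
                loadings[i] = -row
        self.loadings_ = loadings
        self.column_means_ = self._pca.mean_.copy()
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_.copy()
        return self

    def transform(self, X: np.ndarray | ProfileMatrix) -> np.ndarray:
        values = X.values if isinstance(X, ProfileMatrix) else np.asarray(X, float)
        return (values - self.column_means_) @ self.loadings_.T


def run_pca(matrix: ProfileMatrix, n_components: int) -> PcaResult:
    """Fit PCA on a profile matrix and bundle loadings/scores/variance."""
    model = ProfilePCA(n_components=n_components).fit(matrix)
    return PcaResult(
        ingredient_ids=matrix.ingredient_ids,
        gene_columns=matrix.gene_columns,
        loadings=model.loadings_,
        scores=model.transform(matrix),
        explained_variance_ratio=model.explained_variance_ratio_,
        column_means=model.column_means_,
    )


def purity(cluster_labels: Sequence[int], class_labels: Sequence[str]) -> float:
    """Fraction of samples in their cluster's majority class."""
    df = pd.DataFrame({"cluster": cluster_labels, "label": class_labels})
    return float(
        sum(grp["label"].value_counts().iloc[0] for _, grp in df.groupby("cluster"))
        / len(df)
    )


def assign_groups(
    result: PcaResult,
    labels: Mapping[str, str],
    k: int = 3,
    random_state: int = 0,
) -> GroupingReport:
    """K-means on the first two component scores, scored against labels.

    ``labels`` maps ingredient id to chemical class ("unknown" allowed);
    every ingredient must be covered. Default k=3 mirrors the three
    broad chemical classes of a typical formula (saponins, glycosides,
    alkaloids) but is a free parameter.
    """
    ids = result.ingredient_ids
    uncovered = [i for i in ids if i not in labels]
    if uncovered:
        raise ValueError(f"labels missing for ingredients: {uncovered[:5]}")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of ingredients {len(ids)}")
    coords = result.scores[:, : min(2, result.scores.shape[1])]
    km = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit(coords)
    clusters = [int(c) for c in km.labels_]
    class_labels = [labels[i] for i in ids]
    contingency = pd.crosstab(
        pd.Series(clusters, name="cluster"), pd.Series(class_labels, name="class")
    )
    return GroupingReport(
        cluster_labels=dict(zip(ids, clusters)),
        contingency=contingency,
        purity=purity(clusters, class_labels),
    )
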