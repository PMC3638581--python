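"""Synthetic reference spaces and the packaged QLY worked-example fixture.

The generator plants the statistical structure the concordance method
assumes — "like attracts like": reference drugs fall into families that
share a fingerprint template (chemical similarity) *and* draw their
targets from one module of a modular interaction network (network
proximity). A query built from a family's template should then recover
that family's module genes in its target profile.

The modular network is a stochastic-block-model-style graph: Bernoulli
edges at ``within_density`` inside each module, plus a fixed number of
uniformly random between-module edges. All randomness flows from one
integer seed through a single ``numpy`` generator; outputs are
byte-identical for identical (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

try:  # py>=3.9
    from importlib.resources import files as _resource_files
except ImportError:  # pragma: no cover
    _resource_files = None

from .compounds import Compound
from .ppi import InteractionNetwork, network_from_edges
from .synergy import PathwayModel, load_pathway_model

__all__ = [
    "SyntheticSpace",
    "generate_space",
    "generate_query",
    "write_space",
    "QlyFixture",
    "qly_fixture",
    "precision_at_k",
]


@dataclass(frozen=True)
class SyntheticSpace:
    """A planted-structure reference drug space."""

    ppi: InteractionNetwork
    reference_fingerprints: dict[str, np.ndarray]
    reference_targets: dict[str, frozenset[str]]
    family_of_drug: dict[str, int]
    modules: tuple[tuple[str, ...], ...]
    templates: np.ndarray  # (n_families, n_bits)
    fingerprint_noise: float
    seed: int

    @property
    def references(self) -> list[Compound]:
        return [
            Compound(id=rid, herb="reference", structure="", fingerprint=fp)
            for rid, fp in self.reference_fingerprints.items()
        ]


def generate_space(
    n_families: int = 5,
    drugs_per_family: int = 10,
    genes_per_module: int = 80,
    inter_module_edges: int = 120,
    fingerprint_noise: float = 0.1,
    seed: int = 42,
    n_bits: int = 256,
    within_density: float = 0.15,
    targets_per_drug: int = 10,
) -> SyntheticSpace:
    """Generate a modular network plus family-structured reference drugs."""
    if min(n_families, drugs_per_family, genes_per_module) < 1:
        raise ValueError("family/drug/gene counts must all be >= 1")
    if not (0.0 <= fingerprint_noise < 1.0):
        raise ValueError("fingerprint_noise must lie in [0, 1)")
    if targets_per_drug > genes_per_module:
        raise ValueError("targets_per_drug exceeds genes_per_module")
    rng = np.random.default_rng(seed)

    modules = tuple(
        tuple(f"G{m}_{i:03d}" for i in range(genes_per_module))
        for m in range(n_families)
    )
    edges: list[tuple[str, str]] = []
    for genes in modules:
        n = len(genes)
        if n >= 2:
            mask = rng.random((n, n)) < within_density
            for i in range(n):
                for j in range(i + 1, n):
                    if mask[i, j]:
                        edges.append((genes[i], genes[j]))
            # spanning chain keeps every module gene reachable
            for i in range(n - 1):
                edges.append((genes[i], genes[i + 1]))
    all_genes = [g for genes in modules for g in genes]
    if n_families > 1:
        for _ in range(inter_module_edges):
            m1, m2 = rng.choice(n_families, size=2, replace=False)
            g1 = modules[m1][rng.integers(len(modules[m1]))]
            g2 = modules[m2][rng.integers(len(modules[m2]))]
            edges.append((g1, g2))
    ppi = network_from_edges(edges)

    templates = rng.integers(0, 2, size=(n_families, n_bits)).astype(np.uint8)
    fingerprints: dict[str, np.ndarray] = {}
    targets: dict[str, frozenset[str]] = {}
    family_of: dict[str, int] = {}
    for fam in range(n_families):
        for d in range(drugs_per_family):
            rid = f"drug_f{fam}_{d:02d}"
            flips = rng.random(n_bits) < fingerprint_noise
            fingerprints[rid] = np.where(
                flips, 1 - templates[fam], templates[fam]
            ).astype(np.uint8)
            picked = rng.choice(
                len(modules[fam]), size=targets_per_drug, replace=False
            )
            targets[rid] = frozenset(modules[fam][i] for i in sorted(picked))
            family_of[rid] = fam
    return SyntheticSpace(
        ppi=ppi,
        reference_fingerprints=fingerprints,
        reference_targets=targets,
        family_of_drug=family_of,
        modules=modules,
        templates=templates,
        fingerprint_noise=fingerprint_noise,
        seed=seed,
    )


def generate_query(
    space: SyntheticSpace,
    family_index: int,
    noise: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Compound, frozenset[str]]:
    """A query compound from one family, with its planted true targets.

    The fingerprint perturbs the family template at rate ``noise``
    (default: the space's own noise); the planted targets are the whole
    module of that family.
    """
    if not (0 <= family_index < len(space.modules)):
        raise ValueError(f"no family {family_index} in this space")
    if noise is None:
        noise = space.fingerprint_noise
    if rng is None:
        rng = np.random.default_rng(space.seed + 7919 * (family_index + 1))
    template = space.templates[family_index]
    flips = rng.random(len(template)) < noise
    fp = np.where(flips, 1 - template, template).astype(np.uint8)
    query = Compound(
        id=f"query_f{family_index}", herb="query", structure="", fingerprint=fp
    )
    return query, frozenset(space.modules[family_index])


def precision_at_k(profile_genes, planted) -> float:
    """Fraction of profile genes that are planted true targets."""
    genes = list(profile_genes)
    if not genes:
        return 0.0
    planted = set(planted)
    return sum(g in planted for g in genes) / len(genes)


def write_space(space: SyntheticSpace, outdir: str | Path) -> dict[str, Path]:
    """Write a space as plain TSVs (network, fingerprints, targets, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": outdir / "ppi.tsv",
        "fingerprints": outdir / "reference_fingerprints.tsv",
        "targets": outdir / "reference_targets.tsv",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["ppi"], "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in space.ppi.edges):
            fh.write(f"{a}\t{b}\n")
    with open(paths["fingerprints"], "w") as fh:
        fh.write("id\tbits\n")
        for rid, fp in space.reference_fingerprints.items():
            fh.write(f"{rid}\t{''.join(map(str, fp))}\n")
    with open(paths["targets"], "w") as fh:
        fh.write("drug\tgene\n")
        for rid, ts in space.reference_targets.items():
            for t in sorted(ts):
                fh.write(f"{rid}\t{t}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("drug\tfamily\n")
        for rid, fam in space.family_of_drug.items():
            fh.write(f"{rid}\t{fam}\n")
    return paths


def read_fingerprints(path: str | Path) -> dict[str, np.ndarray]:
    """Read an id/bitstring fingerprint TSV written by :func:`write_space`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        row["id"]: np.array([int(c) for c in row["bits"]], dtype=np.uint8)
        for _, row in df.iterrows()
    }


def read_target_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column (drug, gene) TSV into a drug → target-set map."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if str(df.iloc[0, 0]).lower() in ("drug", "ingredient", "id"):
        df = df.iloc[1:]
    first, second = df.columns[:2]
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row[first]), set()).add(str(row[second]).upper())
    return {k: frozenset(v) for k, v in out.items()}


@dataclass(frozen=True)
class QlyFixture:
    """The packaged QLY worked example.

    Transcribed from the published description of the formula's five
    major ingredients (Matrine and Kurarinone in Ku-Shen, Sinomenine in
    Qing-Feng-Teng, Berberine in Huang-Bai, Diosgenin in Bi-Xie), their
    literature-reported targets, and the curated TNF/IL1B/VEGFA → NF-κB
    signalling model with the NFKB1-NFKB2-RELA-RELB complex declared as
    a feedback loop. PTGS1 is the adverse-effect off-target gene.
    """

    ingredient_targets: dict[str, frozenset[str]]
    herb_of_ingredient: dict[str, str]
    major_ingredients: tuple[str, ...]
    pathway_model: PathwayModel
    adverse_genes: frozenset[str]
    data_dir: Path

    @property
    def major_targets(self) -> dict[str, frozenset[str]]:
        return {
            i: self.ingredient_targets[i] for i in self.major_ingredients
        }

    def herb_ingredients(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ing, herb in self.herb_of_ingredient.items():
            out.setdefault(herb, []).append(ing)
        return out


def qly_fixture() -> QlyFixture:
    """Load the packaged QLY worked-example fixture."""
    data_dir = Path(str(_resource_files("herbnet") / "data" / "qly_fig3"))
    targets = read_target_table(data_dir / "targets.tsv")
    herbs_df = pd.read_csv(
        data_dir / "herbs.tsv", sep="\t", comment="#", header=None,
        names=["ingredient", "herb", "major"],
    )
    herb_of = dict(zip(herbs_df["ingredient"], herbs_df["herb"]))
    major = tuple(herbs_df.loc[herbs_df["major"] == 1, "ingredient"])
    model = load_pathway_model(data_dir / "pathways.tsv")
    with open(data_dir / "adverse.txt") as fh:
        adverse = frozenset(
            line.strip().upper()
            for line in fh
            if line.strip() and not line.startswith("#")
        )
    return QlyFixture(
        ingredient_targets=targets,
        herb_of_ingredient=herb_of,
        major_ingredients=major,
        pathway_model=model,
        adverse_genes=adverse,
        data_dir=data_dir,
    )
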