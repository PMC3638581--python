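"""Chemical space: compound loading, fingerprints and Tanimoto similarity.

Similarity of a query ingredient to a panel of reference drugs forms the
"drug space" axis of the concordance scoring in :mod:`herbnet.cipher`.
Fingerprints are hashed path-based bit vectors (RDKit, 2048 bits by
default); Morgan fingerprints are available as an alternative. The
coefficient is the Tanimoto (Jaccard) coefficient on bit sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Compound",
    "SimilarityVector",
    "compute_fingerprint",
    "load_compounds",
    "tanimoto",
    "similarity_vector",
    "similarity_matrix",
    "write_similarity_matrix",
]


@dataclass(frozen=True)
class Compound:
    """An ingredient or reference drug with structure and fingerprint.

    ``herb`` is the herb of origin for formula ingredients, or
    ``"reference"`` for drugs of the reference panel. ``fingerprint`` is a
    0/1 ``uint8`` vector; all compounds in one analysis must share its
    length.
    """

    id: str
    herb: str
    structure: str
    fingerprint: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        fp = np.asarray(self.fingerprint, dtype=np.uint8)
        object.__setattr__(self, "fingerprint", fp)


@dataclass(frozen=True)
class SimilarityVector:
    """Tanimoto similarities of one query to an ordered reference panel."""

    query_id: str
    reference_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if len(values) != len(self.reference_ids):
            raise ValueError("values and reference_ids differ in length")
        object.__setattr__(self, "values", values)


def compute_fingerprint(
    mol: Chem.Mol, kind: str = "path", n_bits: int = 2048
) -> np.ndarray:
    """Return a 0/1 uint8 fingerprint vector for an RDKit molecule."""
    if kind == "path":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    elif kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    else:
        raise ValueError(f"unknown fingerprint kind: {kind!r}")
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)


def _iter_smiles_records(path: Path) -> Iterable[tuple[str, str]]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                yield parts[0], ""
            else:
                yield parts[0], parts[1]


def load_compounds(
    path: str | Path,
    herb_label: str = "reference",
    fingerprint_kind: str = "path",
    n_bits: int = 2048,
) -> list[Compound]:
    """Load compounds from a SMILES table or an SDF file.

    SMILES files are whitespace-delimited, one record per line, columns
    ``id smiles``. Unparseable records are skipped with a logged count; a
    file yielding zero valid compounds is a hard error. On duplicate ids
    the last record wins (logged).
    """
    path = Path(path)
    records: list[tuple[str, Chem.Mol | None, str]] = []
    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                records.append((f"record_{i}", None, ""))
            else:
                name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record_{i}"
                records.append((name or f"record_{i}", mol, Chem.MolToSmiles(mol)))
    else:
        for cid, smi in _iter_smiles_records(path):
            mol = Chem.MolFromSmiles(smi) if smi else None
            records.append((cid, mol, smi))

    compounds: dict[str, Compound] = {}
    n_skipped = 0
    for cid, mol, smi in records:
        if mol is None:
            n_skipped += 1
            continue
        if cid in compounds:
            logger.warning("duplicate compound id %r: last record wins", cid)
        compounds[cid] = Compound(
            id=cid,
            herb=herb_label,
            structure=Chem.MolToSmiles(mol),
            fingerprint=compute_fingerprint(mol, fingerprint_kind, n_bits),
        )
    if n_skipped:
        logger.info("skipped %d unparseable record(s) in %s", n_skipped, path)
    if not compounds:
        raise ValueError(f"no parseable compound records in {path}")
    return list(compounds.values())


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two equal-length bit vectors.

    Two all-zero (featureless) fingerprints compare as 1.0 by convention,
    with a warning — this avoids 0/0 while keeping degenerate inputs
    visible.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("tanimoto of two all-zero fingerprints: returning 1.0")
        return 1.0
    return np.count_nonzero(a & b) / union


def similarity_vector(
    query: Compound, references: Sequence[Compound]
) -> SimilarityVector:
    """Tanimoto of ``query`` against each reference, order preserved."""
    if len(references) == 0:
        raise ValueError("empty reference set")
    values = np.array(
        [tanimoto(query.fingerprint, r.fingerprint) for r in references]
    )
    return SimilarityVector(
        query_id=query.id,
        reference_ids=tuple(r.id for r in references),
        values=values,
    )


def similarity_matrix(
    queries: Sequence[Compound], references: Sequence[Compound]
) -> pd.DataFrame:
    """Query × reference Tanimoto matrix as a DataFrame."""
    rows = {q.id: similarity_vector(q, references).values for q in queries}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[r.id for r in references]
    )


def write_similarity_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="query")
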