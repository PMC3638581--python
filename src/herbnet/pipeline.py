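"""Whole-formula pipeline orchestration and the run manifest.

Executes profile → cluster → network → enrich → synergy from a single
YAML-style config mapping, writing every stage output plus a manifest
(package version, config hash, input checksums) so a run is reproducible
from one artifact. Stages whose inputs are not configured are skipped;
a stage failure aborts the run naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cipher import DrugCipherCS, write_profiles, read_profiles, integrative_targets
from .compounds import Compound, load_compounds
from .disease import (
    assemble_seeds,
    expand_to_disease_network,
    flag_off_targets,
    map_herb_targets,
    read_seed_list,
    write_network_sif,
)
from .enrichment import enrich_network, read_gmt
from .ppi import load_network
from .profiles import assign_groups, build_profile_matrix, run_pca
from .synergy import build_synergy_network, load_pathway_model
from .synthetic import read_fingerprints, read_target_table

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "DEFAULT_PARAMS"]

DEFAULT_PARAMS: dict[str, Any] = {
    "k": 100,
    "fingerprint_kind": "path",
    "n_bits": 2048,
    "correlation": "pearson",
    "kernel": "gaussian",
    "n_components": 2,
    "n_clusters": 3,
    "alpha": 0.05,
    "expansion_depth": 1,
    "random_state": 0,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_compound_table(path: Path, params: Mapping[str, Any], herb="query"):
    """SMILES/SDF via RDKit, or an id/bitstring fingerprint TSV."""
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("id\tbits"):
        return [
            Compound(id=cid, herb=herb, structure="", fingerprint=fp)
            for cid, fp in read_fingerprints(path).items()
        ]
    return load_compounds(
        path, herb_label=herb,
        fingerprint_kind=params["fingerprint_kind"], n_bits=params["n_bits"],
    )


def run_pipeline(config: Mapping[str, Any]) -> dict[str, Path]:
    """Run all configured stages; return a name → output-path map."""
    inputs = dict(config.get("inputs", {}))
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    outdir = Path(config.get("outdir", "herbnet_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    herb_of: dict[str, str] = {}
    if "herbs" in inputs:
        df = pd.read_csv(inputs["herbs"], sep="\t", comment="#", header=None)
        herb_of = dict(zip(df[0].astype(str), df[1].astype(str)))

    profiles = None
    if {"compounds", "ref_compounds", "ref_targets", "ppi"} <= set(inputs):
        try:
            network = load_network(inputs["ppi"])
            queries = _load_compound_table(Path(inputs["compounds"]), params)
            refs = _load_compound_table(
                Path(inputs["ref_compounds"]), params, herb="reference"
            )
            ref_targets = read_target_table(inputs["ref_targets"])
            model = DrugCipherCS(
                k=params["k"],
                correlation=params["correlation"],
                kernel=params["kernel"],
            ).fit(refs, ref_targets, network)
            profiles = model.predict(queries)
            outputs["profiles"] = outdir / "profiles.tsv"
            write_profiles(profiles, outputs["profiles"])
            if herb_of:
                outputs["integrative_targets"] = outdir / "integrative_targets.tsv"
                integrative_targets(profiles, herb_of).to_csv(
                    outputs["integrative_targets"], sep="\t", index=False
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError("profile", exc) from exc
    elif "profiles" in inputs:
        profiles = read_profiles(inputs["profiles"])

    if profiles is not None and len(profiles) >= 2:
        try:
            matrix = build_profile_matrix(profiles)
            n_comp = min(
                params["n_components"],
                len(matrix.ingredient_ids) - 1,
                len(matrix.gene_columns),
            )
            pca = run_pca(matrix, n_components=n_comp)
            scores = pd.DataFrame(
                pca.scores,
                index=matrix.ingredient_ids,
                columns=[f"PC{i+1}" for i in range(n_comp)],
            )
            if herb_of:
                scores["herb"] = [
                    herb_of.get(i, "unknown") for i in matrix.ingredient_ids
                ]
            if params["n_clusters"] <= len(matrix.ingredient_ids):
                labels = {i: "unknown" for i in matrix.ingredient_ids}
                report = assign_groups(
                    pca, labels,
                    k=params["n_clusters"], random_state=params["random_state"],
                )
                scores["cluster"] = [
                    report.cluster_labels[i] for i in matrix.ingredient_ids
                ]
            outputs["pca_scores"] = outdir / "pca_scores.tsv"
            scores.to_csv(outputs["pca_scores"], sep="\t", index_label="ingredient")
            outputs["pca_variance"] = outdir / "pca_variance.tsv"
            pd.DataFrame(
                {
                    "component": [f"PC{i+1}" for i in range(n_comp)],
                    "explained_variance_ratio": pca.explained_variance_ratio,
                }
            ).to_csv(outputs["pca_variance"], sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError("cluster", exc) from exc

    disease_net = None
    seed_inputs = {"seeds_known", "seeds_predicted", "seeds_drug_targets"}
    if "ppi" in inputs and seed_inputs & set(inputs):
        try:
            network = load_network(inputs["ppi"])
            seeds = assemble_seeds(
                known=read_seed_list(inputs["seeds_known"])
                if "seeds_known" in inputs else (),
                predicted=read_seed_list(inputs["seeds_predicted"])
                if "seeds_predicted" in inputs else (),
                drug_targets=read_seed_list(inputs["seeds_drug_targets"])
                if "seeds_drug_targets" in inputs else (),
            )
            disease_net = expand_to_disease_network(
                seeds, network, depth=params["expansion_depth"]
            )
            outputs["disease_network"] = outdir / "disease_network.sif"
            write_network_sif(disease_net, outdir / "disease_network")
        except Exception as exc:  # noqa: BLE001
            raise StageError("network", exc) from exc

    herb_nets = {}
    if disease_net is not None and profiles is not None and herb_of:
        try:
            by_herb: dict[str, dict] = {}
            for iid, prof in profiles.items():
                by_herb.setdefault(herb_of.get(iid, "unknown"), {})[iid] = prof
            adverse = (
                read_seed_list(inputs["adverse"]) if "adverse" in inputs else []
            )
            for herb, hp in by_herb.items():
                net = map_herb_targets(herb, hp, disease_net)
                herb_nets[herb] = net
            for herb, net in herb_nets.items():
                net = flag_off_targets(net, adverse, herb_nets)
                herb_nets[herb] = net
                write_network_sif(net, outdir / f"herb_{herb}")
            outputs["herb_networks"] = outdir
        except Exception as exc:  # noqa: BLE001
            raise StageError("herb_networks", exc) from exc

    if "gmt" in inputs and (herb_nets or profiles is not None):
        try:
            background = None
            if "ppi" in inputs:
                background = load_network(inputs["ppi"]).nodes
            collection = read_gmt(inputs["gmt"], background=background)
            frames = []
            if herb_nets:
                for herb, net in herb_nets.items():
                    if not net.mapped_targets:
                        continue
                    df = enrich_network(net, collection, alpha=params["alpha"])
                    df.insert(0, "query", herb)
                    frames.append(df)
            else:
                genes = {g for p in profiles.values() for g in p.genes}
                genes &= collection.background
                if genes:
                    df = enrich_network(genes, collection, alpha=params["alpha"])
                    df.insert(0, "query", "all_profiles")
                    frames.append(df)
            outputs["enrichment"] = outdir / "enrichment.tsv"
            (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame()
            ).to_csv(outputs["enrichment"], sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrich", exc) from exc

    if "pathways" in inputs:
        try:
            model = load_pathway_model(inputs["pathways"])
            if "synergy_targets" in inputs:
                targets = read_target_table(inputs["synergy_targets"])
            elif profiles is not None:
                targets = {
                    i: frozenset(p.genes) for i, p in profiles.items()
                }
            else:
                raise ValueError("no ingredient targets for synergy stage")
            synergy = build_synergy_network(targets, model)
            outputs["synergy"] = outdir / "synergy.tsv"
            synergy.to_frame().to_csv(outputs["synergy"], sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError("synergy", exc) from exc

    manifest = {
        "herbnet_version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in config.items()}, sort_keys=True, default=str
            ).encode()
        ).hexdigest(),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
            if Path(p).is_file()
        },
        "params": params,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    outputs["manifest"] = outdir / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outputs
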