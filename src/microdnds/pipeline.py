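"""Orchestration of the full analysis: filter -> aggregate -> fit -> tests.

Stage order is fixed; any stage failure aborts with the failing stage named.
A manifest JSON lists every artifact with its SHA-256 hash, the config hash
and the seed, so reruns can be checked for bit-identity.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io as mio
from .model import fit_model, species_residuals
from .permutation import test_pathways, test_species
from .records import compute_dnds, filter_records
from .pathways import aggregate_by_pathway
from .stats import (
    cophenetic_distances,
    cv_summary,
    pairwise_pathway_correlation,
    phylo_distance_regression,
    taylor_regression,
)

logger = logging.getLogger(__name__)

STAGES = [
    "filter",
    "aggregate",
    "fit-model",
    "test-pathways",
    "test-species",
    "scaling",
    "phylosignal",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def pair_points(table: pd.DataFrame, correction: str = "none") -> pd.DataFrame:
    """Genome-wide (dS, dN/dS) per lineage pair, from pooled counts."""
    pooled = table.groupby(["species_id", "pair_id"], sort=True)[
        ["n_diff", "n_opp", "s_diff", "s_opp"]
    ].sum()
    rows = []
    n_undefined = 0
    for (species, pair), counts in pooled.iterrows():
        est = compute_dnds(tuple(int(c) for c in counts), correction=correction)
        if est.ratio is None:
            n_undefined += 1
            continue
        rows.append({"species_id": species, "pair_id": pair, "dS": est.dS, "dNdS": est.ratio})
    if n_undefined:
        logger.info("pair_points: %d pairs with dS=0 excluded", n_undefined)
    return pd.DataFrame(rows)


def run_all(config: mio.PipelineConfig) -> dict:
    """Run the whole pipeline per config; returns artifact paths and results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = mio.provenance(config.digest(), config.seed)
    artifacts: dict[str, Path] = {}
    results: dict[str, object] = {}

    def emit_tsv(name: str, frame: pd.DataFrame, **kw) -> None:
        path = out / name
        mio.write_tsv(frame, path, meta=meta, **kw)
        artifacts[name] = path

    def emit_json(name: str, obj: dict) -> None:
        path = out / name
        mio.write_json(obj, path, meta=meta)
        artifacts[name] = path

    table = mio.read_records(config.records)

    stage = "filter"
    try:
        filtered, filter_report = filter_records(
            table,
            min_s_opp=config.min_s_opp,
            min_pair_dS=config.min_pair_ds,
            max_pair_dS=config.max_pair_ds,
        )
        emit_tsv("filtered_records.tsv", filtered)
        emit_json("filter_report.json", filter_report)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "aggregate"
    try:
        pmap = mio.read_pathway_map(config.pathway_map) if config.pathway_map else None
        matrix, agg_report = aggregate_by_pathway(
            filtered, pathway_map=pmap, min_support=config.min_support
        )
        mio.write_matrix(matrix, out / "pathway_matrix.tsv", meta=meta)
        artifacts["pathway_matrix.tsv"] = out / "pathway_matrix.tsv"
        artifacts["pathway_matrix.tsv.support.json"] = out / "pathway_matrix.tsv.support.json"
        emit_json("aggregate_report.json", agg_report)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "fit-model"
    try:
        points = pair_points(filtered, correction=config.correction)
        emit_tsv("pair_points.tsv", points)
        fit = fit_model(points)
        resid = species_residuals(points, fit, seed=config.seed)
        emit_tsv("species_residuals.tsv", resid)
        emit_json("model_fit.json", fit.to_dict())
        results["fit"] = fit
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "test-pathways"
    try:
        pw = test_pathways(
            matrix, B=config.permutations, seed=config.seed, statistic=config.statistic
        )
        emit_tsv("test_pathways.tsv", pw)
        results["test_pathways"] = pw
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "test-species"
    try:
        sp = test_species(
            matrix, B=config.permutations, seed=config.seed, statistic=config.statistic
        )
        emit_tsv("test_species.tsv", sp)
        results["test_species"] = sp
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "scaling"
    try:
        scaling = taylor_regression(matrix, config.min_species_per_pathway)
        cv = cv_summary(matrix, config.min_species_per_pathway, seed=config.seed)
        emit_json(
            "scaling.json",
            {
                "taylor": scaling.to_dict(),
                "median_cv": cv["median_cv"],
                "median_cv_ci": list(cv["median_ci"]),
                "n_pathways_cv": cv["n_pathways"],
            },
        )
        results["scaling"] = scaling
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "phylosignal"
    try:
        if config.distances:
            distances = mio.read_distances(config.distances)
        elif config.tree:
            distances = cophenetic_distances(config.tree)
        else:
            raise ValueError("config needs 'tree' or 'distances' for the phylosignal stage")
        matrix_species = set(matrix.species_ids)
        dist_species = set(distances.index)
        missing = sorted(matrix_species - dist_species)
        if missing:
            raise ValueError(
                f"species in records but not in tree/distances: {missing}; "
                f"extra in tree: {sorted(dist_species - matrix_species)}"
            )
        corr = pairwise_pathway_correlation(
            matrix,
            min_shared_pathways=config.min_shared_pathways,
            method=config.correlation,
        )
        emit_tsv("pair_correlations.tsv", corr)
        signal = phylo_distance_regression(
            corr, distances, n_mantel=config.n_mantel, seed=config.seed
        )
        emit_json("phylosignal.json", signal.to_dict())
        results["phylosignal"] = signal
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": STAGES,
        "artifacts": {name: mio.sha256_file(path) for name, path in sorted(artifacts.items())},
    }
    mio.write_json(manifest, out / "manifest.json", meta=meta)
    results["manifest"] = manifest
    results["artifacts"] = artifacts
    return results
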