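"""End-to-end orchestration: synthetic or loaded inputs -> ranked candidate report."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import integration, response, similarity, vulnerability
from .io import (
    FoldChangeProfile,
    GeneMatrix,
    PipelineConfig,
    SignatureCompendium,
    write_report,
)
from .simulate import SyntheticWorld

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "final_matrix"]


def final_matrix(sim_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long similarity-predictor table to genes x profiles finals."""
    return sim_long.pivot(index="gene", columns="profile_id", values="final")


def run_pipeline(
    expression: GeneMatrix,
    dependency: GeneMatrix,
    viability: pd.DataFrame,
    profiles: Sequence[FoldChangeProfile],
    compendium: SignatureCompendium,
    anchor: str,
    config: PipelineConfig,
    citations: pd.DataFrame | None = None,
    druggable: set[str] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage of the pipeline and optionally write all artifacts.

    Returns a dict with keys: auc, corr_predictors, consensus, retained,
    sim_long, sim_final, matrix, embedding, neighbors, top_set,
    aggregate_scores, report.
    """
    logger.info("fitting dose-response curves")
    auc = vulnerability.auc_table(viability)

    logger.info("computing correlation predictors")
    corr = vulnerability.correlation_predictors(expression, dependency, auc)

    logger.info("selecting response profiles by consensus")
    consensus = response.consensus_scores(profiles)
    retained_ids = response.select_profiles(consensus, config.drop_count)
    retained = [p for p in profiles if p.profile_id in retained_ids]

    logger.info("scoring %d signatures against %d profiles",
                compendium.n_signatures, len(retained))
    sets = similarity.extract_signature_sets(compendium, config.set_size)
    raw = similarity.score_signatures(retained, sets, rho=config.inter_gene_correlation)
    agg = similarity.aggregate_by_gene(raw, compendium.meta)
    sim_long = similarity.similarity_predictors(agg)
    sim_final = final_matrix(sim_long)

    logger.info("building predictor matrix and embedding")
    matrix = integration.build_predictor_matrix(corr, sim_final)
    embedding = integration.embed(
        matrix,
        min_dist=config.umap_min_dist,
        n_neighbors=config.umap_n_neighbors,
        seed=config.master_seed,
    )
    neighbors, top_set = integration.anchor_neighbors(
        embedding, anchor, config.neighborhood_k
    )
    scores = integration.aggregate_score(corr, sim_final)

    report = neighbors.copy()
    report["aggregate_score"] = scores.reindex(report.index)
    report = integration.filter_candidates(
        report, dependency, citations=citations, druggable=druggable
    )
    report.insert(0, "gene", report.index)
    report = report.reset_index(drop=True)

    results = {
        "auc": auc,
        "corr_predictors": corr,
        "consensus": consensus,
        "retained": retained_ids,
        "sim_long": sim_long,
        "sim_final": sim_final,
        "matrix": matrix,
        "embedding": embedding,
        "neighbors": neighbors,
        "top_set": top_set,
        "aggregate_scores": scores,
        "report": report,
    }
    if outdir is not None:
        _write_outputs(results, config, Path(outdir))
    return results


def run_pipeline_on_world(
    world: SyntheticWorld,
    config: PipelineConfig,
    outdir: str | Path | None = None,
) -> dict:
    """Convenience wrapper running the full pipeline on a synthetic world."""
    return run_pipeline(
        expression=world.expression,
        dependency=world.dependency,
        viability=world.viability,
        profiles=world.profiles,
        compendium=world.compendium,
        anchor=world.truth.anchor,
        config=config,
        citations=world.citations,
        outdir=outdir,
    )


def _write_outputs(results: dict, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    results["auc"].to_csv(outdir / "auc.tsv", sep="\t")
    results["corr_predictors"].to_csv(outdir / "correlation_predictors.tsv",
                                      sep="\t", index_label="gene")
    results["consensus"].to_csv(outdir / "consensus.tsv", sep="\t")
    (outdir / "retained_profiles.txt").write_text(
        "\n".join(results["retained"]) + "\n"
    )
    results["sim_long"].to_csv(outdir / "similarity.tsv", sep="\t", index=False)
    results["matrix"].to_csv(outdir / "predictor_matrix.tsv", sep="\t",
                             index_label="gene")
    results["embedding"].coords.to_csv(outdir / "embedding.tsv", sep="\t",
                                       index_label="gene")
    results["aggregate_scores"].to_csv(outdir / "aggregate_scores.tsv", sep="\t",
                                       index_label="gene")
    write_report(results["report"], outdir / "report.tsv", fmt="tsv")
    write_report(results["report"], outdir / "report.json", fmt="json")
    config.to_yaml(outdir / "effective_config.yaml")
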