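"""End-to-end pipeline driver.

Chains the full workflow on simulated data: library simulation -> amplicon
genotype assignment -> QC / normalization -> clustering and markers ->
genotype x state enrichment -> leverage-score heterogeneity -> control-to-
stress label transfer -> fitness-set permutation test, producing a JSON-
serializable report of summary statistics.  Identical config + seed give an
identical report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import barcode_assign, cross_condition, enrichment, heterogeneity, states
from .io import PipelineConfig, write_mtx
from .synthetic_data import (
    SimConfig,
    WT_ID,
    gen_amplicon_fastq,
    gen_counts,
    gen_fitness_table,
    gen_library,
)

__all__ = ["run_pipeline"]

log = logging.getLogger("perturbatlas")


def _analyse_condition(adata, cfg: PipelineConfig, stage_seed: int):
    """QC, normalize, cluster and mark one condition's matrix."""
    kept = states.qc_filter(
        adata.X, adata.var["is_mito"].to_numpy(),
        n_sd=cfg.qc_sd, max_mito_frac=cfg.qc_mito,
    )
    adata = adata[kept].copy()
    ribo = adata.var["is_ribosomal"].to_numpy()
    adata = adata[:, ~ribo].copy()
    norm = states.normalize_log1p(adata.X, scale=cfg.norm_scale,
                                  cell_names=list(adata.obs_names))
    gene_names = list(adata.var_names)
    hvgs = states.select_hvg(norm, gene_names, n=cfg.n_hvg)
    labels = states.cluster_states(
        norm, gene_names, hvgs, dims=min(cfg.dims, len(hvgs) - 1),
        resolution=cfg.resolution, k_neighbors=cfg.k_neighbors,
        seed=stage_seed,
    )
    adata.obs["state"] = labels
    markers = states.find_markers(
        norm, gene_names, labels, lfc_cut=cfg.marker_lfc, alpha=cfg.alpha,
    )
    return adata, norm, markers


def run_pipeline(
    config: PipelineConfig,
    sim_config: SimConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the complete simulated-study workflow and return the report."""
    config.validate()
    report: dict = {"seed": config.seed}
    if sim_config is None:
        sim_config = SimConfig(seed=config.stage_seed("simulate"))

    log.info("simulate: %d genotypes, seed %d", sim_config.n_genotypes,
             sim_config.seed)
    library = gen_library(
        sim_config.n_genotypes, sim_config.clones_per_genotype,
        seed=sim_config.seed,
    )
    ctrl_cfg = sim_config
    import dataclasses

    stress_cfg = dataclasses.replace(
        sim_config, condition="stress", seed=sim_config.seed + 1
    )
    adata_c, truth_c = gen_counts(library, ctrl_cfg)
    adata_s, truth_s = gen_counts(library, stress_cfg)
    report["n_cells_control"] = int(adata_c.n_obs)
    report["n_cells_stress"] = int(adata_s.n_obs)

    log.info("assign: amplicon genotype calling")
    r1, r2, bc_table = gen_amplicon_fastq(library, truth_c, ctrl_cfg)
    calls = barcode_assign.assign_cells(
        r1, r2, library,
        max_mm_anchor=config.max_mm_anchor, max_mm_bc=config.max_mm_bc,
        majority=config.majority,
    )
    truth_bc = truth_c.merge(bc_table, on="cell")[["cell_barcode", "genotype"]]
    metrics = barcode_assign.evaluate_assignment(calls, truth_bc)
    report["assignment"] = metrics

    log.info("states: QC, clustering, markers per condition")
    seed_states = config.stage_seed("states")
    adata_c, norm_c, markers_c = _analyse_condition(adata_c, config, seed_states)
    adata_s, norm_s, markers_s = _analyse_condition(adata_s, config, seed_states)
    report["n_states_control"] = int(adata_c.obs["state"].nunique())
    report["n_states_stress"] = int(adata_s.obs["state"].nunique())

    log.info("enrichment: genotype x state Fisher tests")
    enr = enrichment.state_enrichment(
        adata_c.obs["state"].to_numpy(), adata_c.obs["genotype"].to_numpy(),
        min_cells=config.min_cells, alpha=config.alpha,
    )
    enriched = sorted(
        enr.loc[enr["class"] == "enriched", "genotype"].unique().tolist()
    )
    report["n_enriched_genotypes"] = len(enriched)

    log.info("leverage: per-plate SVD heterogeneity")
    cell_lev, geno_lev = heterogeneity.leverage_pipeline(
        adata_c.X, norm_c,
        adata_c.obs["plate"].to_numpy(), adata_c.obs["genotype"].to_numpy(),
        wt_id=WT_ID, k=config.k_svd, min_mean=config.min_mean,
        min_cells=config.min_cells, up=config.reg_up, down=config.reg_down,
    )
    report["n_negative_regulators"] = int(
        (geno_lev["class"] == "negative_regulator").sum()
    )
    report["n_positive_regulators"] = int(
        (geno_lev["class"] == "positive_regulator").sum()
    )
    wt_sd = geno_lev.loc[geno_lev["genotype"] == WT_ID, "sd_scaled"]
    report["wt_sd_scaled"] = float(wt_sd.iloc[0]) if len(wt_sd) else None

    log.info("transfer: control -> stress core states")
    shared = sorted(set(adata_c.var_names) & set(adata_s.var_names))
    _, tmap = cross_condition.transfer_labels(
        adata_c[:, shared].X, adata_c.obs["state"].to_numpy(),
        adata_s[:, shared].X, adata_s.obs["state"].to_numpy(),
        shared, dims=config.dims,
        k_neighbors=min(config.transfer_k, adata_c.n_obs),
        min_share=config.core_share, seed=config.stage_seed("transfer"),
    )
    report["n_core_states"] = int(tmap.per_ref_state["core"].sum())
    report["n_ref_states"] = int(len(tmap.per_ref_state))

    log.info("fitness: permutation test over %d draws", config.n_perm)
    fitness = gen_fitness_table(
        library.genotype_ids, seed=config.stage_seed("fitness"),
    )
    test_set = enriched or geno_lev.sort_values("sd_scaled").tail(3)["genotype"].tolist()
    test_set = [g for g in test_set if g != WT_ID][: max(1, len(fitness) // 4)]
    pvals = cross_condition.fitness_permutation(
        test_set, fitness, n_perm=config.n_perm, side=config.fitness_side,
        seed=config.stage_seed("fitness_perm"),
    )
    report["fitness_p_median"] = float(pvals.median())
    report["fitness_set_size"] = len(test_set)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mtx(adata_c, outdir / "control")
        write_mtx(adata_s, outdir / "stress")
        calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
        markers_c.to_csv(outdir / "markers_control.tsv", sep="\t", index=False)
        markers_s.to_csv(outdir / "markers_stress.tsv", sep="\t", index=False)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        cell_lev.to_csv(outdir / "leverage_cells.tsv", sep="\t", index=False)
        geno_lev.to_csv(outdir / "leverage_genotypes.tsv", sep="\t", index=False)
        tmap.per_ref_state.to_csv(outdir / "core_states.tsv", sep="\t")
        pvals.to_frame().to_csv(outdir / "fitness_p.tsv", sep="\t")
        (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                       sort_keys=True))
    return report
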