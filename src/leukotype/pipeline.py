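"""Config-driven end-to-end orchestration on synthetic data.

Stages (dependency order): simulate -> qc -> cluster -> de -> pseudotime ->
rpstate -> cnv -> mut_enrich. Each stage reads its predecessors' outputs
from the run directory and writes its own, so stages can be re-run
individually; a manifest echoing every resolved parameter and per-stage
seed is written at the end. Per-stage seeds are derived from the master
seed by hashing the stage name (documented, deterministic).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, cnv, de, io, mutations, pseudotime, qc, rpstate
from .simulate import (SimulationConfig, SimulationTruth,
                       simulate_allele_calls, simulate_healthy_trajectory,
                       simulate_leukemia_sample, gene_annotation)

log = logging.getLogger("leukotype")

STAGES = ("simulate", "qc", "cluster", "de", "pseudotime", "rpstate", "cnv",
          "mut_enrich")
DEPENDS = {
    "simulate": (),
    "qc": ("simulate",),
    "cluster": ("qc",),
    "de": ("cluster",),
    "pseudotime": ("qc",),
    "rpstate": ("cluster", "pseudotime"),
    "cnv": ("cluster",),
    "mut_enrich": ("cluster", "simulate"),
}


class DependencyError(RuntimeError):
    """A stage is enabled while a stage it depends on is not."""


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults."""

    stages: tuple = STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_clusters: int = 2
    pseudotime_shift: float = 0.3
    n_variants: int = 100
    # QC
    min_cells_per_gene: int = 5
    min_genes_per_cell: int = 200
    max_mito: float = 0.08
    scale_factor: float = 10_000.0
    top_n_hvg_per_sample: int = 1000
    min_hvg_samples: int = 2
    # clustering
    n_components: int = 20
    n_neighbors: int = 20
    res_min: float = 0.1
    res_max: float = 3.0
    res_step: float = 0.1
    min_cluster_frac: float = 0.10
    # pseudotime
    curve_span: float = 0.5
    curve_samples: int = 500
    outlier_k_sd: float = 3.0
    hidden_nodes: int = 15
    cv_splits: int = 100
    cv_train_frac: float = 0.7
    # CNV
    n_metacells: int = 30
    cnv_window: int = 101
    cnv_gain_thresh: float = 0.2
    cnv_loss_thresh: float = -0.2
    cnv_min_genes: int = 50
    # mutations
    min_alt_frac: float = 0.001
    seed: int = 0
    out_dir: str = "leukotype_run"


def stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _check_dependencies(stages) -> None:
    enabled = set(stages)
    unknown = enabled - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for s in stages:
        for dep in DEPENDS[s]:
            if dep not in enabled:
                raise DependencyError(f"stage '{s}' requires stage '{dep}'")


# ---------------------------------------------------------------- stages


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    seed = stage_seed(cfg.seed, "simulate")
    sim = dataclasses.replace(cfg.simulation, seed=seed)
    healthy, truth_h = simulate_healthy_trajectory(sim)
    leukemia, truth_l = simulate_leukemia_sample(
        sim, n_clusters=cfg.n_clusters, pseudotime_shift=cfg.pseudotime_shift)
    calls = simulate_allele_calls(truth_l, cfg.n_variants, sim)

    d = out / "simulate"
    io.write_tenx_like(healthy, d / "healthy")
    io.write_tenx_like(leukemia, d / "leukemia")
    io.write_allele_calls(calls, d / "alleles")
    truth_h.cells.to_csv(d / "truth_healthy.tsv", sep="\t")
    truth_l.cells.to_csv(d / "truth_leukemia.tsv", sep="\t")
    gene_annotation(sim).to_csv(d / "gene_annotation.tsv", sep="\t", index=False)
    meta = {"enriched_variant_id": truth_l.enriched_variant_id,
            "enriched_cluster": truth_l.enriched_cluster,
            "planted_cnv": [list(map(str, (c, s, m)))
                            for c, s, m in truth_l.planted_cnv]}
    (d / "truth_meta.json").write_text(json.dumps(meta, indent=2))


def _load_counts(out: Path, which: str):
    return io.read_tenx_like(out / "simulate" / which)


def _stage_qc(cfg: RunConfig, out: Path) -> None:
    seed = stage_seed(cfg.seed, "qc")
    d = out / "qc"
    d.mkdir(parents=True, exist_ok=True)
    expr_by_sample = {}
    for which in ("healthy", "leukemia"):
        counts = _load_counts(out, which)
        flags = qc.gene_flags(counts.gene_symbols)
        filtered = qc.filter_cells_genes(
            counts, flags, min_cells_per_gene=cfg.min_cells_per_gene,
            min_genes_per_cell=cfg.min_genes_per_cell, max_mito=cfg.max_mito)
        fl = qc.gene_flags(filtered.gene_symbols)
        table = qc.compute_cell_qc(filtered, fl)
        expr = qc.normalize_log(filtered, scale_factor=cfg.scale_factor)

        # synthetic stand-in phase gene sets: seeded draw of non-RP genes
        rng = np.random.default_rng(seed)
        pool = [s for s in filtered.gene_symbols
                if not s.startswith(("RPS", "RPL", "MT-"))]
        s_genes = list(rng.choice(pool, size=min(20, len(pool)), replace=False))
        g2m_genes = list(rng.choice(pool, size=min(20, len(pool)), replace=False))
        cycle = qc.score_cell_cycle(expr, s_genes, g2m_genes, seed=seed)
        table = table.join(cycle)

        covs = pd.DataFrame({
            "n_umi": table["n_umi"].to_numpy(float),
            "mito_fraction": table["mito_fraction"].to_numpy(float),
            "s_score": table["s_score"].to_numpy(float),
            "g2m_score": table["g2m_score"].to_numpy(float),
        })
        resid = qc.regress_covariates(expr, covs)
        expr_by_sample[which] = resid

        io.write_tenx_like(filtered, d / f"filtered_{which}")
        table.to_csv(d / f"cell_table_{which}.tsv", sep="\t")

    hvg = qc.select_variable_genes_pooled(
        expr_by_sample, top_n_per_sample=cfg.top_n_hvg_per_sample,
        min_samples=cfg.min_hvg_samples)
    pd.Series(hvg, name="gene_symbol").to_csv(d / "hvg.tsv", sep="\t", index=False)
    for which, expr in expr_by_sample.items():
        mask = np.isin(expr.gene_symbols, hvg)
        sub = expr.subset_genes(mask)
        pd.DataFrame(sub.dense(), index=sub.gene_symbols,
                     columns=sub.cell_barcodes).to_csv(
            d / f"expr_hvg_{which}.tsv", sep="\t")


def _load_expr(out: Path, which: str) -> pd.DataFrame:
    return pd.read_csv(out / "qc" / f"expr_hvg_{which}.tsv", sep="\t", index_col=0)


def _stage_cluster(cfg: RunConfig, out: Path) -> None:
    seed = stage_seed(cfg.seed, "cluster")
    expr = _load_expr(out, "leukemia")
    model = clustering.ConsensusLouvain(
        n_components=cfg.n_components, n_neighbors=cfg.n_neighbors,
        res_min=cfg.res_min, res_max=cfg.res_max, step=cfg.res_step, seed=seed)
    labels = model.fit_predict(expr.to_numpy().T)
    barcodes = expr.columns.to_numpy(dtype=object)
    samples = np.full(len(barcodes), "leukemia", dtype=object)
    labels_obj = np.array([f"L{v}" for v in labels], dtype=object)
    kept_labels, keep = clustering.drop_small_clusters(
        labels_obj, samples, min_frac=cfg.min_cluster_frac)

    d = out / "cluster"
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"barcode": barcodes, "cluster": kept_labels, "kept": keep}) \
        .to_csv(d / "clusters.tsv", sep="\t", index=False)
    ps = model.partition_set_
    long = pd.DataFrame(
        {"resolution": np.repeat(ps.resolutions, len(barcodes)),
         "barcode": np.tile(barcodes, len(ps.resolutions)),
         "label": ps.partitions.ravel()})
    long.to_csv(d / "partitions.tsv", sep="\t", index=False)
    summary = {"chosen_resolution": ps.chosen_resolution,
               "n_resolutions": int(len(ps.resolutions)),
               "mean_ari": dict(zip(map(str, ps.resolutions),
                                    map(float, ps.mean_ari)))}
    (d / "summary.json").write_text(json.dumps(summary, indent=2))


def _load_clusters(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "cluster" / "clusters.tsv", sep="\t",
                       dtype={"barcode": str})


def _stage_de(cfg: RunConfig, out: Path) -> None:
    expr = _load_expr(out, "leukemia")
    cl = _load_clusters(out)
    kept = cl[cl["kept"]]
    top2 = kept["cluster"].value_counts().index[:2]
    if len(top2) < 2:
        raise RuntimeError("fewer than 2 retained clusters; DE skipped")
    order = {b: i for i, b in enumerate(expr.columns)}
    X = expr.to_numpy()
    idx_a = [order[b] for b in kept.loc[kept["cluster"] == top2[0], "barcode"]]
    idx_b = [order[b] for b in kept.loc[kept["cluster"] == top2[1], "barcode"]]
    res = de.hurdle_de_test(X[:, idx_a], X[:, idx_b],
                            gene_symbols=expr.index.to_numpy(dtype=object))
    d = out / "de"
    d.mkdir(parents=True, exist_ok=True)
    res.to_csv(d / "de_results.tsv", sep="\t", index=False)
    pd.Series(de.top_de_genes(res, n=100), name="gene") \
        .to_csv(d / "top_genes.tsv", sep="\t", index=False)


def _stage_pseudotime(cfg: RunConfig, out: Path) -> None:
    seed = stage_seed(cfg.seed, "pseudotime")
    expr_h = _load_expr(out, "healthy")
    truth_h = pd.read_csv(out / "simulate" / "truth_healthy.tsv", sep="\t",
                          index_col=0)
    truth_h = truth_h.loc[[b for b in expr_h.columns]]

    coords = clustering.pca_embed(expr_h.to_numpy().T, n_components=2)
    curve = pseudotime.MaturationCurve(span=cfg.curve_span,
                                       n_samples=cfg.curve_samples)
    curve.fit(coords, stem_mask=(truth_h["population"] == "stem-like").to_numpy())
    arc, dist = curve.project(coords)
    keep = pseudotime.remove_projection_outliers(dist, k_sd=cfg.outlier_k_sd)
    pt = np.full(len(arc), np.nan)
    pt[keep] = pseudotime.assign_pseudotime(arc[keep])

    X = expr_h.to_numpy().T[keep]
    y = pt[keep]
    cv = pseudotime.crossvalidate_regressor(
        X, y, n_splits=cfg.cv_splits, train_frac=cfg.cv_train_frac, seed=seed,
        hidden_nodes=cfg.hidden_nodes)
    model = pseudotime.PseudotimeRegressor(
        hidden_nodes=cfg.hidden_nodes, seed=seed,
        gene_list=list(expr_h.index)).fit(X, y)

    expr_l = _load_expr(out, "leukemia")
    pred = model.predict(expr_l.to_numpy().T, gene_symbols=list(expr_l.index))

    d = out / "pseudotime"
    d.mkdir(parents=True, exist_ok=True)
    healthy_df = pd.DataFrame({"barcode": expr_h.columns, "pseudotime": pt,
                               "kept": keep, "source": "assigned"})
    leuk_df = pd.DataFrame({"barcode": expr_l.columns, "pseudotime": pred,
                            "kept": True, "source": "predicted"})
    pd.concat([healthy_df, leuk_df]).to_csv(d / "pseudotime.tsv", sep="\t",
                                            index=False)
    (d / "cv.json").write_text(json.dumps(
        {"n_splits": int(len(cv.split_rmse)), "mean_rmse": cv.mean_rmse}))


def _stage_rpstate(cfg: RunConfig, out: Path) -> None:
    counts = io.read_tenx_like(out / "qc" / "filtered_leukemia")
    mask = rpstate.rp_gene_set(counts.gene_symbols)
    frac = rpstate.rp_fraction(counts, mask)

    pt = pd.read_csv(out / "pseudotime" / "pseudotime.tsv", sep="\t")
    pt = pt[pt["source"] == "predicted"].set_index("barcode")["pseudotime"]
    cl = _load_clusters(out)
    kept = cl[cl["kept"]].set_index("barcode")

    common = kept.index.intersection(pt.index).intersection(frac.index)
    shift = rpstate.pseudotime_shift_test(pt.loc[common],
                                          kept.loc[common, "cluster"])
    rho, p = rpstate.pseudotime_rp_correlation(pt.loc[common], frac.loc[common])

    d = out / "rpstate"
    d.mkdir(parents=True, exist_ok=True)
    frac.to_csv(d / "rp_fraction.tsv", sep="\t")
    shift.to_csv(d / "shift_tests.tsv", sep="\t", index=False)
    (d / "correlation.json").write_text(json.dumps(
        {"spearman_rho": rho, "p_value": p, "n_cells": int(len(common))}))


def _stage_cnv(cfg: RunConfig, out: Path) -> None:
    seed = stage_seed(cfg.seed, "cnv")
    leukemia = io.read_tenx_like(out / "qc" / "filtered_leukemia")
    healthy = io.read_tenx_like(out / "qc" / "filtered_healthy")
    cl = _load_clusters(out).set_index("barcode")
    labels = np.array([cl["cluster"].get(b, None)
                       for b in leukemia.cell_barcodes], dtype=object)
    labels = np.where(pd.isna(labels), None, labels)

    test_mc = cnv.make_metacells(leukemia, labels, n_metacells=cfg.n_metacells,
                                 seed=seed)
    ctrl_labels = np.full(healthy.n_cells, "healthy", dtype=object)
    ctrl_mc = cnv.make_metacells(healthy, ctrl_labels,
                                 n_metacells=cfg.n_metacells, seed=seed)
    ann = pd.read_csv(out / "simulate" / "gene_annotation.tsv", sep="\t")
    profiler = cnv.CNVProfiler(gene_order=ann, window=cfg.cnv_window)
    profile = profiler.fit(ctrl_mc).transform(test_mc)
    segments = cnv.call_cnv_segments(
        profile, gain_thresh=cfg.cnv_gain_thresh,
        loss_thresh=cfg.cnv_loss_thresh, min_genes=cfg.cnv_min_genes)

    d = out / "cnv"
    d.mkdir(parents=True, exist_ok=True)
    segments.to_csv(d / "segments.tsv", sep="\t", index=False)
    pd.DataFrame(profile.values, index=profile.genes["gene_symbol"]) \
        .to_csv(d / "profile.tsv", sep="\t")
    profile.origin.to_csv(d / "metacell_origin.tsv", sep="\t", index=False)


def _stage_mut_enrich(cfg: RunConfig, out: Path) -> None:
    calls = io.read_allele_calls(out / "simulate" / "alleles")
    cl = _load_clusters(out).set_index("barcode")
    labels = np.array([cl["cluster"].get(b, None) for b in calls.cell_barcodes],
                      dtype=object)
    labels = np.where(pd.isna(labels), None, labels)
    coverage = mutations.summarize_call_coverage(calls)
    enrich = mutations.cluster_enrichment(calls, labels,
                                          min_alt_frac=cfg.min_alt_frac)
    d = out / "mut_enrich"
    d.mkdir(parents=True, exist_ok=True)
    coverage.to_csv(d / "coverage.tsv", sep="\t")
    enrich.to_csv(d / "enrichment.tsv", sep="\t", index=False)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "de": _stage_de,
    "pseudotime": _stage_pseudotime,
    "rpstate": _stage_rpstate,
    "cnv": _stage_cnv,
    "mut_enrich": _stage_mut_enrich,
}


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in dependency order; returns the manifest."""
    _check_dependencies(config.stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    executed = []
    for stage in STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            _STAGE_FN[stage](config, out)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        executed.append(stage)
    params = dataclasses.asdict(config)
    manifest = {
        "stages": executed,
        "parameters": params,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in executed},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
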