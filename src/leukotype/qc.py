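"""Cell/gene QC, log-normalization, cell-cycle scoring, covariate regression
and pooled highly-variable-gene selection.

Filtering follows the droplet scRNA-seq convention: genes expressed in at
least 5 cells, cells with at least 200 detected genes and a mitochondrial
read fraction strictly below 8% are retained; the gene filter is applied
first, then the cell filter, in a single pass.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, ExpressionMatrix


class EmptyResultError(ValueError):
    """Raised when a filter removes every cell (or gene)."""


def gene_flags(symbols, mito_prefix: str = "MT-", rp_prefixes=("RPS", "RPL"),
               rp_list=None) -> pd.DataFrame:
    """Per-gene mito/RP flags by symbol prefix, or an explicit RP list.

    When ``rp_list`` is given it overrides the prefix rule for RP genes; the
    returned frame records how many of the listed symbols were found.
    """
    symbols = np.asarray(symbols, dtype=object)
    is_mito = np.array([s.startswith(mito_prefix) for s in symbols], bool)
    if rp_list is not None:
        wanted = set(rp_list)
        is_rp = np.array([s in wanted for s in symbols], bool)
    else:
        is_rp = np.array([s.startswith(tuple(rp_prefixes)) for s in symbols], bool)
    return pd.DataFrame({"gene_symbol": symbols, "is_mito": is_mito, "is_rp": is_rp})


def compute_cell_qc(counts: CountMatrix, flags: pd.DataFrame) -> pd.DataFrame:
    """Per-cell QC statistics: nUMI, detected genes, mito fraction.

    Zero-count cells get mito_fraction 0 and are flagged for removal.
    """
    if len(flags) != counts.n_genes:
        raise ValueError("gene flags not aligned to matrix genes")
    X = counts.values.tocsc()
    n_umi = np.asarray(X.sum(axis=0)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=0)).ravel()
    mito_counts = np.asarray(X[flags["is_mito"].to_numpy()].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(n_umi > 0, mito_counts / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "sample": counts.sample_of_cell,
            "n_umi": n_umi.astype(int),
            "n_genes_detected": n_genes.astype(int),
            "mito_fraction": mito_fraction,
            "flag_zero_count": n_umi == 0,
        },
        index=pd.Index(counts.cell_barcodes, name="barcode"),
    )


def filter_cells_genes(
    counts: CountMatrix,
    flags: pd.DataFrame | None = None,
    min_cells_per_gene: int = 5,
    min_genes_per_cell: int = 200,
    max_mito: float = 0.08,
) -> CountMatrix:
    """One-pass gene-then-cell filter.

    Genes expressed (count > 0) in >= ``min_cells_per_gene`` cells are kept;
    then cells with >= ``min_genes_per_cell`` detected genes (counted over the
    retained genes) and mito_fraction strictly below ``max_mito`` are kept.
    """
    if min(min_cells_per_gene, min_genes_per_cell) < 0 or max_mito < 0:
        raise ValueError("thresholds must be non-negative")
    if flags is None:
        flags = gene_flags(counts.gene_symbols)
    gene_keep = np.asarray((counts.values > 0).sum(axis=1)).ravel() >= min_cells_per_gene
    sub = counts.subset(gene_mask=gene_keep)
    qc = compute_cell_qc(sub, flags[gene_keep].reset_index(drop=True))
    cell_keep = ((qc["n_genes_detected"].to_numpy() >= min_genes_per_cell)
                 & (qc["mito_fraction"].to_numpy() < max_mito)
                 & ~qc["flag_zero_count"].to_numpy())
    if not cell_keep.any():
        raise EmptyResultError("all cells removed by QC filters")
    return sub.subset(cell_mask=cell_keep)


def normalize_log(counts: CountMatrix, scale_factor: float = 10_000.0
                  ) -> ExpressionMatrix:
    """Library-size normalization to ``scale_factor`` then ln(1 + x)."""
    totals = np.asarray(counts.values.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = counts.cell_barcodes[totals == 0][0]
        raise ValueError(f"zero-total cell present: {bad}")
    X = counts.values.tocsc().astype(float)
    X = X.multiply(scale_factor / totals[None, :]).tocsr()
    X.data = np.log1p(X.data)
    return ExpressionMatrix(
        values=X,
        gene_symbols=counts.gene_symbols,
        cell_barcodes=counts.cell_barcodes,
        sample_of_cell=counts.sample_of_cell,
        provenance=[f"normalize_log(scale_factor={scale_factor:g})"],
    )


def _module_score(dense: np.ndarray, set_idx: np.ndarray, n_bins: int,
                  n_ctrl: int, rng: np.random.Generator) -> np.ndarray:
    """Signature score: mean over the gene set minus the mean over a control
    set drawn from expression-matched bins (the module-score construction
    used for cell-cycle phase signatures)."""
    mean_expr = dense.mean(axis=1)
    n_genes = len(mean_expr)
    order = np.argsort(mean_expr, kind="stable")
    n_bins_eff = max(1, min(n_bins, n_genes // 2))
    bin_of = np.empty(n_genes, int)
    for b, idx in enumerate(np.array_split(order, n_bins_eff)):
        bin_of[idx] = b
    ctrl_idx: list[int] = []
    in_set = np.zeros(n_genes, bool)
    in_set[set_idx] = True
    for b in np.unique(bin_of[set_idx]):
        pool = np.flatnonzero((bin_of == b) & ~in_set)
        if len(pool) == 0:
            pool = np.flatnonzero(bin_of == b)
        take = min(n_ctrl, len(pool))
        ctrl_idx.extend(rng.choice(pool, size=take, replace=False))
    ctrl_idx = np.unique(ctrl_idx)
    return dense[set_idx].mean(axis=0) - dense[ctrl_idx].mean(axis=0)


def score_cell_cycle(expr: ExpressionMatrix, s_genes, g2m_genes,
                     n_bins: int = 25, n_ctrl: int = 50, seed: int = 0
                     ) -> pd.DataFrame:
    """S and G2/M scores (phase-set mean minus expression-matched control mean)
    and the phase call: G1 iff both scores <= 0, else the larger score's phase.
    Control genes are sampled with the given seed (recorded in provenance by
    callers that persist the table).
    """
    symbols = {g: i for i, g in enumerate(expr.gene_symbols)}
    s_idx = np.array([symbols[g] for g in s_genes if g in symbols], int)
    g2m_idx = np.array([symbols[g] for g in g2m_genes if g in symbols], int)
    if len(s_idx) == 0 or len(g2m_idx) == 0:
        raise ValueError("phase gene sets empty after intersecting with the matrix")
    dense = expr.dense()
    rng = np.random.default_rng(seed)
    s = _module_score(dense, s_idx, n_bins, n_ctrl, rng)
    g2m = _module_score(dense, g2m_idx, n_bins, n_ctrl, rng)
    phase = np.where((s <= 0) & (g2m <= 0), "G1", np.where(s > g2m, "S", "G2M"))
    return pd.DataFrame(
        {"s_score": s, "g2m_score": g2m, "phase": phase},
        index=pd.Index(expr.cell_barcodes, name="barcode"),
    )


def regress_covariates(expr: ExpressionMatrix, covariates: pd.DataFrame | None
                       ) -> ExpressionMatrix:
    """Per-gene OLS of expression on the covariates (with intercept); returns
    residuals. An empty covariate set reduces to per-gene centering."""
    Y = expr.dense()
    n_cells = Y.shape[1]
    if covariates is None or covariates.shape[1] == 0:
        X = np.ones((n_cells, 1))
        names = ["intercept"]
    else:
        if covariates.isna().to_numpy().any():
            raise ValueError("covariates contain missing values")
        X = np.column_stack([np.ones(n_cells), covariates.to_numpy(float)])
        names = ["intercept"] + list(covariates.columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient covariate matrix (rank {rank} < "
                         f"{X.shape[1]}); columns: {names}")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    label = f"regress_covariates({', '.join(names[1:]) or 'intercept-only'})"
    return expr.with_values(resid, label)


def _dispersion_ranks(values, n_mean_bins: int = 20) -> np.ndarray:
    """Binned standardized dispersion (var/mean z-scored within mean bins)."""
    if sp.issparse(values):
        mean = np.asarray(values.mean(axis=1)).ravel()
        sq = np.asarray(values.multiply(values).mean(axis=1)).ravel()
    else:
        mean = values.mean(axis=1)
        sq = (values**2).mean(axis=1)
    var = np.maximum(sq - mean**2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    order = np.argsort(mean, kind="stable")
    # equal-frequency bins with enough genes each for a stable z-score
    n_bins_eff = max(1, min(n_mean_bins, len(mean) // 10))
    bins = np.array_split(order, n_bins_eff)
    z = np.zeros_like(disp)
    # floor the bin SD so bins of near-identical dispersion do not amplify
    # numerical noise into large z-scores
    sd_floor = 0.05 * disp.std()
    for idx in bins:
        if len(idx) == 0:
            continue
        mu, sd = disp[idx].mean(), disp[idx].std()
        sd = max(sd, sd_floor)
        z[idx] = (disp[idx] - mu) / sd if sd > 0 else 0.0
    return z


def select_variable_genes_pooled(
    expr_by_sample: dict[str, ExpressionMatrix],
    top_n_per_sample: int = 1000,
    min_samples: int = 2,
    n_mean_bins: int = 20,
) -> list[str]:
    """Pooled HVG list: top-N most dispersed genes per sample, keep genes in
    the top list of at least ``min_samples`` samples.

    Ordering of the result is deterministic: by number of supporting samples
    (descending), then best per-sample rank, then symbol.
    """
    if len(expr_by_sample) < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {len(expr_by_sample)}")
    hits: dict[str, list[int]] = {}
    for name, expr in expr_by_sample.items():
        z = _dispersion_ranks(expr.values, n_mean_bins=n_mean_bins)
        n_take = min(top_n_per_sample, len(z))
        if n_take < top_n_per_sample:
            warnings.warn(f"sample {name} has only {n_take} genes; using all")
        # stable tie-break on symbol for reproducibility
        order = np.lexsort((expr.gene_symbols.astype(str), -z))[:n_take]
        for rank, gi in enumerate(order):
            hits.setdefault(str(expr.gene_symbols[gi]), []).append(rank)
    pooled = [(g, ranks) for g, ranks in hits.items() if len(ranks) >= min_samples]
    pooled.sort(key=lambda item: (-len(item[1]), min(item[1]), item[0]))
    return [g for g, _ in pooled]
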