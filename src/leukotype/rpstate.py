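"""Ribosomal-protein expression fraction and the pseudotime/RP analysis.

RP fraction is the ratio of raw UMI counts mapped to ribosomal-protein genes
over the cell's total raw counts. Pseudotime distribution shifts between
intra-sample clusters are tested with a two-sided Mann-Whitney U test
(Kolmogorov-Smirnov available as an option) with BH correction across
cluster pairs, and the pseudotime/RP relation is summarized by Spearman rank
correlation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix


def rp_gene_set(gene_symbols, rp_list=None, rp_prefixes=("RPS", "RPL")) -> np.ndarray:
    """Boolean RP mask over the matrix genes.

    With an explicit list (e.g. a curated 97-gene ribosomal-protein set) the
    mask is membership; otherwise the RPS/RPL prefix rule applies. An empty
    resulting set is an error.
    """
    symbols = np.asarray(gene_symbols, dtype=object)
    if rp_list is not None:
        wanted = set(rp_list)
        mask = np.array([s in wanted for s in symbols], bool)
    else:
        mask = np.array([s.startswith(tuple(rp_prefixes)) for s in symbols], bool)
    if not mask.any():
        raise ValueError("RP gene set empty after intersection with the matrix")
    return mask


def rp_fraction(raw_counts: CountMatrix, rp_mask) -> pd.Series:
    """Per-cell RP fraction computed on RAW counts."""
    rp_mask = np.asarray(rp_mask, bool)
    if len(rp_mask) != raw_counts.n_genes:
        raise ValueError("RP mask not aligned to matrix genes")
    X = raw_counts.values.tocsc()
    totals = np.asarray(X.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = raw_counts.cell_barcodes[totals == 0][0]
        raise ValueError(f"zero-total cell: {bad}")
    rp = np.asarray(X[rp_mask].sum(axis=0)).ravel()
    return pd.Series(rp / totals, index=pd.Index(raw_counts.cell_barcodes,
                                                 name="barcode"),
                     name="rp_fraction")


def pseudotime_shift_test(pseudotime, clusters, method: str = "mannwhitney",
                          min_cells: int = 20) -> pd.DataFrame:
    """Two-sided distribution-shift test per cluster pair within one sample."""
    pt = np.asarray(pseudotime, float)
    labels = np.asarray(clusters, dtype=object)
    uniq = [u for u in pd.unique(labels) if not pd.isna(u)]
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    rows = []
    for a, b in combinations(uniq, 2):
        xa, xb = pt[labels == a], pt[labels == b]
        if len(xa) < min_cells or len(xb) < min_cells:
            raise ValueError(f"cluster pair ({a}, {b}) below {min_cells} cells")
        if np.unique(np.concatenate([xa, xb])).size == 1:
            stat, p = np.nan, 1.0  # all tied: no evidence of a shift
        elif method == "mannwhitney":
            stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        elif method == "ks":
            stat, p = stats.ks_2samp(xa, xb)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"cluster_a": a, "cluster_b": b, "statistic": stat,
                     "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def pseudotime_rp_correlation(pseudotime, rp_fractions) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected p) between pseudotime and RP
    fraction; (nan, nan) when either vector is constant."""
    pt = np.asarray(pseudotime, float)
    rp = np.asarray(rp_fractions, float)
    if len(pt) < 10:
        raise ValueError("need at least 10 cells")
    if np.unique(pt).size == 1 or np.unique(rp).size == 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(pt, rp)
    return float(rho), float(p)


def rp_expression_heatmap_order(rp_expr, barcodes) -> np.ndarray:
    """Cell order by mean normalized RP expression, high to low; ties break
    by barcode lexicographically."""
    X = np.asarray(rp_expr.todense()) if hasattr(rp_expr, "todense") \
        else np.asarray(rp_expr, float)
    means = X.mean(axis=0)
    barcodes = np.asarray(barcodes, dtype=object).astype(str)
    order = np.lexsort((barcodes, -means))
    return order
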