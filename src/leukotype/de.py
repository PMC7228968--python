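"""Two-part (hurdle) differential expression between clusters and
hypergeometric gene-set over-representation.

Single-cell expression is zero-inflated, so each gene is tested in two
parts: a Fisher exact test on the detection (expressed vs not) 2x2 table,
and a two-sided Wilcoxon rank-sum test on the positive log-normalized
values; the two p-values are combined with Fisher's method. log_fc is the
natural-log mean difference of log-normalized expression (group A minus
group B). Benjamini-Hochberg correction is applied per comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


def _dense_rows(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.todense())
    return np.asarray(values, float)


def hurdle_de_test(expr_a, expr_b, gene_symbols=None) -> pd.DataFrame:
    """Hurdle test per gene between two cell groups.

    Parameters
    ----------
    expr_a, expr_b : array or sparse, genes x cells
        Log-normalized expression of the two groups (same gene order).

    Returns
    -------
    DataFrame with gene, log_fc, p_value, q_value, pct_expressed_a/b.
    """
    A = _dense_rows(expr_a)
    B = _dense_rows(expr_b)
    if A.shape[0] != B.shape[0]:
        raise ValueError("gene dimensions differ between groups")
    if A.shape[1] < 3 or B.shape[1] < 3:
        raise ValueError("need at least 3 cells per group")
    n_genes = A.shape[0]
    if gene_symbols is None:
        gene_symbols = [f"gene{i}" for i in range(n_genes)]

    p = np.ones(n_genes)
    log_fc = np.zeros(n_genes)
    pct_a = np.zeros(n_genes)
    pct_b = np.zeros(n_genes)
    for g in range(n_genes):
        a, b = A[g], B[g]
        pos_a, pos_b = a > 0, b > 0
        ka, kb = int(pos_a.sum()), int(pos_b.sum())
        pct_a[g] = ka / len(a)
        pct_b[g] = kb / len(b)
        if ka == 0 and kb == 0:
            continue  # p = 1, log_fc = 0 by construction
        log_fc[g] = a.mean() - b.mean()
        parts = []
        table = np.array([[ka, len(a) - ka], [kb, len(b) - kb]])
        if table[:, 0].sum() and table[:, 1].sum():
            parts.append(stats.fisher_exact(table, alternative="two-sided")[1])
        if ka > 0 and kb > 0:
            parts.append(stats.mannwhitneyu(a[pos_a], b[pos_b],
                                            alternative="two-sided")[1])
        if not parts:
            # detected everywhere in both groups with identical margins,
            # or positives only in one group -> detection table is the test
            parts = [stats.fisher_exact(table, alternative="two-sided")[1]]
        if len(parts) == 1:
            p[g] = parts[0]
        else:
            p[g] = stats.combine_pvalues(parts, method="fisher")[1]
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": np.asarray(gene_symbols, dtype=object),
        "log_fc": log_fc, "p_value": p, "q_value": q,
        "pct_expressed_a": pct_a, "pct_expressed_b": pct_b,
    })


def de_between_clusters(expr: ExpressionMatrix, labels, cluster_a, cluster_b
                        ) -> pd.DataFrame:
    """Convenience wrapper: hurdle test between two labelled cell groups."""
    labels = np.asarray(labels, dtype=object)
    mask_a = labels == cluster_a
    mask_b = labels == cluster_b
    X = expr.values
    A = X[:, mask_a] if not sp.issparse(X) else X.tocsc()[:, mask_a]
    B = X[:, mask_b] if not sp.issparse(X) else X.tocsc()[:, mask_b]
    return hurdle_de_test(A, B, gene_symbols=expr.gene_symbols)


def top_de_genes(results: pd.DataFrame, n: int = 100) -> list[str]:
    """Top genes by adjusted p-value, ties broken by |log_fc| descending."""
    if len(results) == 0:
        raise ValueError("empty DE results")
    ranked = results.assign(_abs_lfc=results["log_fc"].abs()) \
        .sort_values(["q_value", "_abs_lfc", "gene"],
                     ascending=[True, False, True], kind="stable")
    return ranked["gene"].head(n).tolist()


def geneset_overrepresentation(de_genes, universe, genesets: dict[str, list[str]]
                               ) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    p = P(X >= overlap) with X ~ Hypergeom(|universe|, |set & universe|,
    |de_genes|); BH correction across the tested sets. Sets with no overlap
    with the universe are skipped with a warning.
    """
    import warnings

    universe = set(universe)
    de = set(de_genes)
    if not de <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    rows = []
    for name, members in genesets.items():
        in_universe = set(members) & universe
        if not in_universe:
            warnings.warn(f"gene set {name} has no overlap with the universe; skipped")
            continue
        overlap = len(in_universe & de)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(in_universe),
                                     len(de)))
        rows.append({"set": name, "set_size": len(in_universe),
                     "overlap": overlap, "p_value": min(p, 1.0)})
    result = pd.DataFrame(rows)
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result
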