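"""Per-cell somatic mutant-allele enrichment in transcriptional clusters.

Allele calls are tri-state (no coverage / ref / alt) per variant and cell.
Variants with more than 0.1% of a sample's cells carrying the mutant allele
are testable; for each testable variant and cluster pair, a 2x2 Fisher exact
test compares alt-carriers vs covered non-carriers between the clusters,
with BH correction across all tests in the sample. Cells without coverage
are excluded from the contingency table.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import ALT, NO_COVERAGE, AlleleCallMatrix


def summarize_call_coverage(calls: AlleleCallMatrix) -> pd.DataFrame:
    """Per-variant tallies: cells with any call, cells with the alt allele."""
    covered = (calls.codes != NO_COVERAGE).sum(axis=1)
    alt = (calls.codes == ALT).sum(axis=1)
    return pd.DataFrame(
        {"covered_cells": covered.astype(int), "alt_cells": alt.astype(int)},
        index=pd.Index(calls.variant_ids, name="variant_id"),
    )


def filter_testable_mutations(calls: AlleleCallMatrix,
                              min_alt_frac: float = 0.001) -> list[str]:
    """Variants with alt-carrying cells strictly above ``min_alt_frac`` of the
    sample's cells, evaluated per sample."""
    testable: list[str] = []
    samples = np.asarray(calls.sample_of_cell, dtype=object)
    for v in range(calls.n_variants):
        ok = False
        for s in pd.unique(samples):
            in_s = samples == s
            n_alt = int((calls.codes[v, in_s] == ALT).sum())
            if n_alt / int(in_s.sum()) > min_alt_frac:
                ok = True
                break
        if ok:
            testable.append(str(calls.variant_ids[v]))
    return testable


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    p sums hypergeometric probabilities of tables (at fixed margins) as or
    less probable than the observed one; the odds ratio is the sample
    ad/bc, infinite when bc = 0 and ad > 0, nan for an all-zero table.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or (t < 0).any() or (t != np.round(t)).any():
            raise ValueError("table must be 2x2 non-negative integers")
        t = t.astype(int)
    if t.sum() == 0:
        return float("nan"), 1.0
    res = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = a * d / (b * c)
    return float(odds), float(res[1])


def cluster_enrichment(calls: AlleleCallMatrix, clusters,
                       min_alt_frac: float = 0.001) -> pd.DataFrame:
    """Per-variant mutant-allele enrichment between cluster pairs.

    Only covered cells enter the 2x2 table (alt-carrier vs covered
    non-carrier x cluster A vs B). BH correction spans all tested
    (variant, pair) combinations within the sample.
    """
    labels = np.asarray(clusters, dtype=object)
    if len(labels) != calls.n_cells:
        raise ValueError("cluster labels not aligned to cells")
    uniq = [u for u in pd.unique(labels) if not pd.isna(u)]
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    testable = set(filter_testable_mutations(calls, min_alt_frac))

    rows = []
    for v in range(calls.n_variants):
        vid = str(calls.variant_ids[v])
        if vid not in testable:
            continue
        code = calls.codes[v]
        for a, b in combinations(uniq, 2):
            in_a = (labels == a) & (code != NO_COVERAGE)
            in_b = (labels == b) & (code != NO_COVERAGE)
            table = np.array([
                [int((code[in_a] == ALT).sum()), int((code[in_b] == ALT).sum())],
                [int((code[in_a] != ALT).sum()), int((code[in_b] != ALT).sum())],
            ])
            odds, p = fisher_exact_2x2(table)
            rows.append({
                "variant_id": vid, "cluster_a": a, "cluster_b": b,
                "alt_a": table[0, 0], "alt_b": table[0, 1],
                "nonalt_a": table[1, 0], "nonalt_b": table[1, 1],
                "odds_ratio": odds, "p_value": p,
            })
    out = pd.DataFrame(rows, columns=["variant_id", "cluster_a", "cluster_b",
                                      "alt_a", "alt_b", "nonalt_a", "nonalt_b",
                                      "odds_ratio", "p_value"])
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
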