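"""Metacell construction and windowed relative-expression CNV profiling.

Each transcriptional cluster is summarized as thirty equal-sized metacells
(gene-wise sums of raw counts over a seeded random balanced split of its
cells). CNV profiles are windowed log2 expression ratios against healthy
control metacells: library-size normalize, log2(1 + x), subtract the
control-metacell per-gene mean, smooth with a centered moving average over
101 genes within each chromosome (truncated at the edges), and re-center
each metacell by its genome-wide median. Segments are maximal runs of at
least ``min_genes`` genes beyond a threshold, promoted to cluster-level
calls when at least half the cluster's metacells agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountMatrix


@dataclass
class MetacellMatrix:
    """Summed raw counts, genes x metacells."""

    values: np.ndarray
    gene_symbols: np.ndarray
    origin: pd.DataFrame  # per metacell: sample, cluster, index
    member_cells: list

    @property
    def n_metacells(self) -> int:
        return self.values.shape[1]


def make_metacells(counts: CountMatrix, labels, n_metacells: int = 30,
                   seed: int = 0) -> MetacellMatrix:
    """Seeded random balanced split of each cluster into ``n_metacells``
    groups (sizes differ by at most 1), summed gene-wise."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) != counts.n_cells:
        raise ValueError("labels not aligned to cells")
    rng = np.random.default_rng(seed)
    X = counts.values.tocsc()
    cols, origin, members = [], [], []
    for cluster in pd.unique(labels[~pd.isna(labels)]):
        idx = np.flatnonzero(labels.astype(str) == str(cluster))
        if len(idx) < n_metacells:
            raise ValueError(f"cluster {cluster} has {len(idx)} cells, fewer than "
                             f"{n_metacells} metacells")
        idx = rng.permutation(idx)
        for k, group in enumerate(np.array_split(idx, n_metacells)):
            cols.append(np.asarray(X[:, group].sum(axis=1)).ravel())
            sample = counts.sample_of_cell[group[0]]
            origin.append({"sample": sample, "cluster": cluster, "index": k})
            members.append(list(counts.cell_barcodes[group]))
    return MetacellMatrix(
        values=np.column_stack(cols),
        gene_symbols=counts.gene_symbols,
        origin=pd.DataFrame(origin),
        member_cells=members,
    )


def _normalize_log2(values: np.ndarray) -> np.ndarray:
    totals = values.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("metacell with zero total counts")
    return np.log2(1.0 + values / totals * 1e5)


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (shorter windows at the
    chromosome ends)."""
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    n = len(v)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


@dataclass
class CNVProfile:
    """Smoothed log2 ratios (ordered genes x metacells) plus gene annotation."""

    values: np.ndarray
    genes: pd.DataFrame  # gene_symbol, chromosome, start (profile order)
    origin: pd.DataFrame


class CNVProfiler(BaseEstimator, TransformerMixin):
    """Windowed log2-ratio CNV profiling against control metacells.

    Parameters
    ----------
    gene_order : DataFrame
        Columns gene_symbol, chromosome, start; defines the genomic order.
    window : int
        Odd moving-average window in genes (default 101).
    """

    def __init__(self, gene_order: pd.DataFrame = None, window: int = 101):
        self.gene_order = gene_order
        self.window = window

    def fit(self, control: MetacellMatrix, y=None):
        if self.window % 2 == 0:
            raise ValueError(f"window must be odd, got {self.window}")
        if self.gene_order is None:
            raise ValueError("gene_order annotation is required")
        ann = self.gene_order
        annotated = set(ann["gene_symbol"])
        matrix_genes = list(control.gene_symbols)
        dropped = [g for g in matrix_genes if g not in annotated]
        if dropped:
            import warnings
            warnings.warn(f"{len(dropped)} genes lack coordinates; excluded")
        order = ann[ann["gene_symbol"].isin(set(matrix_genes))] \
            .sort_values(["chromosome", "start"], kind="stable")
        self.genes_ = order[["gene_symbol", "chromosome", "start"]] \
            .reset_index(drop=True)
        pos = {g: i for i, g in enumerate(matrix_genes)}
        self._row_index = np.array([pos[g] for g in self.genes_["gene_symbol"]])
        ctrl = _normalize_log2(control.values.astype(float))[self._row_index]
        self.control_mean_ = ctrl.mean(axis=1)
        return self

    def transform(self, test: MetacellMatrix) -> CNVProfile:
        X = _normalize_log2(test.values.astype(float))[self._row_index]
        ratio = X - self.control_mean_[:, None]
        smoothed = np.empty_like(ratio)
        chroms = self.genes_["chromosome"].to_numpy()
        for chrom in pd.unique(chroms):
            rows = np.flatnonzero(chroms == chrom)
            for j in range(ratio.shape[1]):
                smoothed[rows, j] = _moving_average(ratio[rows, j], self.window)
        smoothed -= np.median(smoothed, axis=0, keepdims=True)
        return CNVProfile(values=smoothed, genes=self.genes_.copy(),
                          origin=test.origin.copy())


def cnv_relative_profile(test: MetacellMatrix, control: MetacellMatrix,
                         gene_order: pd.DataFrame, window: int = 101
                         ) -> CNVProfile:
    return CNVProfiler(gene_order=gene_order, window=window).fit(control) \
        .transform(test)


def _runs(mask: np.ndarray, min_genes: int):
    """Maximal runs of True with length >= min_genes as (start, end) spans."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_genes:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


def call_cnv_segments(profile: CNVProfile, gain_thresh: float = 0.2,
                      loss_thresh: float = -0.2, min_genes: int = 50,
                      min_metacell_frac: float = 0.5) -> pd.DataFrame:
    """Cluster-level CNV segment calls.

    Per metacell, segments are maximal runs of >= ``min_genes`` consecutive
    genes (within a chromosome) all above ``gain_thresh`` or below
    ``loss_thresh``. A cluster-level segment is a run of genes covered by
    same-direction metacell segments in at least ``min_metacell_frac`` of
    the cluster's metacells.
    """
    genes = profile.genes
    chroms = genes["chromosome"].to_numpy()
    rows = []
    for (sample, cluster), grp in profile.origin.groupby(["sample", "cluster"],
                                                         sort=False):
        cols = grp.index.to_numpy()
        votes = {"gain": np.zeros(len(genes)), "loss": np.zeros(len(genes))}
        for j in cols:
            v = profile.values[:, j]
            for direction, mask in (("gain", v > gain_thresh),
                                    ("loss", v < loss_thresh)):
                for chrom in pd.unique(chroms):
                    r = np.flatnonzero(chroms == chrom)
                    for lo, hi in _runs(mask[r], min_genes):
                        votes[direction][r[lo:hi]] += 1
        for direction in ("gain", "loss"):
            called = votes[direction] >= min_metacell_frac * len(cols)
            for chrom in pd.unique(chroms):
                r = np.flatnonzero(chroms == chrom)
                for lo, hi in _runs(called[r], min_genes):
                    span = r[lo:hi]
                    rows.append({
                        "sample": sample, "cluster": cluster,
                        "chromosome": chrom, "direction": direction,
                        "start_gene": genes["gene_symbol"].iloc[span[0]],
                        "end_gene": genes["gene_symbol"].iloc[span[-1]],
                        "gene_index_start": int(span[0]),
                        "gene_index_end": int(span[-1] + 1),
                        "n_genes": int(len(span)),
                        "mean_ratio": float(
                            profile.values[span][:, cols].mean()),
                    })
    return pd.DataFrame(rows, columns=[
        "sample", "cluster", "chromosome", "direction", "start_gene",
        "end_gene", "gene_index_start", "gene_index_end", "n_genes",
        "mean_ratio"])
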