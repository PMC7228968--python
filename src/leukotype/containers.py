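"""Core in-memory containers shared across the pipeline.

All matrices are oriented genes x cells, matching the 10x MatrixMarket
convention in which features are rows and barcodes columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Sparse raw UMI counts, genes x cells.

    Attributes
    ----------
    values : scipy.sparse.csr_matrix
        Non-negative integer counts, shape (n_genes, n_cells).
    gene_ids, gene_symbols : ndarray of str
        Per-gene identifiers; ``gene_ids`` must be unique.
    cell_barcodes : ndarray of str
        Unique per-cell barcodes.
    sample_of_cell : ndarray of str
        Sample label per cell.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    cell_barcodes: np.ndarray
    sample_of_cell: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        self.sample_of_cell = np.asarray(self.sample_of_cell, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.gene_symbols) != n_genes:
            raise ValueError("gene annotation length does not match matrix rows")
        if len(self.cell_barcodes) != n_cells or len(self.sample_of_cell) != n_cells:
            raise ValueError("cell annotation length does not match matrix columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_barcodes)) != n_cells:
            raise ValueError("cell_barcodes must be unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Return a new CountMatrix restricted to the masked genes/cells."""
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            values=self.values[gm][:, cm].tocsr(),
            gene_ids=self.gene_ids[gm],
            gene_symbols=self.gene_symbols[gm],
            cell_barcodes=self.cell_barcodes[cm],
            sample_of_cell=self.sample_of_cell[cm],
        )


@dataclass
class ExpressionMatrix:
    """Processed expression values (genes x cells) with transform provenance."""

    values: object  # scipy sparse or ndarray, genes x cells
    gene_symbols: np.ndarray
    cell_barcodes: np.ndarray
    sample_of_cell: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        self.sample_of_cell = np.asarray(self.sample_of_cell, dtype=object)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def with_values(self, values, transform: str) -> "ExpressionMatrix":
        return replace(self, values=values, provenance=self.provenance + [transform])

    def subset_genes(self, gene_mask) -> "ExpressionMatrix":
        gm = np.asarray(gene_mask)
        return replace(self, values=self.values[gm], gene_symbols=self.gene_symbols[gm])

    def subset_cells(self, cell_mask) -> "ExpressionMatrix":
        cm = np.asarray(cell_mask)
        return replace(
            self,
            values=self.values[:, cm],
            cell_barcodes=self.cell_barcodes[cm],
            sample_of_cell=self.sample_of_cell[cm],
        )


def make_cell_table(barcodes, sample_of_cell) -> pd.DataFrame:
    """Empty per-cell annotation table indexed by barcode."""
    return pd.DataFrame(
        {
            "sample": np.asarray(sample_of_cell, dtype=object),
            "n_umi": np.nan,
            "n_genes_detected": np.nan,
            "mito_fraction": np.nan,
            "s_score": np.nan,
            "g2m_score": np.nan,
            "phase": pd.Series([None] * len(barcodes), dtype=object),
            "cell_type": pd.Series([None] * len(barcodes), dtype=object),
            "cluster": pd.Series([None] * len(barcodes), dtype=object),
            "pseudotime": np.nan,
            "rp_fraction": np.nan,
        },
        index=pd.Index(np.asarray(barcodes, dtype=object), name="barcode"),
    )
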