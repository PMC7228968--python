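"""QC statistics against brute-force oracles, filter threshold semantics,
normalization, cycle scoring, covariate regression and pooled HVG rules."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from leukotype.containers import CountMatrix, ExpressionMatrix
from leukotype.qc import (EmptyResultError, compute_cell_qc,
                          filter_cells_genes, gene_flags, normalize_log,
                          regress_covariates, score_cell_cycle,
                          select_variable_genes_pooled)


def _matrix(values, symbols=None):
    values = np.asarray(values)
    n_genes, n_cells = values.shape
    symbols = symbols or [f"S{i}" for i in range(n_genes)]
    return CountMatrix(sp.csr_matrix(values), [f"G{i}" for i in range(n_genes)],
                       symbols, [f"BC{i}" for i in range(n_cells)],
                       ["s1"] * n_cells)


class TestCellQC:
    def test_mito_fraction_arithmetic(self):
        cm = _matrix([[5], [5]], symbols=["geneA", "MT-geneB"])
        qc = compute_cell_qc(cm, gene_flags(cm.gene_symbols))
        assert qc["n_umi"].iloc[0] == 10
        assert qc["mito_fraction"].iloc[0] == 0.5

    def test_all_zero_cell(self):
        cm = _matrix([[1, 0], [2, 0]])
        qc = compute_cell_qc(cm, gene_flags(cm.gene_symbols))
        assert qc["n_umi"].iloc[1] == 0
        assert qc["n_genes_detected"].iloc[1] == 0
        assert qc["mito_fraction"].iloc[1] == 0.0
        assert qc["flag_zero_count"].iloc[1]

    def test_matches_brute_force_on_random_matrix(self, rng):
        values = rng.poisson(1.0, size=(20, 30))
        cm = _matrix(values)
        qc = compute_cell_qc(cm, gene_flags(cm.gene_symbols))
        for j in range(30):  # brute-force per-cell enumeration
            assert qc["n_umi"].iloc[j] == values[:, j].sum()
            assert qc["n_genes_detected"].iloc[j] == (values[:, j] > 0).sum()


class TestFilter:
    def test_gene_below_min_cells_removed(self):
        values = np.ones((2, 5), int)
        values[1, 0] = 0  # gene 1 expressed in 4 of 5 cells
        cm = _matrix(values)
        out = filter_cells_genes(cm, min_cells_per_gene=5, min_genes_per_cell=0,
                                 max_mito=1.0)
        assert list(out.gene_ids) == ["G0"]

    def test_mito_exactly_at_threshold_removed(self):
        # cell 0: mito fraction exactly 0.08; cell 1 below
        values = np.array([[92, 99], [8, 1]])
        cm = _matrix(values, symbols=["geneA", "MT-geneB"])
        out = filter_cells_genes(cm, min_cells_per_gene=0, min_genes_per_cell=0,
                                 max_mito=0.08)
        assert list(out.cell_barcodes) == ["BC1"]

    def test_identity_thresholds_keep_everything(self, rng):
        cm = _matrix(rng.poisson(2.0, size=(10, 8)) + 1)
        out = filter_cells_genes(cm, min_cells_per_gene=0, min_genes_per_cell=0,
                                 max_mito=1.0)
        assert out.values.shape == cm.values.shape

    def test_all_cells_removed_is_explicit(self):
        cm = _matrix(np.ones((3, 3), int))
        with pytest.raises(EmptyResultError):
            filter_cells_genes(cm, min_cells_per_gene=0,
                               min_genes_per_cell=100, max_mito=1.0)

    def test_cell_order_permutation_equivariance(self, rng):
        values = rng.poisson(3.0, size=(15, 12))
        cm = _matrix(values)
        perm = rng.permutation(12)
        cm_p = cm.subset(cell_mask=np.ones(12, bool))
        cm_p = CountMatrix(cm.values[:, perm], cm.gene_ids, cm.gene_symbols,
                           cm.cell_barcodes[perm], cm.sample_of_cell[perm])
        out = filter_cells_genes(cm, min_cells_per_gene=2,
                                 min_genes_per_cell=3, max_mito=1.0)
        out_p = filter_cells_genes(cm_p, min_cells_per_gene=2,
                                   min_genes_per_cell=3, max_mito=1.0)
        assert set(out.cell_barcodes) == set(out_p.cell_barcodes)
        a = pd.DataFrame(out.values.toarray(), columns=out.cell_barcodes)
        b = pd.DataFrame(out_p.values.toarray(), columns=out_p.cell_barcodes)
        assert a[sorted(a.columns)].equals(b[sorted(b.columns)])


class TestNormalize:
    def test_closed_forms(self):
        cm = _matrix([[100], [0]])
        expr = normalize_log(cm, scale_factor=10_000)
        dense = expr.dense()
        assert dense[1, 0] == 0.0
        assert np.isclose(dense[0, 0], np.log(10001))

    def test_matches_per_entry_formula(self, rng):
        values = rng.poisson(2.0, size=(5, 4)) + 1
        expr = normalize_log(_matrix(values), scale_factor=1000)
        expected = np.log1p(values * 1000 / values.sum(axis=0, keepdims=True))
        assert np.allclose(expr.dense(), expected)

    def test_monotone_within_cell(self, rng):
        values = rng.poisson(5.0, size=(30, 3)) + 1
        dense = normalize_log(_matrix(values)).dense()
        for j in range(3):
            order = np.argsort(values[:, j], kind="stable")
            assert (np.diff(dense[order, j]) >= -1e-12).all()

    def test_zero_total_cell_named(self):
        cm = _matrix([[1, 0]])
        with pytest.raises(ValueError, match="BC1"):
            normalize_log(cm)


class TestCellCycle:
    def _expr(self, values, symbols):
        values = np.asarray(values, float)
        return ExpressionMatrix(values, symbols,
                                [f"BC{i}" for i in range(values.shape[1])],
                                ["s1"] * values.shape[1], ["norm"])

    def test_zero_cell_is_g1(self, rng):
        values = rng.lognormal(0, 1, size=(30, 10))
        values[:, 0] = 0.0
        symbols = [f"S{i}" for i in range(30)]
        out = score_cell_cycle(self._expr(values, symbols), symbols[:5],
                               symbols[5:10], n_ctrl=10, seed=0)
        assert out["s_score"].iloc[0] == 0.0
        assert out["g2m_score"].iloc[0] == 0.0
        assert out["phase"].iloc[0] == "G1"

    def test_s_overexpression_called_s(self, rng):
        values = rng.lognormal(0, 0.2, size=(30, 20))
        symbols = [f"S{i}" for i in range(30)]
        values[:5, 0] += 10.0  # cell 0 over-expresses only the S set
        out = score_cell_cycle(self._expr(values, symbols), symbols[:5],
                               symbols[5:10], n_ctrl=10, seed=0)
        assert out["s_score"].iloc[0] > 0
        assert out["phase"].iloc[0] == "S"

    def test_seeded_determinism(self, rng):
        values = rng.lognormal(0, 1, size=(40, 15))
        symbols = [f"S{i}" for i in range(40)]
        e = self._expr(values, symbols)
        a = score_cell_cycle(e, symbols[:6], symbols[6:12], seed=7)
        b = score_cell_cycle(e, symbols[:6], symbols[6:12], seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_intersection_rejected(self, rng):
        values = rng.lognormal(0, 1, size=(10, 5))
        e = self._expr(values, [f"S{i}" for i in range(10)])
        with pytest.raises(ValueError):
            score_cell_cycle(e, ["NOPE1"], ["NOPE2"])


class TestRegression:
    def _expr(self, values):
        values = np.asarray(values, float)
        return ExpressionMatrix(values, [f"S{i}" for i in range(values.shape[0])],
                                [f"BC{i}" for i in range(values.shape[1])],
                                ["s1"] * values.shape[1], ["norm"])

    def test_empty_covariates_center(self, rng):
        values = rng.normal(size=(4, 10))
        out = regress_covariates(self._expr(values), None)
        assert np.allclose(out.dense(), values - values.mean(axis=1, keepdims=True))

    def test_residual_orthogonality(self, rng):
        values = rng.normal(size=(6, 50))
        covs = pd.DataFrame(rng.normal(size=(50, 3)),
                            columns=["n_umi", "mito", "s"])
        resid = regress_covariates(self._expr(values), covs).dense()
        for c in covs.columns:
            x = covs[c] - covs[c].mean()
            for g in range(6):
                assert abs(np.corrcoef(resid[g], x)[0, 1]) < 1e-8

    def test_exact_linear_fit_zero_residuals(self):
        n_umi = np.array([1.0, 2, 3, 4, 5, 6])
        values = (2.5 * n_umi + 1.0)[None, :]
        resid = regress_covariates(self._expr(values),
                                   pd.DataFrame({"n_umi": n_umi})).dense()
        assert np.abs(resid).max() < 1e-8

    def test_collinear_covariates_named(self, rng):
        values = rng.normal(size=(3, 20))
        x = rng.normal(size=20)
        covs = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank-deficient"):
            regress_covariates(self._expr(values), covs)


class TestPooledHVG:
    def _expr(self, values, symbols, sample):
        return ExpressionMatrix(np.asarray(values, float), symbols,
                                [f"{sample}-BC{i}" for i in range(values.shape[1])],
                                [sample] * values.shape[1], ["norm"])

    def test_identical_samples_agree_with_single_top_list(self, rng):
        values = rng.lognormal(0, 1, size=(50, 30))
        symbols = [f"S{i}" for i in range(50)]
        e1 = self._expr(values, symbols, "a")
        e2 = self._expr(values, symbols, "b")
        pooled = select_variable_genes_pooled({"a": e1, "b": e2},
                                              top_n_per_sample=10)
        single = select_variable_genes_pooled({"a": e1, "b": e1},
                                              top_n_per_sample=10)
        assert set(pooled) == set(single) and len(pooled) == 10

    def test_gene_variable_in_one_of_three_excluded(self, rng):
        base = rng.lognormal(0, 0.1, size=(40, 30))
        symbols = [f"S{i}" for i in range(40)]
        variant = base.copy()
        variant[0] = rng.lognormal(0, 3, size=30)  # S0 hypervariable in one sample
        exprs = {"a": self._expr(variant, symbols, "a"),
                 "b": self._expr(base, symbols, "b"),
                 "c": self._expr(base, symbols, "c")}
        pooled = select_variable_genes_pooled(exprs, top_n_per_sample=5,
                                              min_samples=2)
        top_a = select_variable_genes_pooled(
            {"a": exprs["a"], "a2": exprs["a"]}, top_n_per_sample=5)
        assert "S0" in top_a
        assert "S0" not in pooled

    def test_disjoint_planted_genes_give_empty_pool(self, rng):
        symbols = [f"S{i}" for i in range(30)]
        levels = np.linspace(0.3, 3.0, 30)
        exprs = {}
        for k, sample in enumerate(("a", "b", "c")):
            # planted variable genes interleave with near-constant genes so
            # every mean bin mixes both; plantings are disjoint across samples
            v = levels[:, None] * (1.0 + rng.normal(0, 0.02, size=(30, 300)))
            planted = np.arange(k, 30, 3)
            v[planted] = levels[planted, None] * rng.lognormal(
                -0.5, 1.0, size=(10, 300))
            exprs[sample] = self._expr(v, symbols, sample)
        pooled = select_variable_genes_pooled(exprs, top_n_per_sample=10,
                                              min_samples=2)
        assert pooled == []
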