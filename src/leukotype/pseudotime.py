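"""Maturation-curve pseudotime and the supervised developmental-state
regressor.

The healthy maturation spectrum is modelled as a local-regression (LOWESS)
fit of the second embedding coordinate on the first; cells are projected
onto the densely sampled fit line at the closest Euclidean distance,
projection outliers beyond mean + 3 SD are discarded, and arc-length
positions are min-max scaled to [0, 1] as pseudotime (0 at the stem-like
end). A one-hidden-layer network (15 sigmoid nodes, linear output) is then
trained to regress pseudotime on standardized expression of the variable
genes, validated with a hundred random 70/30 splits, and used to transfer
developmental states to leukemia cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.model_selection import ShuffleSplit
from sklearn.neural_network import MLPRegressor
from statsmodels.nonparametric.smoothers_lowess import lowess


class CurveFitError(ValueError):
    """Raised when the maturation spectrum cannot be fitted."""


class MaturationCurve(BaseEstimator, TransformerMixin):
    """LOWESS maturation curve in a 2-D embedding.

    Parameters
    ----------
    span : float
        LOWESS smoothing fraction (default 0.5).
    n_samples : int
        Number of dense sample points along the fitted line (default 500).

    Attributes
    ----------
    sample_points_ : ndarray (n_samples, 2)
        Curve samples ordered from the stem-like end.
    arc_length_ : ndarray
        Cumulative arc length per sample point, starting at 0.
    """

    def __init__(self, span: float = 0.5, n_samples: int = 500):
        self.span = span
        self.n_samples = n_samples

    def fit(self, coords, stem_mask=None, y=None):
        """Fit the curve on spectrum cells.

        ``coords`` is (n_cells, 2); ``stem_mask`` marks the stem-like
        (CD34+-like) cells used to orient pseudotime 0.
        """
        coords = np.asarray(coords, float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be (n_cells, 2)")
        if coords.shape[0] < 10:
            raise CurveFitError(f"need >= 10 spectrum cells, got {coords.shape[0]}")
        x, y2 = coords[:, 0], coords[:, 1]
        x_range = x.max() - x.min()
        if x_range <= 1e-12 * max(1.0, np.abs(x).max()):
            raise CurveFitError(
                "degenerate (vertical) spectrum: the first coordinate has no "
                "spread; swap the embedding axes and refit")
        grid = np.linspace(x.min(), x.max(), self.n_samples)
        fitted = lowess(y2, x, frac=self.span, xvals=grid)
        pts = np.column_stack([grid, fitted])

        if stem_mask is not None:
            stem_mask = np.asarray(stem_mask, bool)
            if stem_mask.sum() == 0:
                raise CurveFitError("stem_mask selects no cells")
            centroid = coords[stem_mask].mean(axis=0)
            d_first = np.linalg.norm(pts[0] - centroid)
            d_last = np.linalg.norm(pts[-1] - centroid)
            if d_last < d_first:
                pts = pts[::-1].copy()
        self.sample_points_ = pts
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.arc_length_ = np.concatenate([[0.0], np.cumsum(seg)])
        return self

    def project(self, coords):
        """Closest-point projection: per cell (arc_position, distance).

        Ties between equally distant sample points resolve to the smaller
        arc length.
        """
        coords = np.asarray(coords, float)
        pts = self.sample_points_
        # (n_cells, n_samples) distances; fine at the default 500 samples
        d = np.linalg.norm(coords[:, None, :] - pts[None, :, :], axis=2)
        nearest = d.argmin(axis=1)  # argmin takes the first (smaller arc) tie
        return self.arc_length_[nearest], d[np.arange(len(coords)), nearest]

    def transform(self, coords):
        """Pseudotime in [0, 1] for the given cells (after outlier removal)."""
        arc, dist = self.project(coords)
        keep = remove_projection_outliers(dist)
        pt = np.full(len(coords), np.nan)
        pt[keep] = assign_pseudotime(arc[keep])
        return pt


def fit_maturation_curve(embedding, cell_types, spectrum_types, stem_type,
                         span: float = 0.5, n_samples: int = 500
                         ) -> MaturationCurve:
    """Fit the curve on cells of the named spectrum types, oriented so the
    stem-like type's end is pseudotime 0."""
    cell_types = np.asarray(cell_types, dtype=object)
    in_spectrum = np.isin(cell_types, list(spectrum_types))
    coords = np.asarray(embedding, float)[in_spectrum]
    stem_mask = cell_types[in_spectrum] == stem_type
    return MaturationCurve(span=span, n_samples=n_samples).fit(coords, stem_mask)


def project_cells(curve: MaturationCurve, coords):
    return curve.project(coords)


def remove_projection_outliers(distances, k_sd: float = 3.0) -> np.ndarray:
    """Keep cells with projection distance <= mean + k_sd * SD (one pass)."""
    d = np.asarray(distances, float)
    if len(d) < 2:
        raise ValueError("need at least 2 cells")
    sd = d.std(ddof=1)
    if sd == 0 or not np.isfinite(k_sd):
        return np.ones(len(d), bool)
    return d <= d.mean() + k_sd * sd


def assign_pseudotime(arc_positions) -> np.ndarray:
    """Min-max scale arc positions of the retained cells onto [0, 1]."""
    arc = np.asarray(arc_positions, float)
    lo, hi = arc.min(), arc.max()
    if hi == lo:
        warnings.warn("all arc positions identical; assigning pseudotime 0.5")
        return np.full(len(arc), 0.5)
    return (arc - lo) / (hi - lo)


class PseudotimeRegressor(BaseEstimator, RegressorMixin):
    """Developmental-state regressor: expression -> pseudotime in [0, 1].

    One hidden layer of ``hidden_nodes`` sigmoid units with a linear output,
    L2 weight decay ``alpha``, trained by L-BFGS to tolerance ``tol`` or
    ``max_iter`` iterations. Inputs are standardized per gene with stored
    constants; genes missing at prediction time are imputed as standardized
    zero. Predictions are clipped to [0, 1] (``n_clipped_`` counts them).
    """

    def __init__(self, hidden_nodes: int = 15, alpha: float = 1e-4,
                 max_iter: int = 500, tol: float = 1e-6, seed: int = 0,
                 gene_list=None):
        self.hidden_nodes = hidden_nodes
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.gene_list = gene_list

    def _as_dense(self, X):
        return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)

    def fit(self, X, y):
        """X: cells x genes expression; y: pseudotime in [0, 1]."""
        X = self._as_dense(X)
        y = np.asarray(y, float)
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in training inputs")
        if X.shape[0] < 50:
            raise ValueError(f"need >= 50 training cells, got {X.shape[0]}")
        self.center_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        Z = (X - self.center_) / self.scale_
        self.net_ = MLPRegressor(
            hidden_layer_sizes=(self.hidden_nodes,), activation="logistic",
            solver="lbfgs", alpha=self.alpha, max_iter=self.max_iter,
            tol=self.tol, random_state=self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.net_.fit(Z, y)
        self.n_features_in_ = X.shape[1]
        self.gene_list_ = (None if self.gene_list is None
                           else list(self.gene_list))
        self.training_rmse_ = float(np.sqrt(np.mean(
            (self.predict(X) - y) ** 2)))
        return self

    def predict(self, X, gene_symbols=None):
        """Predict pseudotime; clipped to [0, 1].

        When ``gene_symbols`` names the columns of ``X``, they are aligned to
        the training gene list; missing genes are imputed as standardized 0
        (with a warning), and more than 50% missing is an error.
        """
        X = self._as_dense(X)
        if gene_symbols is not None and self.gene_list_ is not None:
            Z = self._align(X, list(gene_symbols))
        else:
            if X.shape[1] != self.n_features_in_:
                raise ValueError(f"expected {self.n_features_in_} genes, got "
                                 f"{X.shape[1]}")
            Z = (X - self.center_) / self.scale_
        raw = self.net_.predict(Z)
        clipped = np.clip(raw, 0.0, 1.0)
        self.n_clipped_ = int((raw != clipped).sum())
        return clipped

    def _align(self, X, gene_symbols):
        index = {g: i for i, g in enumerate(gene_symbols)}
        Z = np.zeros((X.shape[0], self.n_features_in_))
        missing = 0
        for j, g in enumerate(self.gene_list_):
            i = index.get(g)
            if i is None:
                missing += 1  # standardized 0 imputation
            else:
                Z[:, j] = (X[:, i] - self.center_[j]) / self.scale_[j]
        if missing > self.n_features_in_ / 2:
            raise ValueError(f"{missing}/{self.n_features_in_} model genes missing "
                             "from the input")
        if missing:
            warnings.warn(f"{missing} model genes missing; imputed as standardized 0")
        return Z


@dataclass
class CrossValidationResult:
    split_rmse: np.ndarray
    mean_rmse: float


def crossvalidate_regressor(X, y, n_splits: int = 100, train_frac: float = 0.7,
                            seed: int = 0, **regressor_kwargs
                            ) -> CrossValidationResult:
    """Held-out RMSE over ``n_splits`` independent random train/test splits."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac={train_frac} outside (0, 1)")
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
    y = np.asarray(y, float)
    splitter = ShuffleSplit(n_splits=n_splits, train_size=train_frac,
                            random_state=seed)
    rmses = []
    for split_i, (tr, te) in enumerate(splitter.split(X)):
        model = PseudotimeRegressor(seed=seed + split_i, **regressor_kwargs)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        rmses.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
    rmses = np.asarray(rmses)
    return CrossValidationResult(rmses, float(rmses.mean()))
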