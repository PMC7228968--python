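"""PCA embedding, shared-neighbor graph, Louvain partitions across a
resolution grid, and ARI-consensus solution selection.

The consensus rule: run Louvain at resolutions res_min..res_max (default 0.1
to 3.0, step 0.1, i.e. 30 solutions), compute all pairwise Adjusted Rand
Index values, and keep the solution with the highest mean ARI against the
others (ties to the lowest resolution). Clusters holding less than 10% of a
sample's cells are then discarded.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .containers import ExpressionMatrix


@dataclass
class PartitionSet:
    """Clustering solutions over a resolution grid plus the consensus choice."""

    resolutions: np.ndarray
    partitions: np.ndarray  # (n_resolutions, n_cells) integer labels
    pairwise_ari: np.ndarray
    mean_ari: np.ndarray
    chosen_resolution: float

    @property
    def chosen_labels(self) -> np.ndarray:
        i = int(np.flatnonzero(np.isclose(self.resolutions,
                                          self.chosen_resolution))[0])
        return self.partitions[i]


def pca_embed(expr, n_components: int = 20) -> np.ndarray:
    """Top principal-component scores per cell.

    Accepts an ExpressionMatrix (genes x cells) or an array (cells x
    features). Sign convention: each component's largest-magnitude loading is
    made positive, so recomputation is deterministic.
    """
    if isinstance(expr, ExpressionMatrix):
        X = expr.dense().T
    else:
        X = np.asarray(sp.csr_matrix(expr).todense()) if sp.issparse(expr) \
            else np.asarray(expr, float)
    n_cells, n_feat = X.shape
    if n_components > min(n_cells, n_feat):
        raise ValueError(f"n_components={n_components} exceeds "
                         f"min(cells, genes)={min(n_cells, n_feat)}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores


def knn_graph(scores: np.ndarray, k: int = 20,
              prune: float = 1 / 15) -> ig.Graph:
    """Symmetric k-nearest-neighbor graph with Jaccard shared-neighbor weights.

    Neighborhoods include the cell itself; an undirected edge (i, j) exists
    when j is among i's k nearest (or vice versa) and is weighted by
    |N(i) & N(j)| / |N(i) | N(j)|. Edges with Jaccard weight below ``prune``
    are removed (the shared-nearest-neighbor pruning convention; set 0 to
    keep all edges).
    """
    scores = np.asarray(scores, float)
    n = scores.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)  # includes self at distance 0

    rows = np.repeat(np.arange(n), k + 1)
    A = sp.csr_matrix((np.ones(n * (k + 1)), (rows, idx.ravel())), shape=(n, n))
    A.data[:] = 1.0  # collapse duplicates from tied self-distances
    sizes = np.asarray(A.sum(axis=1)).ravel()

    sym = ((A + A.T) > 0).astype(float)  # knn edge in either direction
    inter = (A @ A.T).multiply(sym).tocoo()
    mask = inter.row < inter.col
    ii, jj, cc = inter.row[mask], inter.col[mask], inter.data[mask]
    union = sizes[ii] + sizes[jj] - cc
    weight = cc / union
    keep = weight >= prune
    ii, jj, weight = ii[keep], jj[keep], weight[keep]
    g = ig.Graph(n=n, edges=list(zip(ii.tolist(), jj.tolist())))
    g.es["weight"] = weight.tolist()
    return g


def louvain_partition(graph: ig.Graph, resolution: float = 1.0, seed: int = 0
                      ) -> np.ndarray:
    """Seeded Louvain community labels at the given resolution."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    ig.set_random_number_generator(random.Random(seed))
    part = graph.community_multilevel(
        weights="weight" if "weight" in graph.es.attributes() else None,
        resolution=resolution)
    return np.asarray(part.membership, dtype=int)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    Returns 1.0 when the partitions are identical, including the degenerate
    0/0 case (both trivial).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 elements")
    return float(adjusted_rand_score(a, b))


def consensus_sweep(graph: ig.Graph, res_min: float = 0.1, res_max: float = 3.0,
                    step: float = 0.1, seed: int = 0) -> PartitionSet:
    """One Louvain partition per grid resolution; consensus by highest mean
    pairwise ARI (self excluded), ties to the lowest resolution."""
    if step <= 0 or res_min > res_max:
        raise ValueError("need step > 0 and res_min <= res_max")
    n_steps = int(round((res_max - res_min) / step))
    resolutions = np.round(res_min + step * np.arange(n_steps + 1), 10)
    if resolutions.size == 0:
        raise ValueError("empty resolution grid")

    # one restart per resolution; independent RNG streams derived from the
    # global seed so agreement between solutions reflects the data, not a
    # shared random vertex-processing order
    parts = np.stack([louvain_partition(graph, float(r), seed=seed + 7919 * i)
                      for i, r in enumerate(resolutions)])
    m = len(resolutions)
    ari = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            ari[i, j] = ari[j, i] = adjusted_rand_index(parts[i], parts[j])
    mean_ari = (ari.sum(axis=1) - np.diag(ari)) / max(m - 1, 1)
    best = mean_ari.max()
    chosen = float(resolutions[np.flatnonzero(mean_ari >= best - 1e-12)[0]])
    return PartitionSet(resolutions, parts, ari, mean_ari, chosen)


def drop_small_clusters(labels, sample_of_cell, min_frac: float = 0.10):
    """Flag clusters holding < ``min_frac`` of their sample's cells.

    The fraction is computed against the sample's pre-filter cell count and
    the rule is strict (exactly 10% is retained). Returns (labels_out,
    keep_mask) where dropped cells carry label None.
    """
    labels = np.asarray(labels, dtype=object)
    samples = np.asarray(sample_of_cell, dtype=object)
    keep = np.ones(len(labels), bool)
    for s in np.unique(samples):
        in_s = samples == s
        total = int(in_s.sum())
        values, counts = np.unique(labels[in_s].astype(str), return_counts=True)
        for v, c in zip(values, counts):
            if c / total < min_frac:
                keep &= ~(in_s & (labels.astype(str) == v))
    out = labels.copy()
    out[~keep] = None
    return out, keep


class ConsensusLouvain(BaseEstimator, ClusterMixin):
    """ARI-consensus Louvain clustering over a resolution grid.

    Parameters
    ----------
    n_components : int
        Principal components used for the neighbor graph (default 20).
    n_neighbors : int
        k of the shared-neighbor graph (default 20).
    res_min, res_max, step : float
        Resolution grid (default 0.1..3.0 by 0.1, i.e. 30 solutions).
    seed : int
        Louvain random seed.

    Attributes
    ----------
    labels_ : ndarray
        Consensus partition labels per cell.
    partition_set_ : PartitionSet
        All partitions, the pairwise ARI matrix and the chosen resolution.
    """

    def __init__(self, n_components: int = 20, n_neighbors: int = 20,
                 res_min: float = 0.1, res_max: float = 3.0, step: float = 0.1,
                 seed: int = 0):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.res_min = res_min
        self.res_max = res_max
        self.step = step
        self.seed = seed

    def fit(self, X, y=None):
        """X: cells x features (expression or embedding)."""
        X = np.asarray(sp.csr_matrix(X).todense()) if sp.issparse(X) \
            else np.asarray(X, float)
        n_comp = min(self.n_components, min(X.shape))
        scores = pca_embed(X, n_components=n_comp)
        graph = knn_graph(scores, k=min(self.n_neighbors, X.shape[0] - 1))
        self.partition_set_ = consensus_sweep(
            graph, self.res_min, self.res_max, self.step, seed=self.seed)
        self.scores_ = scores
        self.labels_ = self.partition_set_.chosen_labels
        self.chosen_resolution_ = self.partition_set_.chosen_resolution
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
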