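"""PCA/graph/Louvain/ARI/consensus contracts, with brute-force oracles for
the ARI pair-counting formula and neighbor lists."""

from itertools import combinations

import igraph as ig
import numpy as np
import pytest

from leukotype.clustering import (ConsensusLouvain, PartitionSet,
                                  adjusted_rand_index, consensus_sweep,
                                  drop_small_clusters, knn_graph,
                                  louvain_partition, pca_embed)


def brute_force_ari(a, b) -> float:
    """Pair-counting ARI over all C(n,2) element pairs (independent oracle)."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    index = ss
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total if total else 0.0
    maximum = 0.5 * ((ss + sd) + (ss + ds))
    if maximum == expected:
        return 1.0
    return (index - expected) / (maximum - expected)


def all_partitions(n):
    """Every partition of range(n) as a label vector (restricted growth)."""
    def rec(prefix, k):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for lab in range(k + 1):
            yield from rec(prefix + [lab], max(k, lab + 1))
    yield from rec([0], 1)


class TestPCA:
    def test_single_axis_variance(self, rng):
        X = np.zeros((50, 5))
        X[:, 2] = rng.normal(0, 3, size=50)
        scores = pca_embed(X, n_components=2)
        total = X.var(axis=0).sum()
        assert scores[:, 0].var() / total >= 0.99

    def test_deterministic_recomputation(self, rng):
        X = rng.normal(size=(40, 10))
        assert np.array_equal(pca_embed(X, 3), pca_embed(X, 3))

    def test_two_gene_closed_form(self):
        # oracle: analytic eigendecomposition of the sample covariance
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(500, 2))
        L = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        X = Z @ L.T
        scores = pca_embed(X, 2)
        Xc = X - X.mean(axis=0)
        _, vecs = np.linalg.eigh(np.cov(Xc.T))
        lead = vecs[:, -1]  # largest-eigenvalue direction
        proj = Xc @ lead
        # scores along component 1 equal the eigenvector projection (up to
        # the fixed sign convention)
        assert (np.abs(scores[:, 0] - proj).max() < 1e-6
                or np.abs(scores[:, 0] + proj).max() < 1e-6)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_embed(rng.normal(size=(5, 3)), n_components=4)


class TestKnnGraph:
    def test_collinear_middle_connected_to_both(self):
        pts = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
        g = knn_graph(pts, k=1)
        nbrs = set(g.neighbors(1))
        assert nbrs == {0, 2}

    def test_separated_blobs_no_cross_edges(self, rng):
        a = rng.normal(0, 0.5, size=(50, 3))
        b = rng.normal(100, 0.5, size=(50, 3))
        g = knn_graph(np.vstack([a, b]), k=5)
        for e in g.es:
            assert (e.source < 50) == (e.target < 50)

    def test_neighbors_match_brute_force(self, rng):
        pts = rng.normal(size=(10, 4))
        g = knn_graph(pts, k=3)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        directed = set()
        for i in range(10):
            order = np.argsort(d[i], kind="stable")
            for j in order[1:4]:
                directed.add((i, int(j)))
        edges = {(e.source, e.target) for e in g.es} \
            | {(e.target, e.source) for e in g.es}
        expected = directed | {(j, i) for i, j in directed}
        assert edges == expected

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            knn_graph(rng.normal(size=(5, 2)), k=5)


def _two_cliques(n=10):
    g = ig.Graph.Full(n) + ig.Graph.Full(n)
    g.es["weight"] = [1.0] * g.ecount()
    return g


class TestLouvain:
    def test_disconnected_cliques_two_communities(self):
        labels = louvain_partition(_two_cliques(), resolution=1.0, seed=0)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_seeded_determinism(self, rng):
        g = knn_graph(rng.normal(size=(60, 4)), k=5)
        a = louvain_partition(g, 1.0, seed=3)
        b = louvain_partition(g, 1.0, seed=3)
        assert np.array_equal(a, b)

    def test_planted_blobs_recovered(self, rng):
        X = np.vstack([rng.normal(c, 1.0, size=(100, 10)) for c in (0, 8, 16)])
        truth = np.repeat([0, 1, 2], 100)
        g = knn_graph(X, k=10)
        labels = louvain_partition(g, 1.0, seed=0)
        assert adjusted_rand_index(labels, truth) >= 0.95

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain_partition(ig.Graph(), 1.0, 0)


class TestARI:
    def test_relabeling_invariance(self):
        assert adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_crossed_partition(self):
        assert np.isclose(adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]), -0.5)
        assert np.isclose(brute_force_ari([1, 1, 2, 2], [1, 2, 1, 2]), -0.5)

    def test_trivial_vs_split(self):
        assert adjusted_rand_index([1, 1, 1, 1], [1, 1, 2, 2]) == 0.0

    def test_both_trivial_convention(self):
        assert adjusted_rand_index([0, 0, 0], [1, 1, 1]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])

    def test_symmetry_and_bound(self, rng):
        for _ in range(50):
            a = rng.integers(0, 4, size=12)
            b = rng.integers(0, 4, size=12)
            ab = adjusted_rand_index(a, b)
            assert ab == adjusted_rand_index(b, a)
            assert ab <= 1.0 + 1e-12

    def test_random_shuffle_mean_near_zero(self, rng):
        labels = rng.integers(0, 5, size=200)
        vals = []
        for _ in range(1000):
            vals.append(adjusted_rand_index(labels, rng.permutation(labels)))
        assert abs(np.mean(vals)) < 0.02


class TestConsensusSweep:
    def test_default_grid_has_30_partitions(self):
        ps = consensus_sweep(_two_cliques(), seed=0)
        assert len(ps.resolutions) == 30
        assert ps.partitions.shape[0] == 30
        assert np.isclose(ps.resolutions[0], 0.1)
        assert np.isclose(ps.resolutions[-1], 3.0)

    def test_two_clique_tie_chooses_lowest_resolution(self):
        ps = consensus_sweep(_two_cliques(), res_min=0.1, res_max=1.0, step=0.1,
                             seed=0)
        assert np.allclose(ps.mean_ari, 1.0)
        assert ps.chosen_resolution == 0.1

    def test_planted_blob_consensus_recovery(self, rng):
        X = np.vstack([rng.normal(c, 1.0, size=(200, 20)) for c in (0, 6, 12)])
        truth = np.repeat([0, 1, 2], 200)
        model = ConsensusLouvain(seed=0).fit(X)
        assert adjusted_rand_index(model.labels_, truth) >= 0.95

    def test_cell_order_invariance(self, rng):
        # well-separated blobs, grid restricted to the regime where the
        # consensus lands on the stable two-community solution
        X = np.vstack([rng.normal(c, 0.5, size=(80, 8)) for c in (0, 10)])
        perm = rng.permutation(160)
        a = ConsensusLouvain(n_components=5, n_neighbors=10, res_max=1.0,
                             seed=0).fit(X)
        b = ConsensusLouvain(n_components=5, n_neighbors=10, res_max=1.0,
                             seed=0).fit(X[perm])
        assert adjusted_rand_index(a.labels_[perm], b.labels_) == 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            consensus_sweep(_two_cliques(), res_min=1.0, res_max=0.5, step=0.1)


class TestDropSmallClusters:
    def test_small_cluster_dropped(self):
        labels = np.array(["a"] * 700 + ["b"] * 250 + ["c"] * 50, dtype=object)
        out, keep = drop_small_clusters(labels, ["s"] * 1000)
        assert keep.sum() == 950
        assert set(out[keep]) == {"a", "b"}

    def test_exactly_ten_percent_retained(self):
        labels = np.array(["a"] * 90 + ["b"] * 10, dtype=object)
        _, keep = drop_small_clusters(labels, ["s"] * 100, min_frac=0.10)
        assert keep.all()

    def test_single_cluster_untouched(self):
        labels = np.array(["a"] * 30, dtype=object)
        _, keep = drop_small_clusters(labels, ["s"] * 30)
        assert keep.all()

    def test_fraction_is_per_sample(self):
        labels = np.array(["a"] * 95 + ["b"] * 5 + ["b"] * 50, dtype=object)
        samples = np.array(["s1"] * 100 + ["s2"] * 50, dtype=object)
        _, keep = drop_small_clusters(labels, samples)
        assert not keep[95:100].any()  # 5% of s1
        assert keep[100:].all()        # 100% of s2
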