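"""DTW distances, kNN digraph construction and topological metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrvnet.graph import (SimilarityGraph, community_clustering, degree_stats,
                          dtw_distance, find_communities, global_clustering,
                          graph_metrics, knn_adjacency, literal_min_match,
                          reciprocity, similarity_matrix, ensemble_metrics)
from hrvnet.simulate import DEFAULT_CLASS_PARAMS, generate_series

from conftest import make_series


def brute_dtw(a, b):
    """Unbanded DP oracle, independent of the production kernel."""
    n, m = len(a), len(b)
    d = np.full((n + 1, m + 1), np.inf)
    d[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d[i, j] = abs(a[i - 1] - b[j - 1]) + min(d[i - 1, j - 1],
                                                     d[i - 1, j], d[i, j - 1])
    return d[n, m]


class TestDTW:
    def test_self_distance_zero(self, rng):
        x = rng.normal(size=30)
        assert dtw_distance(x, x, 1.0) == 0.0

    def test_hand_table(self):
        assert dtw_distance(np.zeros(3), np.ones(3), 1.0) == pytest.approx(3.0)

    def test_pure_time_warp_free(self):
        assert dtw_distance(np.array([0.0, 1, 2]),
                            np.array([0.0, 0, 1, 1, 2, 2]), 1.0) == 0.0

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.3, 2.0, size=rng.integers(2, 11))
        b = rng.uniform(0.3, 2.0, size=rng.integers(2, 11))
        assert dtw_distance(a, b, 1.0) == pytest.approx(brute_dtw(a, b), rel=1e-12)
        # symmetry and the band lower bound
        assert dtw_distance(b, a, 1.0) == pytest.approx(dtw_distance(a, b, 1.0))
        assert dtw_distance(a, b, 0.3) >= dtw_distance(a, b, 1.0) - 1e-12


class TestLiteralMinMatch:
    def test_self_zero_and_symmetry(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=25)
        assert literal_min_match(x, x) == 0.0
        assert literal_min_match(x, y) == pytest.approx(literal_min_match(y, x))
        assert literal_min_match(x, y) >= 0

    def test_hand_evaluation(self):
        # r1 = [0]: nearest in [5, 1] is 1 (cost 1); r2 side: 5 and 1 both
        # match the single 0 at costs 5 and 1 -> total 1 + 6 = 7
        assert literal_min_match(np.array([0.0]), np.array([5.0, 1.0])) == 7.0


class TestSimilarityAndKNN:
    @pytest.fixture()
    def toy_graph(self):
        series = [make_series([0.8] * 20, patient_id="a"),
                  make_series([0.8] * 19 + [0.81], patient_id="b"),
                  make_series([1.5] * 20, patient_id="c")]
        return similarity_matrix(series, mode="dtw")

    def test_identical_series_weight_one(self):
        series = [make_series([0.7, 0.8, 0.9]), make_series([0.7, 0.8, 0.9])]
        g = similarity_matrix(series)
        assert g.weights[0, 1] == 1.0

    def test_weights_decrease_with_distance(self, toy_graph):
        w = toy_graph.weights
        assert w[0, 1] > w[0, 2]

    def test_asymmetric_adjacency_at_k1(self, toy_graph):
        g = knn_adjacency(toy_graph, 1)
        adj = g.adjacency
        assert adj[0, 1] == 1 and adj[1, 0] == 1  # mutual nearest pair
        assert adj[2].sum() == 1  # far node points somewhere
        assert not np.array_equal(adj, adj.T)

    def test_out_degree_is_k_everywhere(self, toy_graph):
        for k in (1, 2):
            g = knn_adjacency(toy_graph, k)
            assert np.all(g.adjacency.sum(axis=1) == k)
            assert g.adjacency.sum(axis=0).mean() == pytest.approx(k)

    def test_no_self_loops_and_k_bounds(self, toy_graph):
        g = knn_adjacency(toy_graph, 2)
        assert np.all(np.diag(g.adjacency) == 0)
        with pytest.raises(ValueError):
            knn_adjacency(toy_graph, 3)

    def test_complete_digraph_at_k_n_minus_1(self, rng):
        series = [make_series(np.clip(0.8 + 0.1 * rng.normal(size=30), 0.2, 3.0),
                              patient_id=str(i)) for i in range(5)]
        g = knn_adjacency(similarity_matrix(series), 4)
        m = graph_metrics(g)
        assert m.gc == 1.0 and m.gr == 1.0 and m.max_in_degree == 4


def brute_closed_over_paths(adj):
    """Directed triangles (as trace A^3) over directed 2-paths (off-diagonal A^2)."""
    n = adj.shape[0]
    paths = sum(adj[i, j] * adj[j, k] for i in range(n) for j in range(n)
                for k in range(n) if i != k)
    closed = sum(adj[i, j] * adj[j, k] * adj[k, i]
                 for i in range(n) for j in range(n) for k in range(n))
    return closed / paths if paths else float("nan")


class TestTopology:
    def test_ring_has_no_triangles_or_reciprocity(self):
        adj = np.zeros((4, 4), dtype=np.int8)
        for i in range(4):
            adj[i, (i + 1) % 4] = 1
        assert global_clustering(adj) == 0.0
        assert reciprocity(adj) == 0.0
        in_deg, out_deg, max_in, sd = degree_stats(adj)
        assert np.all(in_deg == 1) and np.all(out_deg == 1) and sd == 0.0

    def test_symmetric_graph_reciprocity_one(self):
        adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        assert reciprocity(adj) == 1.0
        assert global_clustering(adj) == 1.0

    def test_hand_reciprocity_two_thirds(self):
        adj = np.zeros((3, 3), dtype=np.int8)
        adj[0, 1] = adj[1, 0] = adj[0, 2] = 1
        assert reciprocity(adj) == pytest.approx(2 / 3)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        adj = (rng.random((n, n)) < 0.4).astype(np.int8)
        np.fill_diagonal(adj, 0)
        got_gc = global_clustering(adj)
        exp_gc = brute_closed_over_paths(adj)
        if np.isnan(exp_gc):
            assert np.isnan(got_gc)
        else:
            assert got_gc == pytest.approx(exp_gc, rel=1e-12)
        edges = adj.sum()
        if edges:
            mutual = sum(adj[i, j] * adj[j, i] for i in range(n) for j in range(n))
            assert reciprocity(adj) == pytest.approx(mutual / edges, rel=1e-12)


class TestCommunities:
    def test_two_disjoint_mutual_triangles(self):
        adj = np.zeros((6, 6), dtype=np.int8)
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.permutations(grp, 2):
                adj[i, j] = 1
        comms = find_communities(adj, 3)
        assert sorted(map(sorted, comms)) == [[0, 1, 2], [3, 4, 5]]

    def test_complete_graph_single_community(self):
        adj = np.ones((5, 5), dtype=np.int8)
        np.fill_diagonal(adj, 0)
        comms = find_communities(adj, 3)
        assert len(comms) == 1 and comms[0] == set(range(5))

    def test_triangles_sharing_edge_merge(self):
        adj = np.zeros((5, 5), dtype=np.int8)
        for i, j in [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (2, 4), (1, 3)]:
            adj[i, j] = adj[j, i] = 1
        comms = find_communities(adj, 3)
        merged = [c for c in comms if len(c) >= 4]
        assert merged, "k-clique adjacency must merge triangles sharing an edge"

    def test_community_clustering_matches_subgraph(self):
        adj = np.ones((4, 4), dtype=np.int8)
        np.fill_diagonal(adj, 0)
        comms = [set(range(4))]
        assert community_clustering(adj, comms) == pytest.approx(
            global_clustering(adj))


@pytest.fixture(scope="module")
def small_cohort():
    return [generate_series(DEFAULT_CLASS_PARAMS[lab], 300, 500 + i,
                            patient_id=f"{lab}{i}", label=lab)
            for lab in ("H", "AF") for i in range(15)]


class TestEnsemble:

    def test_mean_in_degree_forced(self, small_cohort):
        df = ensemble_metrics(small_cohort, "H", n_nodes=10, k=3,
                              realizations=5, seed=1)
        assert np.allclose(df["mean_in_degree"], 3.0)
        assert len(df) == 5

    def test_deterministic(self, small_cohort):
        a = ensemble_metrics(small_cohort, "AF", n_nodes=8, k=2, realizations=4, seed=9)
        b = ensemble_metrics(small_cohort, "AF", n_nodes=8, k=2, realizations=4, seed=9)
        assert a.equals(b)

    def test_class_too_small(self, small_cohort):
        with pytest.raises(ValueError):
            ensemble_metrics(small_cohort, "CD", n_nodes=10, k=2, realizations=1)
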