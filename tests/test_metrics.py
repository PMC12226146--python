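import numpy as np
import networkx as nx
import pytest

from lesionnet import Connectome, compute_all_metrics
from lesionnet.metrics import (
    all_pairs_shortest_paths,
    betweenness_centrality,
    characteristic_path_length,
    clustering_onnela,
    global_assortativity,
    global_efficiency,
    local_assortativity,
    local_efficiency,
    nodal_shortest_path_length,
    nodal_strength,
    weight_to_length,
)

from oracles import (
    betweenness_enumeration_oracle,
    clustering_literal_oracle,
    floyd_warshall_oracle,
    lengths_from_weights,
    local_assortativity_oracle,
    local_efficiency_literal_oracle,
    random_weighted_graph,
)


def chain3():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    return w


def complete(n, weight=1.0):
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0)
    return w


class TestLengthsAndDistances:
    def test_weight_to_length_values(self):
        w = np.array([[0, 0.5, 0], [0.5, 0, 1.0], [0, 1.0, 0]])
        l = weight_to_length(w)
        assert l[0, 1] == 2.0
        assert l[1, 2] == 1.0
        assert np.isinf(l[0, 2])
        assert np.all(np.diag(l) == 0)

    def test_chain_distance(self):
        d = all_pairs_shortest_paths(weight_to_length(chain3()))
        assert d[0, 2] == 2.0

    def test_disconnected_components_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        d = all_pairs_shortest_paths(weight_to_length(w))
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    def test_negative_length_rejected(self):
        l = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError):
            all_pairs_shortest_paths(l)

    def test_dijkstra_matches_floyd_warshall_oracle(self, rng):
        # equality up to float associativity: the two algorithms sum the
        # same edge lengths in different orders
        for _ in range(30):
            n = int(rng.integers(4, 13))
            w = random_weighted_graph(n, 0.4, rng)
            l = weight_to_length(w)
            d1 = all_pairs_shortest_paths(l)
            d2 = floyd_warshall_oracle(lengths_from_weights(w))
            finite = np.isfinite(d1)
            assert np.array_equal(finite, np.isfinite(d2))
            assert np.abs(d1[finite] - d2[finite]).max() < 1e-12

    def test_triangle_inequality_and_symmetry(self, rng):
        w = random_weighted_graph(10, 0.5, rng)
        d = all_pairs_shortest_paths(weight_to_length(w))
        assert np.allclose(d, d.T)
        for k in range(10):
            assert np.all(d <= d[:, [k]] + d[[k], :] + 1e-12)

    def test_adding_edge_is_monotone(self, rng):
        w = random_weighted_graph(9, 0.3, rng)
        d0 = all_pairs_shortest_paths(weight_to_length(w))
        e0 = global_efficiency(d0)
        zeros = np.argwhere(np.triu(w == 0, k=1))
        i, j = zeros[rng.integers(len(zeros))]
        w2 = w.copy()
        w2[i, j] = w2[j, i] = 0.7
        d1 = all_pairs_shortest_paths(weight_to_length(w2))
        assert np.all(d1 <= d0 + 1e-12)
        assert global_efficiency(d1) >= e0 - 1e-12


class TestPathAggregates:
    def test_chain_nodal_path_lengths(self):
        d = all_pairs_shortest_paths(weight_to_length(chain3()))
        l = nodal_shortest_path_length(d)
        assert l[1] == 1.0
        assert l[0] == l[2] == 1.5

    def test_complete_graph_unit_paths(self):
        d = all_pairs_shortest_paths(weight_to_length(complete(6)))
        assert np.allclose(nodal_shortest_path_length(d), 1.0)
        cpl, excl = characteristic_path_length(d)
        assert cpl == 1.0 and excl == 0.0
        assert global_efficiency(d) == 1.0

    def test_chain_characteristic_path_length(self):
        d = all_pairs_shortest_paths(weight_to_length(chain3()))
        cpl, excl = characteristic_path_length(d)
        assert np.isclose(cpl, 4 / 3)
        assert excl == 0.0
        assert np.isclose(global_efficiency(d), 5 / 6)

    def test_cpl_equals_mean_nodal_on_complete_graphs(self, rng):
        w = complete(7, 0.5) * rng.uniform(0.9, 1.0)
        d = all_pairs_shortest_paths(weight_to_length(w))
        cpl, _ = characteristic_path_length(d)
        assert np.isclose(cpl, nodal_shortest_path_length(d).mean())

    def test_floating_node_flagged_and_excluded(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        d = all_pairs_shortest_paths(weight_to_length(w))
        l = nodal_shortest_path_length(d)
        assert np.isnan(l[3])
        assert not np.isnan(l[:3]).any()

    def test_fully_disconnected_efficiency_zero(self):
        d = all_pairs_shortest_paths(weight_to_length(np.zeros((5, 5))))
        assert global_efficiency(d) == 0.0
        with pytest.raises(ValueError):
            characteristic_path_length(d)


class TestClustering:
    def test_perfect_triangle(self):
        assert np.allclose(clustering_onnela(complete(3)), 1.0)

    def test_star_has_no_triangles(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        assert np.allclose(clustering_onnela(w), 0.0)

    def test_weighted_triangle_value(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        c = clustering_onnela(w)
        assert np.allclose(c, 0.25 ** (1 / 3))

    def test_matches_literal_oracle_and_networkx(self, rng):
        for _ in range(10):
            w = random_weighted_graph(10, 0.5, rng)
            c = clustering_onnela(w)
            assert np.abs(c - clustering_literal_oracle(w)).max() < 1e-10
            g = nx.from_numpy_array(w)
            c_nx = np.array([v for _, v in sorted(nx.clustering(g, weight="weight").items())])
            assert np.abs(c - c_nx).max() < 1e-10

    def test_all_zero_matrix(self):
        assert np.array_equal(clustering_onnela(np.zeros((4, 4))), np.zeros(4))


class TestLocalEfficiency:
    def test_complete_graph_is_one(self):
        assert np.allclose(local_efficiency(complete(4)), 1.0)

    def test_star_is_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        assert np.allclose(local_efficiency(w), 0.0)

    def test_matches_literal_oracle(self, rng):
        for _ in range(10):
            w = random_weighted_graph(7, 0.5, rng)
            assert np.abs(local_efficiency(w) - local_efficiency_literal_oracle(w)).max() < 1e-10


class TestStrength:
    def test_values_and_handshake(self, rng):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        w[0, 2] = w[2, 0] = 0.3
        s = nodal_strength(w)
        assert np.isclose(s[0], 0.5)
        w2 = random_weighted_graph(12, 0.4, rng)
        assert np.isclose(nodal_strength(w2).sum(), 2 * np.triu(w2).sum())

    def test_floating_node_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        assert nodal_strength(w)[2] == 0.0


class TestBetweenness:
    def test_path_graph(self):
        b = betweenness_centrality(weight_to_length(chain3()))
        assert b[1] == 1.0 and b[0] == b[2] == 0.0

    def test_star_center(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        b = betweenness_centrality(weight_to_length(w))
        assert b[0] == 3.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(8):
            n = int(rng.integers(5, 9))
            w = random_weighted_graph(n, 0.5, rng)
            l = weight_to_length(w)
            assert np.allclose(betweenness_centrality(l),
                               betweenness_enumeration_oracle(lengths_from_weights(w)),
                               atol=1e-9)


class TestAssortativity:
    def test_regular_graph_undefined(self):
        assert np.isnan(global_assortativity(complete(5)))
        assert np.all(np.isnan(local_assortativity(complete(5))))

    def test_strong_clique_with_weak_periphery_is_assortative(self):
        # high-strength nodes {0,1,2} connect to each other, low-strength
        # nodes {3,4} to each other; one weak bridge
        w = np.zeros((5, 5))
        for i, j in ((0, 1), (0, 2), (1, 2)):
            w[i, j] = w[j, i] = 1.0
        w[3, 4] = w[4, 3] = 0.1
        w[2, 3] = w[3, 2] = 0.05
        r = global_assortativity(w)
        assert r > 0

    def test_bounded_when_defined(self, rng):
        for _ in range(20):
            w = random_weighted_graph(8, 0.5, rng)
            r = global_assortativity(w)
            if not np.isnan(r):
                assert -1 - 1e-12 <= r <= 1 + 1e-12

    def test_local_sums_to_global(self, rng):
        for _ in range(10):
            w = random_weighted_graph(9, 0.4, rng)
            r = global_assortativity(w)
            if np.isnan(r):
                continue
            a = local_assortativity(w)
            assert abs(a.sum() - r) < 1e-12

    def test_isolated_node_contributes_zero(self, rng):
        w = random_weighted_graph(6, 0.6, rng)
        w[5, :] = w[:, 5] = 0.0
        a = local_assortativity(w)
        if not np.isnan(a).all():
            assert a[5] == 0.0

    def test_matches_edge_accumulation_oracle(self, rng):
        w = random_weighted_graph(6, 0.7, rng)
        a = local_assortativity(w)
        assert np.allclose(a, local_assortativity_oracle(w), atol=1e-12)


class TestComputeAllMetrics:
    def test_complete_graph_closed_forms(self):
        conn = Connectome(weights=complete(10))
        nodal, whole = compute_all_metrics(conn)
        assert np.allclose(nodal["strength"], 9.0)
        assert np.isclose(whole["global_clustering"], 1.0)
        assert np.isclose(whole["characteristic_path_length"], 1.0)
        assert np.isclose(whole["global_efficiency"], 1.0)

    def test_floating_node_equivalent_to_reduced_graph(self, rng):
        w = random_weighted_graph(9, 0.6, rng)
        w[4, :] = w[:, 4] = 0.0
        nodal, whole = compute_all_metrics(Connectome(weights=w))
        reduced = np.delete(np.delete(w, 4, axis=0), 4, axis=1)
        nodal_r, whole_r = compute_all_metrics(Connectome(weights=reduced))
        assert np.isnan(nodal["path_length"].iloc[4])
        keep = [i for i in range(9) if i != 4]
        for m in ("strength", "clustering", "betweenness", "local_efficiency"):
            assert np.allclose(nodal[m].iloc[keep].to_numpy(), nodal_r[m].to_numpy())
        for m in ("characteristic_path_length", "global_efficiency",
                  "global_clustering", "mean_local_efficiency"):
            assert np.isclose(whole[m], whole_r[m]), m

    def test_deterministic(self, hub_connectome):
        n1, w1 = compute_all_metrics(hub_connectome)
        n2, w2 = compute_all_metrics(hub_connectome)
        assert n1.equals(n2)
        assert w1 == w2
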