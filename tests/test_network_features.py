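"""Graph attributes: closed-form cases, brute-force oracles, invariances."""

import itertools

import numpy as np
import pytest

from dbfn.network_features import (
    assemble_trial_features,
    characteristic_path_length,
    clustering_coefficient,
    edge_frequency_map,
    feature_vectors_batch,
    global_efficiency,
    graph_metrics,
    local_efficiency,
    network_feature_vector,
    retain_frequent_edges,
    shortest_paths,
)

INF = float("inf")


def _adj(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


K4 = _adj(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
PATH3 = _adj(3, [(0, 1), (1, 2)])
STAR4 = _adj(4, [(0, 1), (0, 2), (0, 3)])  # node 0 = centre
TRIANGLE = _adj(3, [(0, 1), (1, 2), (0, 2)])


def _floyd_warshall(a):
    """Literal O(n^3) shortest paths, independent of the production BFS."""
    n = a.shape[0]
    d = np.where(a > 0, 1.0, INF)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _oracle_metrics(a):
    """Triple-loop reference for Eg, Eloc, Ci on one adjacency matrix."""
    n = a.shape[0]
    d = _floyd_warshall(a)
    eg = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                eg += 1.0 / d[i, j]
    eg /= n * (n - 1)

    eloc = np.zeros(n)
    ci = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        deg = len(nbrs)
        if deg < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        ds = _floyd_warshall(sub)
        acc = 0.0
        for u in range(deg):
            for v in range(deg):
                if u != v and np.isfinite(ds[u, v]):
                    acc += 1.0 / ds[u, v]
        eloc[i] = acc / (deg * (deg - 1))
        e_i = sub.sum() / 2
        ci[i] = e_i / (deg * (deg - 1) / 2)
    return eg, eloc, ci


class TestShortestPaths:
    def test_complete_graph_all_distance_one(self):
        d = shortest_paths(K4)
        assert np.all(d[~np.eye(4, dtype=bool)] == 1)

    def test_path_graph_end_to_end(self):
        assert shortest_paths(PATH3)[0, 2] == 2

    def test_disconnected_dyads_infinite(self):
        a = _adj(4, [(0, 1), (2, 3)])
        d = shortest_paths(a)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])


class TestCharacteristicPathLength:
    def test_complete_graph(self):
        assert characteristic_path_length(K4) == (1.0, True)

    def test_path_graph(self):
        lp, connected = characteristic_path_length(PATH3)
        assert connected and lp == pytest.approx(4 / 3)

    def test_edgeless_graph_flagged_undefined(self):
        lp, connected = characteristic_path_length(np.zeros((4, 4), dtype=int))
        assert not connected and np.isinf(lp)


class TestGlobalEfficiency:
    @pytest.mark.parametrize("adj,expected", [
        (K4, 1.0),
        (np.zeros((5, 5), dtype=int), 0.0),
        (PATH3, 5 / 6),
    ])
    def test_closed_forms(self, adj, expected):
        assert global_efficiency(adj) == pytest.approx(expected)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(np.zeros((1, 1), dtype=int))


class TestLocalEfficiency:
    def test_triangle_vertex(self):
        assert local_efficiency(TRIANGLE, 0) == 1.0

    def test_star_centre(self):
        assert local_efficiency(STAR4, 0) == 0.0

    def test_k4_minus_edge(self):
        a = K4.copy()
        a[2, 3] = a[3, 2] = 0
        # node 0 is adjacent to 1,2,3; the neighbour subgraph is a 3-path
        assert local_efficiency(a, 0) == pytest.approx(5 / 6)

    def test_literal_reading_includes_the_node(self):
        # with the node included, the star centre's subgraph is the star
        # itself: 6 ordered centre-leaf pairs at distance 1 and 6 leaf-leaf
        # pairs at distance 2 -> (6 + 3) / 12
        assert local_efficiency(STAR4, 0, include_node=True) == \
            pytest.approx(0.75)
        assert local_efficiency(STAR4, 0) == 0.0


class TestClustering:
    @pytest.mark.parametrize("adj,node,expected", [
        (TRIANGLE, 0, 1.0),
        (STAR4, 0, 0.0),
        (_adj(4, [(0, 1), (0, 2), (0, 3), (1, 2)]), 0, 1 / 3),
        (PATH3, 0, 0.0),  # degree 1
    ])
    def test_closed_forms(self, adj, node, expected):
        assert clustering_coefficient(adj, node) == pytest.approx(expected)


class TestFeatureVector:
    def test_length_1_plus_2n(self, rng):
        for n in (3, 8, 32):
            a = (rng.random((n, n)) < 0.4)
            a = np.triu(a, 1)
            a = (a | a.T).astype(int)
            assert network_feature_vector(a).shape == (1 + 2 * n,)

    def test_edgeless_graph_all_zero(self):
        assert np.all(network_feature_vector(np.zeros((6, 6), int)) == 0.0)

    def test_batch_matches_oracle_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 13))
            p = rng.uniform(0.0, 1.0)
            a = (rng.random((n, n)) < p)
            a = np.triu(a, 1)
            a = (a | a.T).astype(int)
            fv = feature_vectors_batch(a[None])[0]
            eg, eloc, ci = _oracle_metrics(a)
            assert fv[0] == pytest.approx(eg, abs=1e-12)
            np.testing.assert_allclose(fv[1:1 + n], eloc, atol=1e-12)
            np.testing.assert_allclose(fv[1 + n:], ci, atol=1e-12)

    def test_batch_matches_networkx(self, rng):
        # independent cross-check against the established graph library
        import networkx as nx

        for _ in range(30):
            n = int(rng.integers(3, 15))
            a = (rng.random((n, n)) < rng.uniform(0.1, 0.9))
            a = np.triu(a, 1)
            a = (a | a.T).astype(int)
            fv = feature_vectors_batch(a[None])[0]
            G = nx.from_numpy_array(a)
            assert fv[0] == pytest.approx(nx.global_efficiency(G), abs=1e-12)
            eloc = [nx.global_efficiency(G.subgraph(list(G[i])))
                    if G.degree[i] >= 2 else 0.0 for i in range(n)]
            np.testing.assert_allclose(fv[1:1 + n], eloc, atol=1e-12)
            np.testing.assert_allclose(
                fv[1 + n:], [nx.clustering(G, i) for i in range(n)],
                atol=1e-12)

    def test_metrics_bounded(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 10))
            a = (rng.random((n, n)) < rng.uniform(0.2, 0.9))
            a = np.triu(a, 1)
            a = (a | a.T).astype(int)
            fv = network_feature_vector(a)
            assert np.all((fv >= 0.0) & (fv <= 1.0))
            m = graph_metrics(a)
            if m.connected and n >= 2:
                assert m.Lp >= 1.0

    def test_adding_an_edge_never_decreases_global_efficiency(self):
        # exhaustive over all graphs on 5 nodes
        pairs = list(itertools.combinations(range(5), 2))
        adjs = np.zeros((1 << len(pairs), 5, 5), dtype=int)
        for code in range(1 << len(pairs)):
            for b, (i, j) in enumerate(pairs):
                if code >> b & 1:
                    adjs[code, i, j] = adjs[code, j, i] = 1
        eg = feature_vectors_batch(adjs)[:, 0]
        for code in range(1 << len(pairs)):
            for b in range(len(pairs)):
                if not code >> b & 1:
                    assert eg[code | 1 << b] >= eg[code] - 1e-12

    def test_isomorphism_invariance(self, rng):
        n = 9
        a = (rng.random((n, n)) < 0.4)
        a = np.triu(a, 1)
        a = (a | a.T).astype(int)
        perm = rng.permutation(n)
        b = a[np.ix_(perm, perm)]
        fa, fb = network_feature_vector(a), network_feature_vector(b)
        assert fb[0] == pytest.approx(fa[0], abs=1e-12)
        np.testing.assert_allclose(fb[1:1 + n], fa[1:1 + n][perm], atol=1e-12)
        np.testing.assert_allclose(fb[1 + n:], fa[1 + n:][perm], atol=1e-12)


class TestTrialAssembly:
    @pytest.mark.parametrize("window_s,n_networks", [(6.0, 120), (60.0, 12),
                                                     (1.0, 720), (10.0, 72)])
    def test_network_counts(self, rng, window_s, n_networks):
        n = 4
        adjs = (rng.random((n_networks, n, n)) < 0.3).astype(int)
        adjs = np.triu(adjs, 1) + np.triu(adjs, 1).swapaxes(1, 2)
        tf = assemble_trial_features(adjs, window_s)
        assert tf.vector.size == n_networks * (1 + 2 * n)
        assert len(tf.layout) == tf.vector.size

    def test_t6_on_32_channels_yields_7800_values(self, rng):
        adjs = np.zeros((120, 32, 32), dtype=int)
        tf = assemble_trial_features(adjs, 6.0)
        assert tf.vector.size == 12 * 10 * 65 == 7800

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="networks"):
            assemble_trial_features(np.zeros((7, 4, 4), int), 6.0)

    def test_layout_order_is_signal_major(self):
        adjs = np.zeros((24, 3, 3), dtype=int)
        tf = assemble_trial_features(adjs, 30.0,
                                     signal_names=[f"s{i}" for i in range(12)])
        assert tf.layout[0].startswith("s0|w00|Eg")
        per_block = 1 + 2 * 3
        assert tf.layout[per_block].startswith("s0|w01|")
        assert tf.layout[2 * per_block].startswith("s1|w00|")


class TestEdgeAggregation:
    def test_counts_and_strict_retention(self, rng):
        nets = np.zeros((12, 4, 4), dtype=int)
        nets[:, 0, 1] = nets[:, 1, 0] = 1          # always present
        nets[:9, 2, 3] = nets[:9, 3, 2] = 1        # 9 of 12 = 75%
        fmap = edge_frequency_map(nets)
        assert fmap.max_count == 12
        assert fmap.counts[0, 1] == 12 and fmap.counts[2, 3] == 9
        kept80 = retain_frequent_edges(fmap, 0.8)
        assert kept80.values[0, 1] == 1 and kept80.values[2, 3] == 0
        kept70 = retain_frequent_edges(fmap, 0.7)
        assert kept70.values[2, 3] == 1
        # exactly at the cutoff is discarded (strict inequality)
        kept75 = retain_frequent_edges(fmap, 0.75)
        assert kept75.values[2, 3] == 0

    def test_dynamic_window_max_count(self, rng):
        nets = (rng.random((120, 5, 5)) < 0.5).astype(int)
        assert edge_frequency_map(nets).max_count == 120

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            edge_frequency_map(np.zeros((0, 4, 4), int))
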