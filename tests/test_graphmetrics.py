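"""Graph metrics against hand-enumerated and brute-force oracles."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from oracles import (brute_char_path_length, brute_global_efficiency,
                     brute_local_efficiency, brute_onnela_clustering,
                     brute_top_k_edges, random_weighted_graph)
from plvnet.graphmetrics import (ThresholdedGraph, characteristic_path_length,
                                 clustering_coefficient, global_efficiency,
                                 inverse_path_length_efficiency, local_efficiency,
                                 metrics_sweep, minimum_connected_sparsity,
                                 normalize_vs_random, proportional_threshold)


def graph_of(w):
    w = np.asarray(w, dtype=float)
    return ThresholdedGraph(weights=w, sparsity=1.0,
                            connected=nx.is_connected(nx.from_numpy_array(w)))


def complete(n, weight=1.0):
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return w


def ring(n, weight=1.0):
    w = np.zeros((n, n))
    for i in range(n):
        w[i, (i + 1) % n] = w[(i + 1) % n, i] = weight
    return w


def star(n):
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 1.0
    return w


class TestProportionalThreshold:
    def test_sparsity_one_only_zeroes_diagonal(self, rng):
        m = rng.uniform(0.1, 1, size=(6, 6))
        m = (m + m.T) / 2
        g = proportional_threshold(m, 1.0)
        expected = m.copy()
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(g.weights, expected)

    def test_68_nodes_at_005_keeps_114_edges(self, rng):
        m = rng.uniform(0, 1, size=(68, 68))
        m = (m + m.T) / 2
        g = proportional_threshold(m, 0.05)
        assert (np.triu(g.weights, 1) > 0).sum() == 114  # round(0.05 * 2278)

    def test_matches_full_sort_oracle(self, rng):
        for _ in range(5):
            m = rng.uniform(0, 1, size=(10, 10))
            m = (m + m.T) / 2
            g = proportional_threshold(m, 0.3)
            kept = {(i, j) for i, j in zip(*np.where(np.triu(g.weights, 1) > 0))}
            k = int(round(0.3 * 45))
            np.fill_diagonal(m, 0.0)
            assert kept == brute_top_k_edges(m, k)

    def test_invalid_sparsity(self, rng):
        with pytest.raises(ValueError):
            proportional_threshold(np.eye(4), 0.0)


class TestPathMetrics:
    def test_complete_unit_graph(self):
        g = graph_of(complete(5))
        assert characteristic_path_length(g) == pytest.approx(1.0)
        assert global_efficiency(g) == pytest.approx(1.0)

    def test_unit_ring_of_four(self):
        """Hand enumeration: L = 4/3, Eglob = (1 + 1 + 1/2)/3 = 5/6."""
        g = graph_of(ring(4))
        assert characteristic_path_length(g) == pytest.approx(4.0 / 3.0)
        assert global_efficiency(g) == pytest.approx(5.0 / 6.0)
        assert inverse_path_length_efficiency(g) == pytest.approx(3.0 / 4.0)

    def test_halving_weights_doubles_path_length(self, rng):
        w = random_weighted_graph(rng, 6)
        g = graph_of(w)
        if not g.connected:
            pytest.skip("random draw disconnected")
        assert characteristic_path_length(graph_of(w / 2)) == pytest.approx(
            2 * characteristic_path_length(g))

    def test_disconnected_graph_errors_for_L_but_not_Eglob(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        g = graph_of(w)
        with pytest.raises(ValueError, match="sparsity"):
            characteristic_path_length(g)
        # only the (0,1) pair of 12 ordered pairs is reachable
        assert global_efficiency(g) == pytest.approx(2.0 / 12.0)

    def test_fully_disconnected_efficiency_zero(self):
        assert global_efficiency(graph_of(np.zeros((5, 5)))) == 0.0


class TestClusteringAndLocalEfficiency:
    def test_complete_graph_all_ones(self):
        g = graph_of(complete(4))
        assert clustering_coefficient(g)[1] == pytest.approx(1.0)
        assert local_efficiency(g)[1] == pytest.approx(1.0)

    def test_star_graph_all_zero(self):
        g = graph_of(star(6))
        assert clustering_coefficient(g)[1] == 0.0
        assert local_efficiency(g)[1] == 0.0

    def test_weighted_fixture_matches_triple_enumeration(self, rng):
        w = random_weighted_graph(rng, 5)
        per_node, mean_c = clustering_coefficient(graph_of(w))
        assert np.allclose(per_node, brute_onnela_clustering(w))
        # independent library cross-check (networkx implements Onnela)
        gx = nx.from_numpy_array(w)
        nx_c = nx.clustering(gx, weight="weight")
        assert np.allclose(per_node, [nx_c[i] for i in range(5)])

    def test_local_efficiency_matches_subgraph_oracle(self, rng):
        w = random_weighted_graph(rng, 6)
        per_node, _ = local_efficiency(graph_of(w))
        assert np.allclose(per_node, brute_local_efficiency(w))


class TestBruteForceSweep:
    def test_all_metrics_match_oracles_on_random_graphs(self, rng):
        """All four metrics agree with exhaustive enumeration on >= 20
        random weighted and binary graphs of <= 6 nodes."""
        checked = 0
        while checked < 20:
            n = int(rng.integers(4, 7))
            w = random_weighted_graph(rng, n, binary=bool(checked % 2))
            g = graph_of(w)
            assert global_efficiency(g) == pytest.approx(brute_global_efficiency(w))
            assert np.allclose(clustering_coefficient(g)[0],
                               brute_onnela_clustering(w))
            assert np.allclose(local_efficiency(g)[0], brute_local_efficiency(w))
            if g.connected:
                assert characteristic_path_length(g) == pytest.approx(
                    brute_char_path_length(w))
            checked += 1


class TestInvariants:
    def test_efficiency_monotone_in_sparsity(self, rng):
        m = rng.uniform(0, 1, size=(20, 20))
        m = (m + m.T) / 2
        effs = [global_efficiency(proportional_threshold(m, s))
                for s in np.arange(0.05, 0.51, 0.05)]
        assert all(b >= a - 1e-12 for a, b in zip(effs, effs[1:]))

    def test_node_permutation_equivariance(self, rng):
        w = random_weighted_graph(rng, 6)
        perm = rng.permutation(6)
        wp = w[np.ix_(perm, perm)]
        c, mean_c = clustering_coefficient(graph_of(w))
        cp, mean_cp = clustering_coefficient(graph_of(wp))
        assert np.allclose(cp, c[perm])
        assert mean_cp == pytest.approx(mean_c)
        e, mean_e = local_efficiency(graph_of(w))
        ep, mean_ep = local_efficiency(graph_of(wp))
        assert np.allclose(ep, e[perm])


class TestNullNormalization:
    def test_dense_random_graph_normalized_L_near_one(self, rng):
        w = random_weighted_graph(rng, 16, p_edge=0.5)
        g = graph_of(w)
        assert g.connected
        nl, nc = normalize_vs_random(g, n_null=10, seed=1)
        assert nl == pytest.approx(1.0, rel=0.10)

    def test_ring_lattice_clusters_above_random(self):
        # ring lattice: each node joined to 2 neighbors on each side
        n = 16
        w = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                w[i, (i + d) % n] = w[(i + d) % n, i] = 1.0
        nl, nc = normalize_vs_random(graph_of(w), n_null=10, seed=2)
        assert nc > 1.0

    def test_seeded_reproducibility(self, rng):
        w = random_weighted_graph(rng, 12, p_edge=0.5)
        g = graph_of(w)
        assert normalize_vs_random(g, n_null=5, seed=7) == \
            normalize_vs_random(g, n_null=5, seed=7)


def _brute_min_sparsity(m, grid):
    """Union-find-style oracle: first grid sparsity whose top-k edge set
    is connected, using brute-force sorting and networkx connectivity."""
    n = m.shape[0]
    for s in grid:
        k = int(round(s * n * (n - 1) / 2))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(brute_top_k_edges(m, k))
        if nx.is_connected(g):
            return s
    raise AssertionError("oracle: never connected")


class TestMinimumConnectedSparsity:
    def test_backbone_matrix_connects_at_first_grid_point(self, rng):
        """A matrix with a strong spanning backbone (the structured case
        connectivity matrices resemble) is connected at sparsity 0.05,
        and the scan agrees with the brute-force oracle on a random one."""
        m = rng.uniform(0.2, 0.8, size=(68, 68))
        m = (m + m.T) / 2
        rand_min = minimum_connected_sparsity(m)
        grid = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
        assert rand_min == pytest.approx(_brute_min_sparsity(m, grid))
        for i in range(67):  # spanning chain of strong edges
            m[i, i + 1] = m[i + 1, i] = 0.9 + 0.001 * i
        assert minimum_connected_sparsity(m) == 0.05

    def test_weak_node_matches_brute_scan(self, rng):
        m = rng.uniform(0.5, 1.0, size=(20, 20))
        m = (m + m.T) / 2
        m[5, :] = m[:, 5] = 0.3   # one weakly connected node ...
        m[5, 6] = m[6, 5] = 0.9   # ... with a single strong edge
        got = minimum_connected_sparsity(m)
        grid = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
        assert got == pytest.approx(_brute_min_sparsity(m, grid))
        assert got > 0.05

    def test_spanning_tree_needs_its_weakest_edge(self):
        """A path graph only connects once its faintest edge enters."""
        n = 8
        m = np.zeros((n, n))
        for i in range(n - 1):
            m[i, i + 1] = m[i + 1, i] = 1.0 - 0.1 * i  # weakest edge last
        # add strong clutter edges among the first half
        m[0, 2] = m[2, 0] = 0.95
        grid = tuple(np.round(np.arange(0.05, 1.01, 0.05), 2))
        got = minimum_connected_sparsity(m, grid=grid)
        assert got == pytest.approx(_brute_min_sparsity(m, grid))

    def test_isolated_node_errors(self):
        m = complete(5)
        m[4, :] = m[:, 4] = 0.0
        with pytest.raises(ValueError):
            minimum_connected_sparsity(m)


class TestSweepTable:
    def test_long_format_rows(self, rng):
        m = rng.uniform(0.2, 1, size=(12, 12))
        m = (m + m.T) / 2
        df = metrics_sweep(m, subject_id="s0", band="alpha")
        assert set(df.metric) == {"L", "Eglob", "C", "Eloc"}
        assert len(df) == 4 * 10  # four metrics x ten grid sparsities
        assert (df.groupby("metric").size() == 10).all()
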