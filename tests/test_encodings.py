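"""Structural encodings: shortest paths, degree, spatial and edge biases."""

import networkx as nx
import numpy as np
import pytest

from dtafusion import encodings
from dtafusion.autodiff import Parameter, Tensor
from dtafusion.chem import DrugGraph, build_drug_graph, parse_molecule
from dtafusion.encodings import (DegreeEmbeddingTable, EdgePathTable,
                                 bond_onehot, canonical_shortest_path,
                                 compute_spd, degree_encode, edge_path_bias,
                                 path_feature_matrix, spatial_bias)

from conftest import random_adjacency


def floyd_warshall_oracle(adj):
    """Independent all-pairs hop counts; -1 where unreachable."""
    n = adj.shape[0]
    INF = 10 ** 9
    d = np.where(adj > 0, 1, INF)
    np.fill_diagonal(d, 0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return np.where(d >= INF, -1, d)


def graph_from_adjacency(adj, bond_feature=None):
    edges = []
    for i in range(adj.shape[0]):
        for j in range(i + 1, adj.shape[0]):
            if adj[i, j]:
                bf = bond_feature(i, j) if bond_feature else np.array([0, 0, 1])
                edges.append((i, j, bf))
    return DrugGraph(node_features=np.zeros((adj.shape[0], 9), dtype=np.int64),
                     adjacency=adj, edges=edges, degrees=adj.sum(axis=1))


class TestComputeSPD:
    def test_path_graph(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        spd = compute_spd(graph_from_adjacency(adj))
        assert spd.phi[0, 2] == 2
        assert np.all(np.diag(spd.phi) == 0)

    def test_disconnected_components_marked_unreachable(self):
        adj = np.zeros((4, 4), dtype=np.int64)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1
        spd = compute_spd(graph_from_adjacency(adj))
        assert spd.phi[0, 2] == -1
        assert spd.phi[1, 3] == -1

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            adj = random_adjacency(rng, n, p=rng.uniform(0.1, 0.6))
            spd = compute_spd(graph_from_adjacency(adj))
            assert np.array_equal(spd.phi, floyd_warshall_oracle(adj))


class TestDegreeEncode:
    def test_zero_tables_are_identity(self, rng):
        table = DegreeEmbeddingTable(4)
        x = Tensor(rng.normal(size=(5, 4)))
        h = degree_encode(x, np.array([1, 2, 3, 0, 2]), table)
        np.testing.assert_array_equal(h.data, x.data)

    def test_in_and_out_lookups_share_the_degree_key(self, rng):
        table = DegreeEmbeddingTable(4, rng=rng, scale=0.5)
        x = Tensor(np.zeros((3, 4)))
        h = degree_encode(x, np.array([2, 2, 2]), table)
        expected = table.in_table.data[2] + table.out_table.data[2]
        for row in h.data:
            np.testing.assert_allclose(row, expected)

    def test_degree_above_clip_uses_top_bucket(self, rng):
        table = DegreeEmbeddingTable(4, max_degree_bucket=16, rng=rng, scale=0.5)
        h_clip = degree_encode(Tensor(np.zeros((1, 4))), np.array([40]), table)
        h_top = degree_encode(Tensor(np.zeros((1, 4))), np.array([16]), table)
        np.testing.assert_array_equal(h_clip.data, h_top.data)

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            degree_encode(Tensor(np.zeros((1, 4))), np.array([-1]),
                          DegreeEmbeddingTable(4))


class TestSpatialBias:
    def test_zero_weights_zero_bias(self):
        g = build_drug_graph(parse_molecule("CCO"))
        bias = spatial_bias(compute_spd(g), encodings.make_spatial_weights())
        assert np.all(bias.data == 0)

    def test_one_hot_bucket_marks_adjacent_pairs(self):
        g = build_drug_graph(parse_molecule("CCCC"))
        w = np.zeros(encodings.MAX_SPD_BUCKET + 2)
        w[1] = 1.0
        bias = spatial_bias(compute_spd(g), Parameter(w))
        np.testing.assert_array_equal(bias.data, g.adjacency)

    def test_unreachable_pairs_use_dedicated_bucket(self):
        adj = np.zeros((4, 4), dtype=np.int64)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1
        w = np.zeros(encodings.MAX_SPD_BUCKET + 2)
        w[-1] = 7.0
        bias = spatial_bias(compute_spd(graph_from_adjacency(adj)), Parameter(w))
        assert bias.data[0, 2] == 7.0
        assert bias.data[0, 1] == 0.0

    def test_symmetric_for_random_graphs(self, rng):
        w = Parameter(rng.normal(size=encodings.MAX_SPD_BUCKET + 2))
        for _ in range(20):
            adj = random_adjacency(rng, int(rng.integers(2, 10)))
            bias = spatial_bias(compute_spd(graph_from_adjacency(adj)), w)
            np.testing.assert_array_equal(bias.data, bias.data.T)


def brute_force_edge_bias(g, w_edge, max_path_len=20):
    """Oracle: enumerate *all* shortest paths with networkx, apply the same
    lexicographic tie-break, average projected bond features."""
    G = nx.from_numpy_array(g.adjacency)
    feats = {}
    for i, j, bf in g.edges:
        feats[(i, j)] = feats[(j, i)] = bond_onehot(bf)
    n = g.adjacency.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j or not nx.has_path(G, i, j):
                continue
            paths = sorted(nx.all_shortest_paths(G, i, j))
            best = paths[0]  # lexicographically smallest node sequence
            edges = list(zip(best[:-1], best[1:]))[:max_path_len]
            out[i, j] = np.mean([feats[e] @ w_edge for e in edges])
    return out


class TestEdgePathBias:
    def test_adjacent_pair_equals_single_bond_projection(self):
        g = build_drug_graph(parse_molecule("CCO"))
        w = np.arange(len(bond_onehot(g.edges[0][2]))) * 0.1
        table = EdgePathTable(Parameter(w))
        bias = edge_path_bias(g, compute_spd(g), table)
        i, j, bf = g.edges[0]
        assert bias.data[i, j] == pytest.approx(bond_onehot(bf) @ w)

    def test_two_hop_equal_bonds_average_to_single_value(self):
        g = build_drug_graph(parse_molecule("CCC"))  # two identical C-C bonds
        w = np.ones(len(bond_onehot(g.edges[0][2])))
        table = EdgePathTable(Parameter(w))
        bias = edge_path_bias(g, compute_spd(g), table)
        assert bias.data[0, 2] == pytest.approx(bias.data[0, 1])

    def test_matches_exhaustive_path_enumeration(self, rng):
        for trial in range(30):
            n = int(rng.integers(3, 10))
            adj = random_adjacency(rng, n, p=0.45)
            # distinct bond features to make path choice observable
            g = graph_from_adjacency(
                adj, bond_feature=lambda i, j: np.array([(i + j) % 4, 0, (i * j) % 2]))
            w = rng.normal(size=len(bond_onehot(np.array([0, 0, 0]))))
            table = EdgePathTable(Parameter(w))
            bias = edge_path_bias(g, compute_spd(g), table)
            np.testing.assert_allclose(bias.data, brute_force_edge_bias(g, w),
                                       atol=1e-12)

    def test_unreachable_pairs_and_diagonal_are_zero(self):
        adj = np.zeros((4, 4), dtype=np.int64)
        adj[0, 1] = adj[1, 0] = 1
        g = graph_from_adjacency(adj)
        table = EdgePathTable(Parameter(np.ones(len(bond_onehot(np.array([0, 0, 1]))))))
        bias = edge_path_bias(g, compute_spd(g), table)
        assert bias.data[0, 2] == 0.0
        assert np.all(np.diag(bias.data) == 0)


class TestRelabelInvariance:
    def test_encodings_commute_with_relabelling(self, rng):
        """SPD (hence both biases) transforms by the permutation."""
        for _ in range(10):
            n = int(rng.integers(3, 9))
            adj = random_adjacency(rng, n, p=0.5)
            perm = rng.permutation(n)
            spd1 = compute_spd(graph_from_adjacency(adj)).phi
            spd2 = compute_spd(
                graph_from_adjacency(adj[np.ix_(perm, perm)])).phi
            np.testing.assert_array_equal(spd2, spd1[np.ix_(perm, perm)])
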