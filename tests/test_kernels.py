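"""Commute-time kernels, kernel fusion, and network materialization."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import random_connected_graph
from disconet.kernels import (
    KernelMatrix,
    adjacency_to_graph,
    commute_time,
    consensus_kernel,
    cosine_normalize,
    ct_kernel,
    materialize_network,
)


class TestCtKernel:
    def test_single_edge_closed_form(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        K = ct_kernel(g)
        assert np.allclose(K.K, [[0.25, -0.25], [-0.25, 0.25]])
        assert commute_time(K, g, "a", "b") == pytest.approx(2.0)

    def test_path3_commute_time(self, path3):
        K = ct_kernel(path3)
        # c(A,C) = vol * R(A,C) = 4 * 2 = 8 random-walk steps
        assert commute_time(K, path3, "A", "C") == pytest.approx(8.0, rel=1e-9)

    def test_row_sums_zero_and_psd(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            g = random_connected_graph(rng, 15)
            K = ct_kernel(g)
            assert np.allclose(K.K.sum(axis=1), 0.0, atol=1e-8)
            assert K.min_eigenvalue() >= -1e-8

    def test_matches_resistance_distance_oracle(self):
        """Commute time = vol * effective resistance (independent oracle:
        networkx resistance_distance)."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            g = random_connected_graph(rng, 12)
            nx.set_edge_attributes(g, 1.0, "weight")
            K = ct_kernel(g)
            vol = 2.0 * g.number_of_edges()
            nodes = list(g.nodes())
            u, v = nodes[0], nodes[-1]
            expected = vol * nx.resistance_distance(g, u, v)
            assert commute_time(K, g, u, v) == pytest.approx(expected, rel=1e-8)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        g = random_connected_graph(rng, 10)
        K1 = ct_kernel(g)
        relabeled = nx.relabel_nodes(g, {n: f"X{n}" for n in g.nodes()})
        K2 = ct_kernel(relabeled)
        # sorted node order differs but entries must map across the renaming
        ix1, ix2 = K1.index, K2.index
        for a in g.nodes():
            for b in g.nodes():
                assert K1.K[ix1[a], ix1[b]] == pytest.approx(
                    K2.K[ix2[f"X{a}"], ix2[f"X{b}"]], abs=1e-10
                )

    def test_disconnected_uses_largest_component(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_edge("b", "c")
        g.add_edge("x", "y")
        with pytest.warns(UserWarning, match="largest component"):
            K = ct_kernel(g)
        assert set(K.nodes) == {"a", "b", "c"}

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            ct_kernel(nx.Graph())


class TestCosineNormalize:
    def test_unit_diagonal_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(5, 5))
        K = A @ A.T + 5 * np.eye(5)
        kern = KernelMatrix(nodes=list("abcde"), K=K)
        n1 = cosine_normalize(kern)
        n2 = cosine_normalize(KernelMatrix(nodes=list("abcde"), K=3.7 * K))
        assert np.allclose(np.diag(n1.K), 1.0)
        assert np.allclose(n1.K, n2.K)

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(5, 5))
        K = A @ A.T + 5 * np.eye(5)
        out = cosine_normalize(KernelMatrix(nodes=list("abcde"), K=K)).K
        for i in range(5):
            for j in range(5):
                assert out[i, j] == pytest.approx(
                    K[i, j] / np.sqrt(K[i, i] * K[j, j]), abs=1e-12
                )

    def test_zero_diagonal_raises_with_node_name(self):
        K = np.eye(3)
        K[1, 1] = 0.0
        with pytest.raises(ValueError, match="b"):
            cosine_normalize(KernelMatrix(nodes=list("abc"), K=K))


class TestConsensus:
    def _kern(self, nodes, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(len(nodes), len(nodes)))
        K = A @ A.T + len(nodes) * np.eye(len(nodes))
        return cosine_normalize(KernelMatrix(nodes=list(nodes), K=K))

    def test_empty_second_input_is_identity_operation(self):
        k1 = self._kern("abc", 0)
        out = consensus_kernel(k1, None)
        assert np.allclose(out.K, k1.K)

    def test_equal_kernels_unchanged(self):
        k1 = self._kern("abc", 1)
        out = consensus_kernel(k1, k1)
        assert np.allclose(out.K, k1.K)

    def test_union_embedding_elementwise_mean(self):
        k1 = self._kern("abcd", 2)
        k2 = self._kern("cdef", 3)
        out = consensus_kernel(k1, k2)
        assert out.nodes == list("abcdef")
        ix = out.index
        # overlap pair (c,d): plain mean of both kernels
        expected = 0.5 * k1.K[k1.index["c"], k1.index["d"]] + 0.5 * k2.K[
            k2.index["c"], k2.index["d"]
        ]
        assert out.K[ix["c"], ix["d"]] == pytest.approx(expected)
        # node only in k1 against node only in k2: both embeddings off-diagonal zero
        assert out.K[ix["a"], ix["f"]] == pytest.approx(0.0)
        # PSD preserved
        assert out.min_eigenvalue() >= -1e-8

    def test_disjoint_node_sets_warn(self):
        with pytest.warns(UserWarning, match="block diagonal"):
            consensus_kernel(self._kern("ab", 4), self._kern("cd", 5))


class TestMaterialize:
    def test_quantile_one_limit_keeps_base_edges_only(self):
        rng = np.random.default_rng(6)
        g = random_connected_graph(rng, 12)
        K = cosine_normalize(ct_kernel(g))
        out = materialize_network(K, g, extra_edge_quantile=1.0)
        assert set(map(frozenset, out.edges())) == set(map(frozenset, g.edges()))

    def test_added_edges_match_brute_force_sort(self):
        rng = np.random.default_rng(7)
        g = random_connected_graph(rng, 15)
        K = cosine_normalize(ct_kernel(g))
        q = 0.9
        out = materialize_network(K, g, q)
        base = set(map(frozenset, g.edges()))
        added = set(map(frozenset, out.edges())) - base
        # brute force: all non-base pairs above the q-quantile of their sims
        ix = K.index
        nonbase = [
            (a, b)
            for i, a in enumerate(K.nodes)
            for b in K.nodes[i + 1 :]
            if frozenset((a, b)) not in base
        ]
        sims = np.array([K.K[ix[a], ix[b]] for a, b in nonbase])
        cut = np.quantile(sims, q)
        expected = {frozenset(p) for p, s in zip(nonbase, sims) if s > cut}
        assert added == expected
        assert base <= set(map(frozenset, out.edges()))

    def test_idempotent_given_same_inputs(self):
        rng = np.random.default_rng(8)
        g = random_connected_graph(rng, 10)
        K = cosine_normalize(ct_kernel(g))
        e1 = sorted(map(tuple, map(sorted, materialize_network(K, g, 0.9).edges())))
        e2 = sorted(map(tuple, map(sorted, materialize_network(K, g, 0.9).edges())))
        assert e1 == e2


def test_adjacency_to_graph_threshold():
    adj = pd.DataFrame(
        [[0, 0.5, 0.0], [0.5, 0, 0.2], [0.0, 0.2, 0]],
        index=list("abc"), columns=list("abc"),
    )
    g = adjacency_to_graph(adj, min_weight=0.3)
    assert set(map(frozenset, g.edges())) == {frozenset(("a", "b"))}
    assert g.number_of_nodes() == 3
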