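"""Kernel correctness: components, oracle equivalence, PSD, estimator API."""

import random

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spgk.kernel import (
    KernelParams,
    ShortestPathGraphKernel,
    gram_matrix,
    k_edge,
    k_node,
    k_walk,
    spgk,
)

from conftest import (
    oracle_raw_kernel,
    random_connected_graph,
    sp_graph_via_bfs,
    term_graph_from_nx,
)


class TestComponents:
    def test_k_node_identity(self):
        assert k_node("GO:0005737", "GO:0005737") == 1
        assert k_node("GO:0005737", "GO:0005634") == 0

    @pytest.mark.parametrize(
        "l1,l2,expected",
        [(3, 3, 2.0), (1, 4, 0.0), (2, 3, 1.0), (5, 3, 0.0), (1, 2, 1.0)],
    )
    def test_k_edge_brownian_bridge(self, l1, l2, expected):
        assert k_edge(l1, l2, KernelParams(c=2)) == expected

    @given(st.integers(1, 20), st.integers(1, 20), st.floats(0.5, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_k_edge_symmetric_bounded(self, l1, l2, c):
        params = KernelParams(c=c)
        val = k_edge(l1, l2, params)
        assert val == k_edge(l2, l1, params)
        assert 0 <= val <= c
        if l1 == l2:
            assert val == c

    def test_c_must_be_positive(self):
        with pytest.raises(ValueError):
            KernelParams(c=0)

    def test_k_walk_matching_edge(self):
        e = (("a", "b"), 1)
        # one of the two orientations of e2 lines up with e1: 1 * c * 1
        assert k_walk(e, e, KernelParams(c=2)) == 2.0

    def test_k_walk_disjoint_labels(self):
        assert k_walk((("a", "b"), 1), (("c", "d"), 1)) == 0.0

    def test_k_walk_length_gap_beyond_c(self):
        assert k_walk((("a", "b"), 1), (("a", "b"), 4), KernelParams(c=2)) == 0.0

    def test_k_walk_orientation_invariant(self):
        params = KernelParams(c=2)
        assert k_walk((("a", "b"), 2), (("a", "b"), 3), params) == k_walk(
            (("a", "b"), 3), (("a", "b"), 2), params
        )


def _graph_pair(rng, max_vertices=12, shared_labels=8):
    """Two random graphs over partially overlapping label sets."""
    g1 = random_connected_graph(rng, max_vertices)
    g2 = random_connected_graph(rng, max_vertices)
    # relabel some of g2 into g1's label space so the kernel sees overlap
    mapping = {}
    labels1 = sorted(g1.nodes())
    for i, node in enumerate(sorted(g2.nodes())):
        if i < shared_labels and i < len(labels1):
            mapping[node] = labels1[i]
        else:
            mapping[node] = f"w{i:02d}"
    return g1, nx.relabel_nodes(g2, mapping)


class TestSpgk:
    def test_self_similarity_is_one(self):
        rng = random.Random(5)
        for _ in range(10):
            g = term_graph_from_nx(random_connected_graph(rng, 10))
            assert spgk(g, g) == 1.0

    def test_disjoint_label_sets_give_zero(self):
        g1 = term_graph_from_nx(nx.Graph([("a", "b")]))
        g2 = term_graph_from_nx(nx.Graph([("c", "d")]))
        assert spgk(g1, g2) == 0.0

    def test_degenerate_graph_yields_zero_not_error(self):
        single = term_graph_from_nx(nx.Graph(), "empty")
        g = term_graph_from_nx(nx.Graph([("a", "b")]))
        assert spgk(single, g) == 0.0
        assert spgk(single, single) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = random.Random(2024)
        params = KernelParams(normalize=False)
        for _ in range(30):
            g1, g2 = _graph_pair(rng)
            raw = spgk(
                sp_graph_via_bfs(g1), sp_graph_via_bfs(g2), params
            )
            expected = oracle_raw_kernel(g1, g2, c=2.0)
            assert raw == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_symmetry_bit_exact(self):
        rng = random.Random(77)
        for _ in range(20):
            g1, g2 = _graph_pair(rng)
            a = term_graph_from_nx(g1)
            b = term_graph_from_nx(g2)
            assert spgk(a, b) == spgk(b, a)

    def test_normalized_values_bounded(self):
        rng = random.Random(31)
        for _ in range(30):
            g1, g2 = _graph_pair(rng)
            val = spgk(term_graph_from_nx(g1), term_graph_from_nx(g2))
            assert 0.0 <= val <= 1.0 + 1e-12

    def test_monotone_under_shared_subgraph_duplication(self):
        # growing the shared structure in both graphs cannot reduce the raw kernel
        params = KernelParams(normalize=False)
        shared = [("s0", "s1"), ("s1", "s2")]
        g1 = nx.Graph(shared + [("s0", "x0")])
        g2 = nx.Graph(shared + [("s0", "y0")])
        base = spgk(term_graph_from_nx(g1), term_graph_from_nx(g2), params)
        g1.add_edge("s2", "s3")
        g2.add_edge("s2", "s3")
        grown = spgk(term_graph_from_nx(g1), term_graph_from_nx(g2), params)
        assert grown >= base


class TestGramMatrix:
    def test_single_graph(self):
        g = term_graph_from_nx(nx.Graph([("a", "b")]), "P1")
        m = gram_matrix([g])
        assert m.ids == ["P1"]
        assert m.values[0, 0] == 1.0

    def test_duplicated_graph_all_ones(self):
        g = term_graph_from_nx(nx.Graph([("a", "b"), ("b", "c")]), "P1")
        m = gram_matrix([g, g])
        assert np.allclose(m.values, 1.0)

    def test_positive_semidefinite(self):
        rng = random.Random(8)
        graphs = [
            term_graph_from_nx(random_connected_graph(rng, 10), f"P{i}")
            for i in range(10)
        ]
        m = gram_matrix(graphs)
        assert np.linalg.eigvalsh(m.values).min() >= -1e-8

    def test_diagonal_exactly_one(self):
        rng = random.Random(9)
        graphs = [
            term_graph_from_nx(random_connected_graph(rng, 8), f"P{i}")
            for i in range(5)
        ]
        m = gram_matrix(graphs)
        assert np.all(np.diag(m.values) == 1.0)

    def test_tsv_round_trip(self, tmp_path):
        rng = random.Random(10)
        graphs = [
            term_graph_from_nx(random_connected_graph(rng, 8), f"P{i}")
            for i in range(4)
        ]
        m = gram_matrix(graphs)
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        from spgk.kernel import SimilarityMatrix

        back = SimilarityMatrix.from_tsv(path)
        assert back.ids == m.ids
        assert np.allclose(back.values, m.values)


class TestEstimator:
    def test_fit_transform_equals_gram(self):
        rng = random.Random(12)
        graphs = [
            term_graph_from_nx(random_connected_graph(rng, 8), f"P{i}")
            for i in range(6)
        ]
        est = ShortestPathGraphKernel()
        gram = est.fit_transform(graphs)
        assert np.allclose(gram, gram_matrix(graphs).values)
        assert hasattr(est, "X_fit_")

    def test_transform_cross_kernel_consistent(self):
        rng = random.Random(13)
        graphs = [
            term_graph_from_nx(random_connected_graph(rng, 8), f"P{i}")
            for i in range(5)
        ]
        est = ShortestPathGraphKernel().fit(graphs[:3])
        cross = est.transform(graphs[3:])
        full = gram_matrix(graphs).values
        assert np.allclose(cross, full[3:, :3])

    def test_get_set_params_round_trip(self):
        est = ShortestPathGraphKernel(c=3.0, normalize=False)
        params = est.get_params()
        assert params == {"c": 3.0, "normalize": False}
        est.set_params(c=1.5)
        assert est.c == 1.5

    def test_unfitted_transform_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            ShortestPathGraphKernel().transform([])

    def test_invalid_input_type_raises(self):
        with pytest.raises(TypeError):
            ShortestPathGraphKernel().fit([nx.Graph([("a", "b")])])
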