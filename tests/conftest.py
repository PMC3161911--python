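"""Shared fixtures: tiny hand-built ontologies and random-graph helpers."""

import random

import networkx as nx
import pytest

from spgk.graphs import ShortestPathGraph, TermGraph
from spgk.ontology import OntologyDAG

NS = "biological_process"


def make_dag(edges, extra_terms=(), namespace=NS):
    """Build an OntologyDAG from (child, parent, relation) triples."""
    terms = {t for c, p, _ in edges for t in (c, p)} | set(extra_terms)
    return OntologyDAG(
        terms=terms,
        names={t: t for t in terms},
        namespaces={t: namespace for t in terms},
        edges=set(edges),
    )


@pytest.fixture
def chain_dag():
    """t3 is_a t2 is_a t1 (t1 is the root)."""
    return make_dag([("t3", "t2", "is_a"), ("t2", "t1", "is_a")])


@pytest.fixture
def diamond_dag():
    """t4 -> t2 -> t1 and t4 -> t3 -> t1."""
    return make_dag(
        [
            ("t4", "t2", "is_a"),
            ("t4", "t3", "part_of"),
            ("t2", "t1", "is_a"),
            ("t3", "t1", "is_a"),
        ]
    )


def random_connected_graph(rng: random.Random, max_vertices: int = 25) -> nx.Graph:
    """Random connected undirected unit-weight graph with string labels."""
    n = rng.randint(2, max_vertices)
    g = nx.Graph()
    labels = [f"v{i:02d}" for i in range(n)]
    g.add_nodes_from(labels)
    # random spanning tree guarantees connectivity
    order = labels[:]
    rng.shuffle(order)
    for i in range(1, n):
        g.add_edge(order[i], rng.choice(order[:i]))
    extra = rng.randint(0, n)
    for _ in range(extra):
        u, v = rng.sample(labels, 2)
        g.add_edge(u, v)
    return g


def term_graph_from_nx(g: nx.Graph, protein_id: str = "") -> TermGraph:
    edges = frozenset(tuple(sorted(e)) for e in g.edges())
    return TermGraph(
        vertices=frozenset(g.nodes()), edges=edges, protein_id=protein_id
    )


def sp_graph_via_bfs(g: nx.Graph, protein_id: str = "") -> ShortestPathGraph:
    """Independent shortest-path-graph construction: BFS from every vertex."""
    lengths = {}
    for source, dists in nx.all_pairs_shortest_path_length(g):
        for target, d in dists.items():
            if source < target and d > 0:
                lengths[(source, target)] = d
    return ShortestPathGraph(
        vertices=frozenset(g.nodes()), lengths=lengths, protein_id=protein_id
    )


def oracle_raw_kernel(g1: nx.Graph, g2: nx.Graph, c: float = 2.0) -> float:
    """Brute-force kernel: BFS distances, exhaustive edge pairs and orientations.

    Re-derives everything independently of the package: shortest
    distances by per-vertex BFS, then the double sum over shortest-path
    edge pairs, scoring both ordered orientations of the second edge
    against a fixed orientation of the first with
    identity-node x Brownian-bridge-edge x identity-node products.
    """

    def sp_edges(g):
        out = []
        for source, dists in nx.all_pairs_shortest_path_length(g):
            for target, d in dists.items():
                if source < target and d > 0:
                    out.append((source, target, d))
        return out

    total = 0.0
    for u1, v1, l1 in sp_edges(g1):
        for u2, v2, l2 in sp_edges(g2):
            bridge = max(0.0, c - abs(l1 - l2))
            for s, t in ((u2, v2), (v2, u2)):
                total += (1 if u1 == s else 0) * bridge * (1 if v1 == t else 0)
    return total
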