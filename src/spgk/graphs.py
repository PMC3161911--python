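"""Per-protein ontology subgraphs and their shortest-path transforms.

A protein is represented by the subgraph of the ontology induced by its
annotating terms together with all their ancestors; every ontology edge
between two included terms is kept, with unit length, and treated as
undirected for path computation (two sibling terms connect through their
common ancestor). The shortest-path graph keeps the same vertices and
places one edge per connected vertex pair whose length is the shortest
distance between them — the object the kernel operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import floyd_warshall

from .ontology import OntologyDAG


@dataclass(frozen=True)
class TermGraph:
    """Induced ontology subgraph for one protein: unit-length undirected edges."""

    vertices: frozenset
    edges: frozenset  # of (u, v) tuples with u < v
    protein_id: str = ""
    namespace: str = ""

    def __post_init__(self):
        for u, v in self.edges:
            if u >= v or u not in self.vertices or v not in self.vertices:
                raise ValueError(f"bad edge ({u}, {v})")


@dataclass(frozen=True)
class ShortestPathGraph:
    """Same vertices as the source graph; one edge per connected pair.

    ``lengths`` maps each (u, v) pair with u < v to the integer shortest
    distance between u and v in the source graph. Pairs at infinite
    distance (disconnected components) carry no edge, and there are no
    self-loops.
    """

    vertices: frozenset
    lengths: dict = field(default_factory=dict)  # (u, v) u < v -> int >= 1
    protein_id: str = ""
    namespace: str = ""

    @property
    def sp_edges(self) -> list:
        """Edges as ((u, v), length) tuples in sorted order."""
        return [(pair, self.lengths[pair]) for pair in sorted(self.lengths)]


def induced_subgraph(
    dag: OntologyDAG,
    terms: Iterable[str],
    protein_id: str = "",
    namespace: str = "",
    relations: Iterable[str] | None = None,
) -> TermGraph:
    """Build the ancestor-closed subgraph for a set of annotating terms.

    The vertex set is the union of ``terms`` and all their ancestors
    (through the relation types in ``relations``, default all); the edge
    set is every ontology edge of those types between two included
    vertices, stored unordered with unit length. An empty term set yields
    the empty graph.
    """
    closure: set = set()
    for term in terms:
        primary = dag.resolve(term)
        closure.add(primary)
        closure |= dag.ancestors(primary, relations=relations)
    allowed = None if relations is None else set(relations)
    edges = set()
    for child, parent, rel in dag.edges:
        if allowed is not None and rel not in allowed:
            continue
        if child in closure and parent in closure:
            edges.add((child, parent) if child < parent else (parent, child))
    return TermGraph(
        vertices=frozenset(closure),
        edges=frozenset(edges),
        protein_id=protein_id,
        namespace=namespace,
    )


def shortest_path_graph(graph: TermGraph) -> ShortestPathGraph:
    """All-pairs shortest distances of the undirected unit-length graph.

    Distances are exact integers. Floyd-Warshall (via
    :func:`scipy.sparse.csgraph.floyd_warshall`) is used; any all-pairs
    algorithm yielding the same distances is equivalent.
    """
    order = sorted(graph.vertices)
    n = len(order)
    if n == 0:
        return ShortestPathGraph(
            vertices=frozenset(),
            lengths={},
            protein_id=graph.protein_id,
            namespace=graph.namespace,
        )
    index = {v: i for i, v in enumerate(order)}
    rows, cols = [], []
    for u, v in graph.edges:
        rows.append(index[u])
        cols.append(index[v])
    adjacency = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    dist = floyd_warshall(adjacency, directed=False, unweighted=True)
    lengths = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if np.isfinite(d):
                lengths[(order[i], order[j])] = int(round(d))
    return ShortestPathGraph(
        vertices=frozenset(order),
        lengths=lengths,
        protein_id=graph.protein_id,
        namespace=graph.namespace,
    )


def build_protein_graph(
    dag: OntologyDAG,
    terms: Iterable[str],
    protein_id: str = "",
    namespace: str = "",
    relations: Iterable[str] | None = None,
) -> ShortestPathGraph:
    """Convenience: induced subgraph followed by the shortest-path transform."""
    return shortest_path_graph(
        induced_subgraph(
            dag, terms, protein_id=protein_id, namespace=namespace, relations=relations
        )
    )


# -- edge-list serialization (CLI --dump-graphs) -------------------------


def write_sp_graph_tsv(graph: ShortestPathGraph, path) -> None:
    """Write a shortest-path graph as a (u, v, length) TSV with a header line."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"# protein={graph.protein_id}\tnamespace={graph.namespace}\n")
        for v in sorted(graph.vertices):
            handle.write(f"# vertex\t{v}\n")
        for (u, v), length in graph.sp_edges:
            handle.write(f"{u}\t{v}\t{length}\n")


def read_sp_graph_tsv(path) -> ShortestPathGraph:
    """Inverse of :func:`write_sp_graph_tsv`."""
    path = Path(path)
    protein_id = namespace = ""
    vertices: set = set()
    lengths: dict = {}
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if line.startswith("# protein="):
                meta = dict(
                    part.split("=", 1) for part in line[2:].split("\t") if "=" in part
                )
                protein_id = meta.get("protein", "")
                namespace = meta.get("namespace", "")
            elif line.startswith("# vertex\t"):
                vertices.add(line.split("\t", 1)[1])
            elif line and not line.startswith("#"):
                u, v, length = line.split("\t")
                vertices.update((u, v))
                key = (u, v) if u < v else (v, u)
                lengths[key] = int(length)
    return ShortestPathGraph(
        vertices=frozenset(vertices),
        lengths=lengths,
        protein_id=protein_id,
        namespace=namespace,
    )
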