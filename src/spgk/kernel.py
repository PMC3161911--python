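"""Shortest-path graph kernel between proteins' ontology subgraphs.

The kernel compares two shortest-path graphs edge-by-edge: every pair of
edges, one from each graph, is scored with a walk kernel

    k_walk(e1, e2) = k_node(start1, start2) * k_edge(len1, len2) * k_node(end1, end2)

summed over the ordered orientations of ``e2`` against a fixed
orientation of ``e1``. The node kernel is the identity on term ids
(1 when the two terms are the same GO term, 0 otherwise) and the edge
kernel is a Brownian bridge on lengths,

    k_edge(l1, l2) = max(0, c - |l1 - l2|),

maximal (= c) at equal lengths and zero once the lengths differ by at
least ``c`` (default c = 2). The raw kernel is the double sum over all
edge pairs; cosine normalization k(x, y) / sqrt(k(x, x) k(y, y)) maps it
into [0, 1] with unit self-similarity.

Because the node kernel is an identity and a shortest-path graph carries
at most one edge per vertex pair, the double sum collapses to a single
sum of k_edge over the vertex pairs connected in *both* graphs. The
implementation exploits that; the exhaustive edge-pair loop lives in the
test suite as an independent oracle.

The kernel is positive semi-definite: the triangular edge kernel is PSD
on lengths, and the collapsed form is a sum of PSD kernels over
per-vertex-pair features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .graphs import ShortestPathGraph, TermGraph, shortest_path_graph

logger = logging.getLogger(__name__)


@dataclass
class KernelParams:
    """Kernel configuration.

    c : float
        Brownian bridge ceiling, in path-length units. Edge pairs whose
        lengths differ by ``c`` or more contribute nothing. Default 2.
    normalize : bool
        Apply cosine normalization (default). Raw kernel values grow
        with graph size; normalized values are comparable across
        proteins and lie in [0, 1].
    """

    c: float = 2.0
    normalize: bool = True

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("c must be positive")


def k_node(u: str, v: str) -> int:
    """Identity node kernel: 1 when the two term ids are equal, else 0."""
    return 1 if u == v else 0


def k_edge(len1: float, len2: float, params: KernelParams | None = None) -> float:
    """Brownian bridge edge kernel max(0, c - |len1 - len2|)."""
    c = (params or _DEFAULT_PARAMS).c
    return max(0.0, c - abs(len1 - len2))


def k_walk(e1, e2, params: KernelParams | None = None) -> float:
    """Walk kernel between two shortest-path edges with their endpoints.

    ``e1`` and ``e2`` are ``((u, v), length)`` tuples. The orientation of
    ``e1`` is fixed; both orientations of ``e2`` are scored and summed,
    which makes the result independent of how either unordered edge is
    stored.
    """
    (u1, v1), len1 = e1
    (u2, v2), len2 = e2
    edge_term = k_edge(len1, len2, params)
    total = 0.0
    for start, end in ((u2, v2), (v2, u2)):
        total += k_node(u1, start) * edge_term * k_node(v1, end)
    return total


def _raw_kernel(g1: ShortestPathGraph, g2: ShortestPathGraph, c: float) -> float:
    """Sum of k_walk over every edge pair, via the shared-vertex-pair identity.

    Iterates common (u, v) keys in sorted order so the accumulation is
    bit-identical regardless of argument order.
    """
    lengths1, lengths2 = g1.lengths, g2.lengths
    if len(lengths2) < len(lengths1):
        lengths1, lengths2 = lengths2, lengths1
    total = 0.0
    for pair in sorted(lengths1):
        if pair in lengths2:
            diff = abs(lengths1[pair] - lengths2[pair])
            if diff < c:
                total += c - diff
    return total


_DEFAULT_PARAMS = KernelParams()


def _coerce(graph) -> ShortestPathGraph:
    if isinstance(graph, ShortestPathGraph):
        return graph
    if isinstance(graph, TermGraph):
        return shortest_path_graph(graph)
    raise TypeError(
        f"expected ShortestPathGraph or TermGraph, got {type(graph).__name__}"
    )


def spgk(g1, g2, params: KernelParams | None = None) -> float:
    """Shortest-path graph kernel between two proteins' graphs.

    With ``params.normalize`` (default) returns the cosine-normalized
    value in [0, 1]; a degenerate side (empty graph, or a single vertex
    with no shortest-path edges, hence zero self-kernel) yields 0 with a
    logged warning rather than a division error.
    """
    params = params or _DEFAULT_PARAMS
    g1, g2 = _coerce(g1), _coerce(g2)
    raw = _raw_kernel(g1, g2, params.c)
    if not params.normalize:
        return raw
    self1 = _raw_kernel(g1, g1, params.c)
    self2 = _raw_kernel(g2, g2, params.c)
    if self1 == 0.0 or self2 == 0.0:
        which = g1.protein_id if self1 == 0.0 else g2.protein_id
        logger.warning(
            "zero self-kernel (empty or single-vertex graph) for %r; similarity 0",
            which,
        )
        return 0.0
    return raw / np.sqrt(self1 * self2)


class SimilarityMatrix:
    """Symmetric pairwise protein similarity matrix with an id index."""

    def __init__(self, ids, values):
        self.ids = list(ids)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")

    def __getitem__(self, pair):
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="protein")

    def to_long_tsv(self, path) -> None:
        """Upper-triangle pairs as (protein1, protein2, similarity) rows."""
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("protein1\tprotein2\tsimilarity\n")
            for i, a in enumerate(self.ids):
                for j in range(i + 1, len(self.ids)):
                    handle.write(f"{a}\t{self.ids[j]}\t{self.values[i, j]:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        frame = pd.read_csv(Path(path), sep="\t", index_col=0)
        return cls(list(frame.index), frame.to_numpy())


def gram_matrix(graphs, params: KernelParams | None = None) -> SimilarityMatrix:
    """Pairwise kernel matrix over a list of shortest-path graphs.

    Self-kernels are computed once and reused for normalization; the
    result is exactly symmetric.
    """
    params = params or _DEFAULT_PARAMS
    graphs = [_coerce(g) for g in graphs]
    if not graphs:
        raise ValueError("at least one graph is required")
    ids = [
        g.protein_id if g.protein_id else f"graph_{i}" for i, g in enumerate(graphs)
    ]
    n = len(graphs)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            raw[i, j] = raw[j, i] = _raw_kernel(graphs[i], graphs[j], params.c)
    if not params.normalize:
        return SimilarityMatrix(ids, raw)
    self_kernels = np.diag(raw).copy()
    values = np.zeros((n, n))
    for i in range(n):
        if self_kernels[i] == 0.0:
            logger.warning(
                "zero self-kernel for %r; its similarities are 0", ids[i]
            )
    nonzero = self_kernels > 0
    denom = np.sqrt(np.outer(self_kernels, self_kernels))
    np.divide(raw, denom, out=values, where=np.outer(nonzero, nonzero))
    np.fill_diagonal(values, np.where(nonzero, 1.0, 0.0))
    values = np.minimum(values, values.T, out=values)  # guard symmetry bit-exactly
    return SimilarityMatrix(ids, values)


class ShortestPathGraphKernel(BaseEstimator, TransformerMixin):
    """Scikit-learn compatible wrapper around the shortest-path graph kernel.

    ``fit`` stores a reference collection of graphs; ``transform``
    returns the kernel values between new graphs and the reference
    collection, and ``fit_transform`` the full Gram matrix — the usual
    graph-kernel estimator contract, so the result plugs into any
    sklearn model accepting a precomputed kernel.

    Parameters
    ----------
    c : float, default 2.0
        Brownian bridge ceiling of the edge kernel.
    normalize : bool, default True
        Cosine-normalize kernel values.
    """

    def __init__(self, c: float = 2.0, normalize: bool = True):
        self.c = c
        self.normalize = normalize

    def _params(self) -> KernelParams:
        return KernelParams(c=self.c, normalize=self.normalize)

    def fit(self, X, y=None):
        params = self._params()  # validates c
        self.X_fit_ = [_coerce(g) for g in X]
        if not self.X_fit_:
            raise ValueError("X must contain at least one graph")
        self.self_kernels_ = np.array(
            [_raw_kernel(g, g, params.c) for g in self.X_fit_]
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "X_fit_"):
            raise ValueError("ShortestPathGraphKernel is not fitted")
        params = self._params()
        graphs = [_coerce(g) for g in X]
        out = np.zeros((len(graphs), len(self.X_fit_)))
        row_selfs = np.array([_raw_kernel(g, g, params.c) for g in graphs])
        for i, gi in enumerate(graphs):
            for j, gj in enumerate(self.X_fit_):
                out[i, j] = _raw_kernel(gi, gj, params.c)
        if self.normalize:
            denom = np.sqrt(np.outer(row_selfs, self.self_kernels_))
            ok = denom > 0
            out = np.divide(out, denom, out=np.zeros_like(out), where=ok)
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        matrix = gram_matrix(self.X_fit_, self._params())
        return matrix.values
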