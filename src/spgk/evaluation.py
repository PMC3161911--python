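"""Correlating semantic with functional similarity and comparing methods.

The benchmark logic: pair up two similarity matrices over their shared
proteins (all unordered off-diagonal pairs), compute the Pearson
correlation between the semantic series and the functional gold series,
and compare two methods' correlations with the Fisher z-transformation
test. Higher correlation with the functional gold standard means the
semantic measure better reflects function.

Note the two correlations compared typically share the gold series, so
the independent-samples Fisher test is anticonservative; it is used here
because it is the standard reporting convention, and the report says so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kernel import SimilarityMatrix


@dataclass
class PairedSimilarities:
    """Aligned per-pair similarity series for a set of proteins.

    ``pairs`` holds unordered (i, j) protein-id pairs with i < j, in
    lexicographic order; ``x`` and ``y`` the corresponding similarity
    values from the two matrices.
    """

    pairs: list
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.pairs) == len(self.x) == len(self.y)):
            raise ValueError("pairs, x and y must have equal length")
        if len(self.pairs) < 3:
            raise ValueError("need at least 3 pairs")

    @property
    def n(self) -> int:
        return len(self.pairs)


def pair_similarities(
    matrix_a: SimilarityMatrix, matrix_b: SimilarityMatrix
) -> PairedSimilarities:
    """Align two similarity matrices on shared proteins, upper triangle only.

    Pairs are enumerated in fixed lexicographic order over the shared
    ids, so the result is invariant to each matrix's internal ordering.
    Self-pairs are excluded — they would trivially inflate correlations.
    """
    shared = sorted(set(matrix_a.ids) & set(matrix_b.ids))
    if len(shared) < 3:
        raise ValueError(
            f"matrices share only {len(shared)} proteins; need at least 3"
        )
    idx_a = {p: matrix_a.ids.index(p) for p in shared}
    idx_b = {p: matrix_b.ids.index(p) for p in shared}
    pairs, x, y = [], [], []
    for i, a in enumerate(shared):
        for b in shared[i + 1 :]:
            pairs.append((a, b))
            x.append(matrix_a.values[idx_a[a], idx_a[b]])
            y.append(matrix_b.values[idx_b[a], idx_b[b]])
    return PairedSimilarities(pairs=pairs, x=np.array(x), y=np.array(y))


def pearson(paired: PairedSimilarities) -> float:
    """Pearson product-moment correlation between the two series."""
    for name, series in (("x", paired.x), ("y", paired.y)):
        if np.ptp(series) == 0:
            raise ValueError(f"series {name} is constant; correlation undefined")
    r, _ = stats.pearsonr(paired.x, paired.y)
    return float(r)


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> tuple:
    """Fisher z-transformation test for the difference of two correlations.

    Returns ``(z_statistic, two_sided_p)`` where z_i = atanh(r_i) and the
    statistic is (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)), referred to the
    standard normal. Swapping the arguments negates the statistic and
    leaves the p-value unchanged.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the Fisher transformation")
    if min(n1, n2) < 4:
        raise ValueError("sample sizes must be at least 4")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    statistic = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(statistic))
    return statistic, min(p, 1.0)


def permuted_gold_correlation(
    semantic: SimilarityMatrix, pfam: dict, seed: int
) -> float:
    """Negative control: correlation after shuffling protein -> Pfam assignments.

    The Pfam family sets are permuted across the proteins of the
    semantic matrix with a seeded RNG, the gold matrix is rebuilt, and
    the Pearson correlation recomputed. A sound evaluation design drives
    this toward 0.
    """
    from .baselines import pfam_matrix  # local import avoids a cycle

    proteins = sorted(set(semantic.ids) & set(pfam))
    rng = np.random.default_rng(seed)
    shuffled = [pfam[p] for p in proteins]
    rng.shuffle(shuffled)
    permuted = dict(zip(proteins, shuffled))
    paired = pair_similarities(semantic, pfam_matrix(permuted, proteins))
    return pearson(paired)


def evaluation_rows(
    gold: SimilarityMatrix, methods: dict
) -> list:
    """Per-method correlation rows (method, r, n_pairs) against one gold matrix."""
    rows = []
    for name, matrix in methods.items():
        paired = pair_similarities(matrix, gold)
        rows.append((name, pearson(paired), paired.n))
    return rows
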