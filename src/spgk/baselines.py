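"""Set-overlap similarity baselines: simUI and Pfam functional similarity.

simUI is the intrinsic baseline the graph kernel is measured against: the
fraction of GO terms shared by two proteins over the terms in their
union, i.e. a Jaccard index over term sets — by default over the
ancestor-closed (induced) sets, so shared ancestry counts, with a
direct-annotation mode for sensitivity analysis.

Pfam functional similarity is the evaluation gold standard: the Jaccard
index of the two proteins' Pfam family sets F(P). Two proteins drawn
from the same families score 1; disjoint family membership scores 0.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .annotations import AnnotationCorpus
from .kernel import SimilarityMatrix
from .ontology import OntologyDAG


def _jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets score 0 (no evidence of similarity)."""
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def sim_ui(
    annotations1: Iterable[str],
    annotations2: Iterable[str],
    dag: OntologyDAG,
    mode: str = "induced",
) -> float:
    """simUI similarity between two proteins' GO term sets.

    ``mode="induced"`` (default) closes each set over its ancestors
    before taking the Jaccard index; ``mode="direct"`` uses the annotated
    terms as given. Unknown terms raise a lookup error.
    """
    if mode not in ("induced", "direct"):
        raise ValueError(f"mode must be 'induced' or 'direct', got {mode!r}")
    sets = []
    for annotations in (annotations1, annotations2):
        resolved = {dag.resolve(t) for t in annotations}
        if mode == "induced":
            closed = set(resolved)
            for term in resolved:
                closed |= dag.ancestors(term)
            sets.append(closed)
        else:
            sets.append(resolved)
    return _jaccard(sets[0], sets[1])


def pfam_similarity(f1: Iterable[str], f2: Iterable[str]) -> float:
    """Functional similarity between two proteins from their Pfam family sets."""
    return _jaccard(set(f1), set(f2))


def simui_matrix(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    proteins: list,
    namespace: str | None = None,
    mode: str = "induced",
) -> SimilarityMatrix:
    """Pairwise simUI matrix over ``proteins`` for one namespace view."""
    term_sets = [corpus.term_set(p, namespace) for p in proteins]
    n = len(proteins)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            values[i, j] = values[j, i] = sim_ui(
                term_sets[i], term_sets[j], dag, mode=mode
            )
    return SimilarityMatrix(proteins, values)


def pfam_matrix(pfam: dict, proteins: list) -> SimilarityMatrix:
    """Pairwise Pfam functional-similarity matrix over ``proteins``."""
    families = [pfam.get(p, set()) for p in proteins]
    n = len(proteins)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            values[i, j] = values[j, i] = pfam_similarity(families[i], families[j])
    return SimilarityMatrix(proteins, values)
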