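"""GAF annotation and Pfam mapping input, plus the protein-selection filter.

GO annotations arrive as GAF (Gene Association File) tab-separated rows
assigning a GO term to a database object (here: a protein), with a
qualifier, an evidence code and an aspect. Pfam family membership arrives
as a plain two-column table. Both feed :class:`AnnotationCorpus`, the
container the rest of the pipeline consumes.

The selection filter reproduces the benchmark protocol of ranking
proteins by annotation count and keeping the top *n* that are annotated
in all three GO namespaces and carry at least one Pfam family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .ontology import OntologyDAG, UnknownTermError

logger = logging.getLogger(__name__)

_GAF_MIN_COLUMNS = 15  # GAF 2.x defines 17; columns 16-17 are optional
_GAF_MAX_COLUMNS = 17


class GafParseError(ValueError):
    """Raised for structurally invalid GAF rows; names the line number."""


@dataclass
class AnnotationCorpus:
    """Protein annotations plus Pfam family membership.

    Attributes
    ----------
    annotations : dict
        Protein id -> set of ``(term id, namespace, evidence code)``
        triples, deduplicated on the (protein, term) level per namespace.
    pfam : dict
        Protein id -> set of Pfam family identifiers.
    metadata : dict
        Free-text provenance and parse statistics (dropped-row counts,
        alt_id resolutions).
    """

    annotations: dict = field(default_factory=dict)
    pfam: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def proteins(self) -> list:
        return sorted(self.annotations)

    def term_set(self, protein: str, namespace: str | None = None) -> set:
        """Direct annotation term ids for one protein, optionally per namespace."""
        triples = self.annotations.get(protein, set())
        return {
            term
            for term, ns, _ in triples
            if namespace is None or ns == namespace
        }

    def namespaces_of(self, protein: str) -> set:
        return {ns for _, ns, _ in self.annotations.get(protein, set())}

    def annotation_count(self, protein: str) -> int:
        """Distinct (term, namespace) pairs for ranking, pooled across namespaces."""
        return len({(t, ns) for t, ns, _ in self.annotations.get(protein, set())})


def parse_gaf(
    path,
    dag: OntologyDAG,
    evidence_filter: set | None = None,
) -> AnnotationCorpus:
    """Parse a GAF 2.x file against a loaded ontology.

    Rows are dropped when qualified with NOT, when the evidence code is
    outside ``evidence_filter`` (default: accept every code), or when the
    term does not resolve in ``dag`` (e.g. it belongs to a namespace the
    dag was not loaded with, or is obsolete). Alternate term ids resolve
    silently to their primary id; drop and resolution counts are logged
    and recorded in the corpus metadata.
    """
    path = Path(path)
    corpus = AnnotationCorpus(metadata={"source": str(path)})
    dropped_not = dropped_unknown = dropped_obsolete = dropped_evidence = 0
    resolved_alt = 0

    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip() or raw.startswith("!"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if not (_GAF_MIN_COLUMNS <= len(fields) <= _GAF_MAX_COLUMNS):
                raise GafParseError(
                    f"{path}: line {lineno}: expected {_GAF_MIN_COLUMNS}-"
                    f"{_GAF_MAX_COLUMNS} tab-separated columns, got {len(fields)}"
                )
            protein = fields[1]
            qualifier = fields[3]
            term = fields[4]
            evidence = fields[6]
            if "NOT" in qualifier.split("|"):
                dropped_not += 1
                continue
            if evidence_filter is not None and evidence not in evidence_filter:
                dropped_evidence += 1
                continue
            try:
                primary = dag.resolve(term)
            except UnknownTermError:
                dropped_unknown += 1
                continue
            if primary != term:
                resolved_alt += 1
            if primary in dag.obsolete:
                dropped_obsolete += 1
                continue
            if primary not in dag.terms:
                dropped_unknown += 1
                continue
            namespace = dag.namespaces[primary]
            corpus.annotations.setdefault(protein, set()).add(
                (primary, namespace, evidence)
            )

    corpus.metadata.update(
        dropped_not=dropped_not,
        dropped_unknown_terms=dropped_unknown,
        dropped_obsolete=dropped_obsolete,
        dropped_evidence=dropped_evidence,
        resolved_alt_ids=resolved_alt,
    )
    for key in ("dropped_unknown_terms", "dropped_obsolete", "resolved_alt_ids"):
        if corpus.metadata[key]:
            logger.warning("%s: %s = %d", path, key, corpus.metadata[key])
    return corpus


def parse_pfam_table(path) -> dict:
    """Parse a headerless two-column (protein, Pfam family) TSV into a mapping.

    Repeated protein rows accumulate; family sets are deduplicated. An
    empty file yields an empty mapping with a logged warning.
    """
    path = Path(path)
    mapping: dict = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GafParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            protein, family = parts[0], parts[1]
            mapping.setdefault(protein, set()).add(family)
    if not mapping:
        logger.warning("%s: empty Pfam mapping", path)
    return mapping


def select_top_annotated(
    corpus: AnnotationCorpus,
    n: int = 100,
    require_all_namespaces: bool = True,
    require_pfam: bool = True,
    allow_list: set | None = None,
) -> list:
    """Rank proteins by annotation count and return the top ``n`` ids.

    Eligibility flags are applied before ranking: membership in an
    optional ``allow_list`` (an offline stand-in for requiring presence
    in a curated database), annotation in all three namespaces, and at
    least one Pfam family. Annotation counts are distinct
    (term, namespace) pairs pooled across namespaces. Ties at rank ``n``
    break by lexicographic protein id, so the result is invariant under
    input-row permutation.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    all_namespaces = {
        ns for triples in corpus.annotations.values() for _, ns, _ in triples
    }
    eligible = []
    for protein in corpus.proteins():
        if allow_list is not None and protein not in allow_list:
            continue
        if require_all_namespaces and corpus.namespaces_of(protein) != all_namespaces:
            continue
        if require_pfam and not corpus.pfam.get(protein):
            continue
        eligible.append(protein)
    eligible.sort(key=lambda p: (-corpus.annotation_count(p), p))
    if len(eligible) < n:
        logger.warning(
            "only %d eligible proteins (requested %d); returning all", len(eligible), n
        )
    return eligible[:n]
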