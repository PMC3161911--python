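"""Loading and querying Gene Ontology style ontologies from OBO flat files.

The Gene Ontology (GO) consists of three separate vocabularies —
biological process (BP), molecular function (MF) and cellular component
(CC) — each structured as a directed acyclic graph whose nodes are terms
and whose edges are typed ``is_a`` / ``part_of`` / ``regulates``
relationships pointing from a child term to a more general parent.

:class:`OntologyDAG` is the validated in-memory form used by the rest of
the package: it answers ancestor queries (the transitive closure towards
the root) and resolves alternate term identifiers, which annotation files
routinely carry. Parsing is delegated to :mod:`obonet`; this module adds
line-numbered error reporting, namespace restriction, cycle detection and
the invariant checks the downstream graph construction relies on.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relationship types recognised in the ontology, child -> parent.
RELATIONS = ("is_a", "part_of", "regulates")

#: Accepted namespace spellings -> canonical OBO namespace.
NAMESPACE_ALIASES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
    "biological_process": "biological_process",
    "molecular_function": "molecular_function",
    "cellular_component": "cellular_component",
}

ALL_NAMESPACES = "ALL"


class OboParseError(ValueError):
    """Raised when an OBO file cannot be parsed; names the offending line."""


class OntologyValidationError(ValueError):
    """Raised when a parsed ontology violates a structural invariant."""


class UnknownTermError(KeyError):
    """Raised when a term identifier cannot be resolved in the ontology."""


def canonical_namespace(namespace: str) -> str:
    """Map a namespace selector (``BP`` or ``biological_process``...) to canonical form."""
    if namespace == ALL_NAMESPACES:
        return ALL_NAMESPACES
    try:
        return NAMESPACE_ALIASES[namespace]
    except KeyError:
        raise ValueError(
            f"unknown namespace {namespace!r}; expected one of "
            f"{sorted(set(NAMESPACE_ALIASES))} or {ALL_NAMESPACES!r}"
        ) from None


@dataclass
class OntologyDAG:
    """A validated ontology: typed child->parent edges over non-obsolete terms.

    Attributes
    ----------
    terms : set of str
        Non-obsolete term identifiers.
    names : dict
        Term id -> human-readable name.
    namespaces : dict
        Term id -> canonical namespace string.
    edges : set of (child, parent, relation) triples
        Typed edges between non-obsolete terms; relation is one of
        :data:`RELATIONS`.
    alt_ids : dict
        Alternate id -> primary id. Keys never collide with ``terms``.
    obsolete : set of str
        Identifiers of obsolete terms; never edge endpoints.
    """

    terms: set = field(default_factory=set)
    names: dict = field(default_factory=dict)
    namespaces: dict = field(default_factory=dict)
    edges: set = field(default_factory=set)
    alt_ids: dict = field(default_factory=dict)
    obsolete: set = field(default_factory=set)

    def __post_init__(self):
        self._parents = {}
        for child, parent, rel in sorted(self.edges):
            self._parents.setdefault(child, []).append((parent, rel))
        self.validate()

    # -- queries ---------------------------------------------------------

    def resolve(self, term: str) -> str:
        """Resolve an alternate id to its primary id; identity for primary ids."""
        if term in self.terms or term in self.obsolete:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise UnknownTermError(term)

    def __contains__(self, term: str) -> bool:
        return term in self.terms or term in self.alt_ids

    def ancestors(self, term: str, relations: Iterable[str] | None = None) -> set:
        """All terms reachable from ``term`` through child->parent edges.

        ``relations`` restricts traversal to the given relationship types
        (default: all three). The term itself is not included.
        """
        term = self.resolve(term)
        if term in self.obsolete:
            raise UnknownTermError(f"{term} is obsolete")
        if term not in self.terms:
            raise UnknownTermError(term)
        allowed = set(RELATIONS) if relations is None else set(relations)
        seen: set = set()
        queue = deque([term])
        while queue:
            node = queue.popleft()
            for parent, rel in self._parents.get(node, ()):
                if rel in allowed and parent not in seen:
                    seen.add(parent)
                    queue.append(parent)
        return seen

    def roots(self) -> set:
        """Terms with no outgoing (child->parent) edge."""
        have_parents = {c for c, _, _ in self.edges}
        return self.terms - have_parents

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        for child, parent, rel in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise OntologyValidationError(
                    f"edge ({child}, {parent}, {rel}) references an unknown "
                    "or obsolete term"
                )
            if rel not in RELATIONS:
                raise OntologyValidationError(f"unknown relation {rel!r}")
            if self.namespaces.get(child) != self.namespaces.get(parent):
                raise OntologyValidationError(
                    f"edge ({child}, {parent}) crosses namespaces"
                )
        collisions = set(self.alt_ids) & self.terms
        if collisions:
            raise OntologyValidationError(
                f"alt_id identifiers collide with primary terms: {sorted(collisions)[:5]}"
            )
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, p, _ in self.edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyValidationError(
                "ontology contains a cycle: "
                + " -> ".join(str(u) for u, _ in cycle)
                + f" -> {cycle[0][0]}"
            )


def _prevalidate_obo_lines(path: Path) -> None:
    """Cheap syntactic scan so malformed stanza lines get a line number."""
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("[") and line.endswith("]"):
                continue
            if ":" not in line:
                raise OboParseError(
                    f"{path}: malformed line {lineno}: {line!r} "
                    "(expected 'key: value' or a stanza header)"
                )


def _canonical_relation(rel: str) -> str | None:
    """Map OBO relationship labels onto the three GO relations; None drops the edge."""
    if rel in RELATIONS:
        return rel
    if rel.endswith("regulates"):  # positively_/negatively_regulates
        return "regulates"
    return None


def parse_obo(path, namespace: str = ALL_NAMESPACES) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Parameters
    ----------
    path : path-like
        OBO file with ``[Term]`` stanzas.
    namespace : str
        One of BP/MF/CC (long or short form) to restrict the view to a
        single vocabulary, or ``"ALL"`` (default) for all namespaces.

    Obsolete terms are retained (flagged, never edge endpoints).
    Relationship types other than is_a / part_of / *regulates are dropped
    with a logged count.
    """
    path = Path(path)
    namespace = canonical_namespace(namespace)
    _prevalidate_obo_lines(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # obonet raises bare ValueError without context
        raise OboParseError(f"{path}: {exc}") from exc

    dag = OntologyDAG.__new__(OntologyDAG)
    terms: set = set()
    names: dict = {}
    namespaces: dict = {}
    edges: set = set()
    alt_ids: dict = {}
    obsolete: set = set()
    dropped_relations = 0

    for term, data in graph.nodes(data=True):
        ns = data.get("namespace", "")
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(term)
            names[term] = data.get("name", term)
            continue
        if namespace != ALL_NAMESPACES and ns != namespace:
            continue
        terms.add(term)
        names[term] = data.get("name", term)
        namespaces[term] = ns
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term

    for child, parent, rel in graph.edges(keys=True):
        if child not in terms or parent not in terms:
            continue
        canonical = _canonical_relation(rel)
        if canonical is None:
            dropped_relations += 1
            continue
        edges.add((child, parent, canonical))

    if dropped_relations:
        logger.warning(
            "%s: dropped %d edges with unsupported relationship types",
            path,
            dropped_relations,
        )

    alt_ids = {a: p for a, p in alt_ids.items() if a not in terms}
    dag.terms = terms
    dag.names = names
    dag.namespaces = namespaces
    dag.edges = edges
    dag.alt_ids = alt_ids
    dag.obsolete = obsolete
    dag.__post_init__()
    return dag
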