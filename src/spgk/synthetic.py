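"""Synthetic ontologies, annotations and Pfam assignments for offline runs.

The generator emulates, at toy scale, the inputs of a GO semantic
similarity benchmark: a three-namespace ontology of layered DAGs (one
root per namespace, every non-root term drawing parents from strictly
shallower layers, so acyclicity holds by construction), a GAF annotation
corpus, and a protein -> Pfam family table.

The functional signal is planted through clusters: proteins are split
into functional clusters, each owning a pool of deep (specific) ontology
terms per namespace and a set of Pfam families. A protein draws most of
its annotations (``within_cluster_term_overlap``) from its cluster's
pool and its Pfam families from the cluster's set, so same-cluster pairs
are similar both semantically and functionally while cross-cluster pairs
are not — the premise that proteins with similar function should receive
high semantic similarity, made tunable.

All randomness flows through one :class:`numpy.random.Generator`
(PCG64), consumed in a fixed order, so a fixed seed yields byte-identical
OBO/GAF/TSV output across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import AnnotationCorpus
from .ontology import RELATIONS, OntologyDAG

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
_ASPECT = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}
_QUALIFIER = {
    "biological_process": "involved_in",
    "molecular_function": "enables",
    "cellular_component": "located_in",
}
_EVIDENCE_CODES = ("IEA", "IDA", "ISS")


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the package's reference corpus.

    seed : RNG seed (PCG64).
    n_terms : total ontology size, split evenly over the three namespaces.
    n_levels : DAG depth per namespace (root at level 0).
    parents_per_term : mean parent count per non-root term (>= 1).
    relation_mix : probabilities for is_a / part_of / regulates edges.
    n_proteins : corpus size.
    n_clusters : number of functional clusters.
    annotations_per_protein : mean direct annotations per protein per namespace.
    within_cluster_term_overlap : fraction of annotations drawn from the
        protein's cluster pool (the signal strength dial, in [0, 1]).
    pfam_families_per_cluster : Pfam families owned by each cluster.
    """

    seed: int = 42
    n_terms: int = 150
    n_levels: int = 5
    parents_per_term: float = 1.5
    relation_mix: dict = field(
        default_factory=lambda: {"is_a": 0.7, "part_of": 0.2, "regulates": 0.1}
    )
    n_proteins: int = 40
    n_clusters: int = 2
    annotations_per_protein: float = 8.0
    within_cluster_term_overlap: float = 0.9
    pfam_families_per_cluster: int = 4

    def validate(self) -> None:
        if self.n_terms < 3 or self.n_levels < 2:
            raise ValueError("need n_terms >= 3 and n_levels >= 2")
        if self.parents_per_term < 1:
            raise ValueError("parents_per_term must be >= 1")
        if set(self.relation_mix) - set(RELATIONS):
            raise ValueError(f"relation_mix keys must be within {RELATIONS}")
        if not np.isclose(sum(self.relation_mix.values()), 1.0):
            raise ValueError("relation_mix probabilities must sum to 1")
        if self.n_proteins < 1 or self.n_clusters < 1:
            raise ValueError("n_proteins and n_clusters must be positive")
        if self.n_clusters > self.n_proteins:
            raise ValueError("n_clusters cannot exceed n_proteins")
        if not 0.0 <= self.within_cluster_term_overlap <= 1.0:
            raise ValueError("within_cluster_term_overlap must lie in [0, 1]")
        if self.annotations_per_protein < 1:
            raise ValueError("annotations_per_protein must be >= 1")
        if self.pfam_families_per_cluster < 1:
            raise ValueError("pfam_families_per_cluster must be positive")


def _term_id(ns_index: int, i: int) -> str:
    return f"GO:9{ns_index}{i:05d}"


def generate_ontology(cfg: SyntheticConfig) -> OntologyDAG:
    """Layered random DAG per namespace with typed edges; see module docs."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    relations = list(RELATIONS)
    probs = np.array([cfg.relation_mix.get(r, 0.0) for r in relations])

    terms: set = set()
    names: dict = {}
    namespaces: dict = {}
    edges: set = set()
    per_ns = max(cfg.n_terms // len(NAMESPACES), 2)

    for k, ns in enumerate(NAMESPACES):
        layer_of = {}
        by_layer: dict = {0: [_term_id(k, 0)]}
        root = _term_id(k, 0)
        layer_of[root] = 0
        for i in range(1, per_ns):
            # deterministic non-decreasing layer assignment keeps every
            # layer populated; randomness lives in parent choice
            layer = 1 + (i - 1) * (cfg.n_levels - 1) // max(per_ns - 1, 1)
            layer = min(layer, cfg.n_levels - 1)
            tid = _term_id(k, i)
            layer_of[tid] = layer
            by_layer.setdefault(layer, []).append(tid)
        for i in range(per_ns):
            tid = _term_id(k, i)
            terms.add(tid)
            names[tid] = f"synthetic term {k}.{i}"
            namespaces[tid] = ns
            layer = layer_of[tid]
            if layer == 0:
                continue
            shallower = [t for t in sorted(layer_of) if layer_of[t] < layer]
            n_parents = min(
                1 + rng.poisson(cfg.parents_per_term - 1.0), len(shallower)
            )
            parents = rng.choice(shallower, size=n_parents, replace=False)
            for parent in parents:
                rel = relations[rng.choice(len(relations), p=probs)]
                edges.add((tid, str(parent), rel))

    return OntologyDAG(
        terms=terms, names=names, namespaces=namespaces, edges=edges
    )


def generate_corpus(cfg: SyntheticConfig, dag: OntologyDAG) -> AnnotationCorpus:
    """Cluster-coupled annotations and Pfam families over a generated ontology."""
    cfg.validate()
    # independent stream from the ontology's, offset so the two never overlap
    rng = np.random.default_rng(cfg.seed + 1_000_003)

    deep_pool: dict = {}
    all_terms: dict = {}
    roots = dag.roots()
    for ns in NAMESPACES:
        ns_terms = sorted(t for t in dag.terms if dag.namespaces[t] == ns)
        non_root = [t for t in ns_terms if t not in roots]
        all_terms[ns] = non_root
        # deep (specific) terms: below the first generated layer
        depth = {t: len(dag.ancestors(t)) for t in non_root}
        deep = [t for t in non_root if depth[t] >= 2] or non_root
        deep = list(deep)
        rng.shuffle(deep)
        chunk = max(len(deep) // cfg.n_clusters, 1)
        deep_pool[ns] = [
            deep[c * chunk : (c + 1) * chunk] or deep for c in range(cfg.n_clusters)
        ]

    cluster_families = [
        {f"PF9{c:02d}{j:02d}" for j in range(cfg.pfam_families_per_cluster)}
        for c in range(cfg.n_clusters)
    ]

    corpus = AnnotationCorpus(metadata={"source": f"synthetic(seed={cfg.seed})"})
    for i in range(cfg.n_proteins):
        protein = f"SP{i:04d}"
        cluster = i % cfg.n_clusters
        for ns in NAMESPACES:
            count = 1 + rng.poisson(cfg.annotations_per_protein - 1.0)
            for _ in range(count):
                if rng.random() < cfg.within_cluster_term_overlap:
                    pool = deep_pool[ns][cluster]
                else:
                    pool = all_terms[ns]
                term = pool[rng.choice(len(pool))]
                evidence = _EVIDENCE_CODES[rng.choice(len(_EVIDENCE_CODES))]
                corpus.annotations.setdefault(protein, set()).add(
                    (term, ns, evidence)
                )
        corpus.pfam[protein] = set(cluster_families[cluster])
    return corpus


# -- serialization -------------------------------------------------------


def write_obo(dag: OntologyDAG, path) -> None:
    """Serialize an ontology as a sorted, deterministic OBO 1.2 file."""
    children: dict = {}
    for child, parent, rel in sorted(dag.edges):
        children.setdefault(child, []).append((rel, parent))
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for term in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.names.get(term, term)}")
        lines.append(f"namespace: {dag.namespaces[term]}")
        for rel, parent in sorted(children.get(term, [])):
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! {dag.names.get(parent, parent)}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def write_gaf(corpus: AnnotationCorpus, path) -> None:
    """Serialize annotations as a sorted, deterministic GAF 2.2 file."""
    lines = ["!gaf-version: 2.2"]
    for protein in sorted(corpus.annotations):
        for term, ns, evidence in sorted(corpus.annotations[protein]):
            cols = [
                "UniProtKB", protein, protein, _QUALIFIER[ns], term,
                "GO_REF:0000001", evidence, "", _ASPECT[ns], "", "",
                "protein", "taxon:9606", "20110729", "SYNTH", "", "",
            ]
            lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_pfam_table(corpus: AnnotationCorpus, path) -> None:
    """Serialize the protein -> Pfam mapping as a sorted two-column TSV."""
    lines = [
        f"{protein}\t{family}"
        for protein in sorted(corpus.pfam)
        for family in sorted(corpus.pfam[protein])
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def generate_files(cfg: SyntheticConfig, outdir) -> dict:
    """Generate ontology + corpus and write the three standard files.

    Returns the paths keyed ``obo`` / ``gaf`` / ``pfam``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dag = generate_ontology(cfg)
    corpus = generate_corpus(cfg, dag)
    paths = {
        "obo": outdir / "synthetic.obo",
        "gaf": outdir / "synthetic.gaf",
        "pfam": outdir / "synthetic_pfam.tsv",
    }
    write_obo(dag, paths["obo"])
    write_gaf(corpus, paths["gaf"])
    write_pfam_table(corpus, paths["pfam"])
    return paths
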