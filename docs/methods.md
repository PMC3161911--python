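# Methods

## Protein graphs

A protein's representation in one GO namespace is the subgraph induced
by its directly annotated terms plus all their ancestors, reached
through is_a, part_of and regulates edges alike (a `relations` argument
restricts the closure, e.g. to is_a only, for sensitivity analysis).
Every ontology edge between two included terms is kept. Edges carry unit
length regardless of relation type: the method deliberately does not
weight relation types or depth, and the node comparison uses only term
identity.

Shortest paths are computed on the **undirected** view of this subgraph.
Direction matters here: in the directed child→parent ontology, two
sibling terms have no connecting path, so a directed reading would make
the kernel blind to exactly the term pairs (close siblings) it should
reward. Undirected paths let siblings connect through their common
ancestor at distance 2. Distances are exact integers (unit weights);
the transform uses `scipy.sparse.csgraph.floyd_warshall`, and the test
suite verifies the distances against an independent per-vertex BFS.
Vertex pairs in different connected components (possible when a
namespace has several roots, as synthetic multi-root ontologies can)
simply carry no shortest-path edge.

## The kernel

With shortest-path graphs G1sp, G2sp, the raw kernel is the double sum
of walk kernels over all edge pairs. A walk kernel multiplies the
identity kernel on the two start nodes, the Brownian bridge kernel
max(0, c − |l1 − l2|) on the two lengths, and the identity kernel on the
two end nodes, summed over the two orientations of the second edge
against a fixed orientation of the first. Summing (rather than taking a
maximum over orientations) keeps the kernel a sum of products of
positive semi-definite factors, hence positive semi-definite.

Two numerical identities shape the implementation:

* Since the node kernel is an identity on term ids and a shortest-path
  graph has at most one edge per vertex pair, a walk kernel is nonzero
  only when the two edges span the *same* unordered term pair, and then
  exactly one orientation matches. The double sum therefore collapses to
  Σ max(0, c − |d1(u,v) − d2(u,v)|) over the vertex pairs connected in
  both graphs. The implementation iterates this intersection in sorted
  key order (bit-exact symmetry); the test suite holds it equal, to
  relative error 1e−12, to a brute-force double loop that re-derives
  distances by BFS and enumerates orientations exhaustively.
* The raw self-kernel of a graph with l shortest-path edges is c·l, so
  cosine normalization is always well defined for graphs with at least
  one edge. Degenerate graphs (no annotations, or a single annotated
  root term) have a zero self-kernel; their similarity is defined as 0
  with a logged warning rather than an error, since absence of
  annotation is not evidence of similarity.

Parameters: `c` (default 2, length units) sets how much two path
lengths may differ and still be considered comparable — with integer
distances and c = 2, only equal lengths (weight 2) and lengths differing
by 1 (weight 1) contribute. `normalize` (default on) rescales to [0, 1]
with unit self-similarity; raw values are available for diagnostics.
Whether to normalize before correlating is a genuinely open design
point; normalization is the default here because it puts the kernel on
the same [0, 1] scale as simUI and the Pfam gold standard, and Pearson
correlation is unaffected by the linear part of any rescaling.

Complexity is O(n³) for the Floyd–Warshall transform and O(E′₁ + E′₂)
per protein pair after the collapse (the naive edge-pair sum would be
O(n⁴)); Gram matrices over hundreds of proteins take seconds.

## Baselines and gold standard

simUI is the Jaccard index of the two proteins' term sets. The default
uses ancestor-closed sets — simUI is a graph union/intersection measure
in the literature, and closing over ancestors is what makes it use the
ontology structure at all — with a `direct` mode on the raw annotation
sets for comparison. The functional gold standard is the Jaccard index
of the proteins' Pfam family sets. Empty-vs-empty sets score 0, not 1,
in both measures: missing annotation carries no evidence.

## Evaluation protocol

The protein universe is the top n (default 100) proteins by distinct
(term, namespace) annotation count, pooled across namespaces, required
to be annotated in all three namespaces and to carry at least one Pfam
family; an optional allow-list file stands in for membership checks
against a curated protein database, keeping the tool offline. Ties at
the cutoff break lexicographically so selection is deterministic under
input permutation.

Correlations are computed over all C(n, 2) unordered protein pairs
(self-pairs excluded — they would trivially inflate every method).
Methods are compared with the Fisher z-transformation test using the
pair count as the sample size. Two caveats are inherent and reported:
the compared correlations share the gold series, so the
independent-samples test is anticonservative (a dependent-correlation
test such as Steiger's is out of scope), and pairs built from n
proteins are not mutually independent, so the nominal sample size
overstates the information content. The evaluation report carries a
note to this effect.

## Synthetic corpus

The generator emulates the benchmark inputs at desk scale. Ontology:
150 terms split over the three GO namespaces, each namespace a layered
DAG of depth 5 with a single root; layer assignment is deterministic
(terms spread evenly over layers) and each non-root term draws
1 + Poisson(0.5) parents uniformly from strictly shallower layers, so
the graph is acyclic by construction; edge types are drawn
is_a/part_of/regulates with probabilities 0.7/0.2/0.1, roughly the mix
observed in the GO. Corpus: 40 proteins in 2 functional clusters
(round-robin assignment). Each cluster owns a pool of deep terms
(≥ 2 ancestors) per namespace and 4 Pfam families. A protein draws
1 + Poisson(7) direct annotations per namespace, each from its cluster
pool with probability `within_cluster_term_overlap` (default 0.9) and
uniformly from the namespace otherwise, and carries its cluster's full
Pfam family set — so the gold standard is a clean same-cluster
indicator, and the semantic signal strength is controlled by a single
dial. The annotation density reflects the selection protocol being
emulated, which deliberately targets heavily annotated proteins because
functional similarity estimates are unreliable for sparsely annotated
ones.

All randomness comes from NumPy's PCG64 generator; the ontology and the
corpus use seed-offset streams consumed in fixed order, and all writers
emit sorted records, so a fixed seed reproduces the OBO/GAF/TSV files
byte for byte.

What the generator does **not** emulate: the GO's term-frequency and
annotation-count distributions (real GOA annotation counts are heavily
skewed), evidence-code structure, obsolete terms and alt_ids in bulk
(these are covered by small hand-written parser fixtures instead),
cross-namespace annotation correlation, and any sequence- or EC-based
gold standard. Passing the planted-signal tests therefore shows the
pipeline recovers a known annotation/function coupling end to end — not
that correlation magnitudes on real GOA/Pfam data will match; those
depend on the specific GO/GOA/Pfam releases used.

## Problem sizes in tests and the acceptance run

The test suite exercises distances on 200 random graphs of up to 25
vertices, kernel-oracle equality on 100 random pairs of up to 12
vertices, PSD checks on 20-graph Gram matrices, and signal recovery on
the default 40-protein corpus (780 pairs), with the overlap-monotonicity
check running 10 seeds at overlaps 0.1/0.5/0.9 in the biological_process
namespace. These sizes give each property enough randomization to be
meaningful while keeping the whole suite and the acceptance script in
the seconds-to-a-minute range on one CPU.

## Known limitations

* The node kernel is a strict identity: near-synonymous sibling terms
  contribute only through path structure, never through term content.
* Relation types are structurally interchangeable; regulates edges in
  particular arguably carry different semantics than is_a.
* Raw kernel values grow with annotation richness; comparisons across
  proteins with very different annotation depths should use the
  normalized kernel.
* The Fisher comparison is anticonservative for methods evaluated
  against a shared gold standard (see above).
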