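# spgk — shortest-path graph kernel semantic similarity for gene products

Computational methods that score the functional relatedness of two gene
products from their Gene Ontology (GO) annotations usually lean on
*information content* — term frequencies counted in an external
annotation corpus — so the score for a fixed pair of proteins drifts as
annotation databases grow and research fashions shift. This package
implements an **intrinsic** alternative: each protein is represented by
the subgraph of the GO induced by its annotating terms and all their
ancestors, and similarity is a **shortest-path graph kernel** between
those subgraphs, computed from the ontology structure alone.

It is aimed at computational biologists who want ontology-only semantic
similarity (e.g. for clustering genes, screening protein-protein
interaction candidates, or benchmarking annotation pipelines) and at
method developers who need the standard evaluation harness — the simUI
baseline, a Pfam-derived functional gold standard, Pearson correlation,
and the Fisher z-test — without downloading versioned GO/GOA/Pfam
releases: a synthetic corpus generator reproduces the whole study design
offline.

## The method

For a protein *P* annotated with terms *T(P)* in one GO namespace, build
the induced subgraph *G = (V, E)* where *V* = *T(P)* ∪ ancestors(*T(P)*)
and *E* contains every ontology edge (is_a, part_of, regulates) between
two included terms, with unit length. Transform *G* into its
shortest-path graph *G*<sub>sp</sub> = (*V*, *E*′): one edge per
connected vertex pair (*u*, *v*), of length *d*(*u*, *v*), the shortest
distance in *G* (computed with Floyd–Warshall, or any all-pairs
algorithm producing the same distances).

The kernel between two proteins compares every pair of shortest-path
edges, one from each graph:

    K(G1, G2) = Σ_{e1 ∈ E'1} Σ_{e2 ∈ E'2} k_walk(e1, e2)

where a walk is an edge plus its two end nodes and

    k_walk(e1, e2) = k_node(v1, v2) · k_edge(l1, l2) · k_node(w1, w2)

summed over the orientations of *e2* against a fixed orientation of
*e1*. The node kernel is the identity on term ids; the edge kernel is a
Brownian bridge on lengths, k_edge(l1, l2) = max(0, c − |l1 − l2|) with
c = 2 by default. Scores are cosine-normalized,
K(x, y)/√(K(x, x)·K(y, y)), into [0, 1].

Baselines and evaluation: **simUI** is the Jaccard index of the two
proteins' (ancestor-closed) term sets; the functional gold standard is
the Jaccard index of their Pfam family sets; methods are scored by the
Pearson correlation of semantic vs. functional similarity over all
protein pairs, and two methods are compared by the Fisher
z-transformation test.

## Worked example

Generate the reference synthetic corpus (40 proteins in 2 functional
clusters over a 150-term, three-namespace ontology) and run the full
evaluation:

```bash
spgk synth --out demo --seed 42
spgk evaluate --obo demo/synthetic.obo --gaf demo/synthetic.gaf \
    --pfam demo/synthetic_pfam.tsv --top-n 40 --permute-seed 7 --out demo/eval
```

which prints:

```
Semantic vs functional similarity over 40 proteins
  biological_process     spgk                 r = +0.3955  n = 780
  biological_process     simui                r = +0.3867  n = 780
  biological_process     spgk_permuted_gold   r = -0.0321  n = 780  (negative control)
  molecular_function     spgk                 r = +0.5151  n = 780
  molecular_function     simui                r = +0.4964  n = 780
  molecular_function     spgk_permuted_gold   r = +0.0465  n = 780  (negative control)
  cellular_component     spgk                 r = +0.5236  n = 780
  cellular_component     simui                r = +0.4988  n = 780
  cellular_component     spgk_permuted_gold   r = +0.0035  n = 780  (negative control)
  biological_process     Fisher z (spgk vs simUI) = +0.2041, two-sided p = 0.8382
  molecular_function     Fisher z (spgk vs simUI) = +0.4940, two-sided p = 0.6213
  cellular_component     Fisher z (spgk vs simUI) = +0.6615, two-sided p = 0.5083
```

Reading the output: over the 780 unordered protein pairs, the kernel's
similarities correlate positively with the Pfam gold standard in every
namespace and slightly above simUI, while the permuted-gold control sits
near zero — the correlation really comes from the planted
annotation/function coupling, not from scale artifacts. At this corpus
size the spgk–simUI difference is not statistically significant (Fisher
p ≫ 0.05).

Other subcommands: `spgk select` (top-N most-annotated protein filter),
`spgk compute` (one similarity matrix; `--method spgk|simui`,
`--dump-graphs` writes per-protein edge lists). Real GO/GOA/Pfam files
in OBO, GAF 2.x and two-column TSV formats are accepted by the same
flags.

The kernel is also exposed as a scikit-learn compatible estimator:

```python
from spgk import ShortestPathGraphKernel, build_protein_graph
est = ShortestPathGraphKernel(c=2.0, normalize=True)
gram = est.fit_transform(graphs)          # precomputed kernel for sklearn models
cross = est.transform(new_graphs)         # kernel against the fitted collection
```

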