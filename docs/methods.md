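# Methods

`mgnet` implements a seeded network analysis of membranous
glomerulonephritis (MGN), an immune-mediated nephrotic syndrome: starting
from curated immune-gene and disease-gene lists and an undirected
protein–protein interaction (PPI) network, it extracts disease-centred
neighbor subnetworks, characterises their topology, detects densely
connected modules, overlays case/control expression data, and tests module
gene sets for over-representation. This note records the model choices,
parameter defaults, numerical conventions and known limitations.

## Seeded subnetwork construction

Two nested subnetworks are built by the same operation:

* **IOMDN** (immune-or-MGN-directed neighbor network): seeds are the union
  of the immune and disease gene lists; the node set is every seed present
  in the PPI network plus all of its direct interactors; the edge set is
  the *induced* subgraph on those nodes.
* **MGND** (MGN-directed network): the same construction applied to the
  IOMDN with the disease genes alone as seeds (a flag allows extraction
  from the full PPI instead, for sensitivity analysis).

Keeping induced (neighbor–neighbor) edges rather than only seed–neighbor
stars is deliberate: dense modules among non-seed genes can only exist if
their mutual edges survive extraction. Two invariants follow and are
enforced by tests: MGND ⊆ IOMDN in both nodes and edges, and every
retained edge joins two nodes each of which is a seed or adjacent to one.
Edge retention is reported as `|E(sub)| / |E(base)|`, rendered as a
percentage with two decimals.

Gene identity is the uppercased symbol string throughout; no alias or
identifier mapping is attempted. This keeps results deterministic and
independent of annotation snapshots, at the cost of losing genes whose
symbols differ between sources; the loaders log how many seed symbols
found no network match.

## Topology statistics

For a simple undirected graph with `N` nodes and `E` edges:
density `2E / N(N−1)`; mean degree `2E / N`; local clustering of node `v`
with degree `d(v) ≥ 2` is `2·e(N(v)) / d(v)(d(v)−1)` where `e(N(v))`
counts edges among `v`'s neighbors, and is defined as 0 for `d(v) < 2`.
Degree-0/1 nodes are *included* in the mean clustering (the convention of
common network-analyzer tools; the alternative — excluding them — is not
exposed). A graph with fewer than two nodes reports density 0 with a
warning rather than failing.

The scale-free check is descriptive, not inferential: ordinary least
squares of `log10 N(k)` on `log10 k` over occupied histogram bins with
`k ≥ 1`. With fewer than two such bins the slope and r² are NaN (emitted
as `null` in reports). A maximum-likelihood power-law exponent fit was
considered and rejected: the claim being supported is qualitative
("heavy-tailed"), and the OLS slope is the statistic readers of such
analyses expect to see.

Hub ranking is by degree, ties broken lexicographically by symbol, so
reports are stable across runs and platforms.

## Module detection (MCODE)

The molecular-complex-detection algorithm is implemented from scratch in
three stages.

1. *Vertex weighting.* For each vertex `v` with degree ≥ `degree_cutoff`,
   take the closed neighborhood `N[v]`, find its highest k-core by
   iterative minimum-degree peeling, and set
   `w(v) = k_max · density(core)`. Vertices below the cutoff (and isolated
   vertices) weigh 0.
2. *Complex prediction.* Seed from the highest-weight unvisited vertex and
   expand breadth-first (depth ≤ `max_depth`), absorbing unvisited
   neighbors with `w(u) > w(seed) · (1 − node_score_cutoff)`. Absorbed
   vertices are globally marked visited, so complexes are node-disjoint.
3. *Post-processing.* Discard candidates containing no `k_core`-core;
   optionally *fluff* (add boundary vertices whose closed-neighborhood
   density exceeds `fluff_density_cutoff`; fluffed vertices may overlap
   between complexes); if *haircut*, iteratively remove vertices with
   fewer than two connections inside the complex. Score = density × size.

Defaults are the reference tool's: loops excluded, degree cutoff 2, node
score cutoff 0.2, k-core 2, haircut on, fluff off, fluff density cutoff
0.1, max depth 100. Where the published algorithm leaves order
unspecified (equal-weight seeds, neighbor visit order), ties break
lexicographically on the symbol; a property test asserts the output is
invariant to node insertion order.

Two module orderings are emitted: the algorithm's own score ordering, and
the analysis ordering by node count (size desc, then score desc, then
smallest member), which selects the "top n modules" carried into the
expression and enrichment stages.

One behaviour worth noting: on a pure cycle every vertex weighs 2/3 and
the expansion threshold (80 % of the seed weight) is below that, so the
whole cycle is absorbed into a single candidate, which is its own 2-core
and survives the haircut. Sparse but regular structures can therefore form
low-scoring modules; the density-times-size score keeps them at the bottom
of the ranking.

`nx.core_number` and brute-force pair/triple counting serve as independent
oracles in the tests; the implementation itself never calls them.

## Expression overlay

Edge co-expression uses Pearson correlation over the **disease samples
only** (a flag allows all samples), with pairwise-complete observations
per edge and the per-edge sample count recorded. Significance is the
two-sided t transform, `t = r·sqrt((n−2)/(1−r²))` on `n−2` degrees of
freedom. Exactly collinear pairs (|r| at 1 within float rounding) are
flagged degenerate and given the smallest positive float as p rather than
0, keeping p in (0, 1]. Zero-variance genes, missing genes and edges with
fewer than four complete pairs yield records flagged invalid and excluded
from summaries.

An edge is *significant* at raw two-sided p < 0.05 (configurable) and
*strong* when |r| > 0.5; the strong share is reported among significant
edges. The strong rule uses the absolute value deliberately: correlations
of either sign count, since anti-correlated interaction partners are as
informative as correlated ones.

Differential expression is an unpaired two-sided t-test per gene, disease
vs control, **Welch by default** (21 vs 18 samples with no variance
homogeneity guarantee); the pooled-variance Student variant is available
to mirror older pipelines. Direction is the sign of
(mean disease − mean control). Genes with fewer than three observations in
either group are skipped with a warning.

No multiple-testing correction is applied to the significant/differential
*flags* — raw p-values drive them, matching how such network overlays are
usually reported — but Benjamini–Hochberg q-values are always computed and
written next to every p, clearly labelled, so FDR-controlled reading needs
no recomputation.

## Over-representation

The hypergeometric upper tail `P(X ≥ k)` tests the overlap `k` between a
query set of size `n` and a term of size `K` over a background of size
`N`, with BH adjustment across the terms of a collection. The default
background is the analyzed (MGND) network's gene set — the sampling frame
from which module genes were actually drawn — configurable to the
collection's universe or a user file. Query genes outside the background
are dropped with a warning, and term sizes are restricted to the
background. Terms are called enriched at p < 0.01. Enriched drug-target
terms are flattened to a bipartite (term, gene) edge list for the
drug–gene network output.

## Synthetic benchmark generator

The generator produces the structures the statistics assume, with full
ground truth:

* **Graph**: a Barabási–Albert preferential-attachment background
  (default 500 nodes, 2 edges per arrival — heavy-tailed like curated PPI
  networks) with planted dense modules (default one module of 12 nodes at
  internal density 0.9, realized by adding uniformly chosen missing edges
  until the target is met). Half of each planted module's members are
  assigned to the disease seed list (so seeded extraction retains the
  module); remaining disease seeds (default total 25) and all immune seeds
  (default 60) are drawn uniformly outside the modules.
* **Expression**: per planted module a latent factor `f ~ N(0,1)` per
  sample; member gene `g` gets `μ_g + β_g f + ε`, `ε ~ N(0, σ²)`. With
  `|β| = σ·sqrt(ρ/(1−ρ))` the implied correlation of two same-sign members
  is exactly ρ (default 0.7); 30 % of loadings are negative, giving
  anti-correlated planted edges with implied value
  `β_g β_h / sqrt((β_g²+σ²)(β_h²+σ²))`, recorded per edge in the truth
  object. Default 21 disease and 18 control samples. DE genes (75 % of
  module members plus 20 background genes) receive a mean shift of
  `d = 1.5` total standard deviations in disease samples, signed by a
  random direction.

At these defaults the correlation test has ≈ 0.95 power per planted edge
and the t-test ≈ 0.99 per DE gene, so recovery assertions ("≥ 90 % of
planted edges detected", "mean Jaccard ≥ 0.8") hold with margin while a
single desk-scale run stays under a few seconds.

What the generator does **not** emulate: probe-level microarray noise,
batch structure, normalization artefacts, the specific degree-mixing of
curated PPI databases, and correlated null genes. Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
model, not performance on any particular real dataset.

## Pipeline and determinism

One YAML/JSON configuration drives all stages; every threshold the
analysis uses (co-expression α 0.05, strong 0.5, DE α 0.05, enrichment α
0.01, top modules 5) appears in the report with its value, so runs are
self-documenting. Stages with absent inputs are skipped. All randomness
flows from the single run seed. The report JSON has sorted keys and
carries no wall-clock timestamps (the log stream does), so identical
inputs, config and seed give byte-identical reports — asserted by test.

Percentages in reports are rounded to two decimals and always accompanied
by the integer counts they were computed from.

## Problem sizes used in the automated checks

Module recovery: 20 replicates of the default scenario. Calibration: 1000
null edges and 500 correlated pairs at n = 21; 2000 null genes and 500
shifted genes at 21 vs 18. Oracle equivalence: exhaustive counting on
graphs of ≤ 15 nodes and enumeration backgrounds of ≤ 12 genes. These
sizes give Monte-Carlo standard errors comfortably inside the asserted
bands (e.g. ±0.007 on a 0.05 null rate over 1000 edges) while a full suite
run takes well under a minute.

## Known limitations

* Symbol-string gene identity: no resolution of aliases or retired
  symbols across input sources.
* The published reference counts for specific database snapshots (node and
  edge totals, category tallies, retention percentages) depend on those
  snapshots and are reproducible only when the user supplies the same
  files; the pipeline then emits every corresponding quantity in its
  report for side-by-side comparison.
* The co-expression test assumes bivariate normality per edge; heavy-tailed
  expression values inflate the null rate slightly.
* Over-representation ignores gene-set overlap structure and the GO DAG;
  parent/child redundancy is not collapsed.
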