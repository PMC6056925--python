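# mgnet

Seeded immune/disease subnetwork analysis for protein–protein interaction
(PPI) networks, built around membranous glomerulonephritis (MGN) — an
immune-mediated nephrotic syndrome — but applicable to any disease with a
seed gene list. For computational biologists who want the whole chain —
network extraction, topology, dense-module detection, expression overlay
and enrichment — as auditable local code instead of a mix of desktop tools
and web services.

## What it computes

Given an immune gene list, a disease gene list, an undirected PPI network
and (optionally) a case/control expression matrix and GMT gene-set
collections, the pipeline:

1. **Extracts seeded neighbor subnetworks.** The IOMDN (immune-or-MGN
   directed neighbor network) is the induced subgraph on all immune ∪
   disease seeds present in the PPI plus their direct interactors; the
   MGND is the same construction applied inside the IOMDN with disease
   seeds only. Nodes are classified four ways (both / disease-only /
   immune-only / other) and edge retention between the two levels is
   reported.
2. **Characterises topology.** Density `2E/N(N−1)`, mean degree `2E/N`,
   mean local clustering, a log–log OLS fit to the degree histogram as a
   scale-free check, and category-stratified mean degree with a
   deterministic hub ranking.
3. **Detects dense modules** with a from-scratch MCODE: vertex weight
   `w(v) = k_max · density` of the highest k-core of the closed
   neighborhood, greedy seeded expansion at threshold
   `w(seed)·(1 − 0.2)`, 2-core filter and haircut; defaults match the
   reference tool. Modules are ranked by node count for downstream stages.
4. **Overlays expression.** Per-edge Pearson correlation on disease
   samples with two-sided significance from `t = r·sqrt((n−2)/(1−r²))`;
   per-gene Welch (or Student) unpaired t-tests disease vs control;
   per-module tallies of differential, up- and down-regulated genes.
   BH q-values accompany every p.
5. **Runs local over-representation.** Hypergeometric upper-tail test of
   module genes against GMT terms over the network background, p < 0.01,
   plus a bipartite drug–gene network from enriched drug-target terms.

A fully ground-truthed synthetic generator (scale-free background with
planted dense modules, latent-factor co-expression at implied correlation
ρ, planted differential expression) makes every stage testable end to end.
See `docs/methods.md` for the model details and conventions.

## Worked example

Run the full pipeline on the default synthetic scenario (500-node
scale-free PPI, one planted 12-node density-0.9 module, 60 immune / 25
disease seeds, 21 disease vs 18 control samples):

```python
from mgnet import run_pipeline
report = run_pipeline({"synthetic": {}}, "out/", seed=7)
```

or equivalently from the shell:

```
mgnet run-all --config config.yaml --out out/ --seed 7
```

Selected numbers from the resulting `out/report.json`:

```
networks.iomdn.topology   {'node_count': 301, 'edge_count': 620, 'density': 0.0137, 'mean_degree': 4.12, 'mean_clustering': 0.094}
networks.mgnd.topology    {'node_count': 97, 'edge_count': 192, 'density': 0.0412, 'mean_degree': 3.96, 'mean_clustering': 0.133}
networks.mgnd.category_tally  {'both': 1, 'disease_only': 24, 'immune_only': 11, 'other': 61, 'total': 97}
retention                 {'sub_edges': 192, 'base_edges': 620, 'percent': 30.97}
modules.top_by_size       [{'size': 12, 'score': 10.91, 'rank': 1}]
expression.correlation_summary  {'significant_count': 66, 'significant_percent': 34.38,
                                 'strong_among_significant': 64, 'strong_percent': 96.97,
                                 'positive_significant': 34, 'negative_significant': 32}
expression.per_module     [{'gene_count': 12, 'differential_count': 9, 'up_count': 5, 'down_count': 4}]
enrichment                {'tested': 2, 'enriched': 2, 'drug_gene_edges': 24}
```

Reading: the disease-directed MGND is denser and more clustered than the
surrounding IOMDN (0.0412 vs 0.0137; clustering 0.133 vs 0.094) and keeps
30.97 % of its edges. MCODE's top module is exactly the planted 12-node
dense region (score = density × size = 10.91); 34.38 % of MGND edges are
significantly co-expressed on disease samples, 96.97 % of those strongly
(|r| > 0.5) with both signs present; 9 of the 12 module genes are
differentially expressed (5 up, 4 down); and both planted gene-set terms —
including the synthetic drug-target signature — come out enriched. All of
this matches the planted ground truth written to `out/inputs/truth.json`.

To run on real data, replace `"synthetic"` with an `inputs:` block naming
your PPI edge list (TSV/SIF/GraphML/HPRD flat), seed lists (plain list,
GAF 2.x or two-column TSV), expression matrix (plain TSV or GEO
series-matrix text) with a sample-label TSV, and GMT collections; the
report then carries the same quantities — node/edge counts, tallies, mean
degrees, densities, retention, co-expression and module DE tallies — for
your snapshot of those databases.

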