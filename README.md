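# obkit

Network toolkit for studying the deeply conserved structure of a cell
type's gene program across species.  Given per-species expression tables
(TPM), STRING-style weighted interaction edges, OrthoFinder-style
orthogroup tables and a rooted species tree, it provides:

* **Phylostratigraphy & transcriptome age.**  The root-to-focal-species
  path of the tree is ranked 1 (oldest) .. K (species-specific); each
  orthogroup — and hence each focal gene — is dated by the oldest clade
  containing all of its member species.  The transcriptome age index of
  a sample is the expression-weighted mean rank,
  `TAI = Σᵢ rankᵢ·TPMᵢ / Σᵢ TPMᵢ`, so higher values mean younger
  transcriptomes.
* **Expression-filtered interaction layers.**  One undirected weighted
  graph per species over the genes expressed in a cell type (mean
  TPM > 1), keeping interactions with confidence score ≥ 0.5.
* **Metric backbones.**  Scores `s ∈ (0, 1]` map to distances
  `d = 1/s − 1`; an edge is *metric* when its direct distance equals the
  shortest-path distance and *semi-metric* (redundant for all shortest
  paths) otherwise.  The backbone — exactly the metric edges — preserves
  every shortest path of the original graph.
* **The orthoBackbone.**  The layers form a multilayer network whose
  interlayer links join genes sharing an orthogroup (one-to-many, so
  paralogs are handled).  A backbone edge is retained iff *every* other
  species' backbone contains an analogous edge between orthologs of its
  endpoints; nodes left without edges are dropped.  The result is the
  cross-species conserved skeleton of the cell type's network.
* **Conservation classification & controls.**  Per-node degree
  centrality and PageRank, Kolmogorov–Smirnov contrasts of conserved vs
  non-conserved genes, random-forest / linear-SVM cross-validated
  prediction of conservation from network features alone, and a
  random-rewiring control that progressively dilutes the signal.
* **DEG edge disruption.**  The fraction of orthoBackbone edges with at
  least one differentially expressed endpoint, with a two-sided Fisher
  exact test for comparing two edge sets.
* **A synthetic multilayer generator** that plants all of the above
  structure (conserved core with elevated connectivity and shared
  interologs, paralogs, Beta-distributed confidence scores, an
  age-stage expression trend, DEG sets), so the whole pipeline is
  testable without any external downloads.

## Worked example

```python
from obkit import (SimulationConfig, simulate_multilayer, simulate_deg,
                   link_layers, compute_backbones, extract_orthobackbone,
                   edge_disruption, node_features, classify_conservation)

cfg = SimulationConfig(n_layers=3, genes_per_layer=500, mean_degree=10.0, seed=7)
layers, orthogroups, truth = simulate_multilayer(cfg)
ml = link_layers(orthogroups, layers)
compute_backbones(ml)
ob = extract_orthobackbone(ml)
for sp in ml.species:
    bb = ml.backbones[sp]
    print(f"{sp}: {layers[sp].n_edges} edges -> backbone {bb.n_metric} "
          f"({100*bb.n_metric/layers[sp].n_edges:.1f}%) -> "
          f"orthoBackbone {len(ob.edges[sp])} "
          f"({100*len(ob.edges[sp])/layers[sp].n_edges:.1f}%)")
report = classify_conservation(node_features(layers["sp1"]), "random-forest", seed=7)
print(f"conservation AUC (random forest, 4-fold): {report.mean_auc:.3f}")
deg = simulate_deg(truth)
d = edge_disruption(ob.edges["sp1"], deg)
print(f"edge disruption: {d.disrupted}/{d.total} = {100*d.fraction:.1f}%")
```

prints

```
sp1: 6477 edges -> backbone 2545 (39.3%) -> orthoBackbone 157 (2.4%)
sp2: 6346 edges -> backbone 2648 (41.7%) -> orthoBackbone 155 (2.4%)
sp3: 6582 edges -> backbone 2682 (40.7%) -> orthoBackbone 160 (2.4%)
conservation AUC (random forest, 4-fold): 1.000
edge disruption: 58/157 = 36.9%
```

Reading: each species layer keeps ~40% of its edges as the metric
backbone, but only ~2.4% of all edges survive the cross-species
orthoBackbone collapse; the planted conserved core is perfectly
recoverable from connectivity features alone (AUC 1.0 at a 3× degree
contrast); and a uniform 20% DEG set disrupts ~37% of orthoBackbone
edges (an edge is disrupted when either endpoint is differentially
expressed).

The same pipeline is available from the shell via the `obkit` command
(`simulate`, `phylostrata`, `tai`, `build`, `backbone`, `orthobackbone`,
`features`, `classify`, `rewire`, `disrupt`); every run writes a
`manifest.json` that reproduces it exactly.

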