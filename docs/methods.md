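# Methods

## Phylostratigraphy and transcriptome age

A rooted, bifurcating species tree is required; a multifurcation at the
root is treated as the signature of an unrooted tree and rejected.  The
nodes on the root-to-focal-leaf path are ranked 1..K in order (1 = root,
oldest; K = focal leaf, species-specific).  An orthogroup is dated by
the deepest ranked node whose leaf set contains every species with
members — the most recent common ancestor restricted to the ranked
path, which always exists because the focal species is a member.  All
focal genes of the orthogroup inherit that rank.  Focal genes belonging
to no orthogroup are assigned rank K, the usual phylostratigraphic
convention for orphan genes.

The transcriptome age index of a sample is
`TAI = Σᵢ rankᵢ·TPMᵢ / Σᵢ TPMᵢ` over the included genes; it is invariant
under positive rescaling of expression and bounded by the smallest and
largest contributing rank.  Genes are included per group when their
arithmetic-mean TPM across the group's samples is strictly above the
cutoff (default 1; configurable, since classic TAI uses all non-zero
genes and cutoff 0 reproduces that convention).  Both per-sample TAIs
and group means are reported because either convention is defensible;
per-rank contribution shares split the group-mean TAI numerator by rank
and sum to 1.  The "conserved fraction" statistic is the fraction of
expressed genes whose rank falls in a configurable old-rank set
(default 1–5, the strata shared by all Metazoa in a 16-rank tree), with
a two-sided Mann–Whitney U comparison of per-sample fractions between
two groups.

## Layers and filtering

A layer is one species' undirected simple graph.  Confidence scores are
normalized to (0, 1] on input (STRING's 0–1000 scale is divided by
1000; auto-detection uses the fact that unit-scale scores cannot exceed
1).  Duplicate undirected edges collapse to the **maximum** score —
conservative retention of the strongest evidence, and deterministic.
Self-edges are dropped and counted.  An edge enters the layer iff both
endpoints are expressed (group-mean TPM strictly > cutoff) and its score
is ≥ the confidence threshold (0.5 by default; the inclusive reading is
the safer one and the two readings differ only at exactly 0.5).
Largest-connected-component reduction is optional; ties — which never
occur on data of realistic size — are broken toward the component whose
sorted node list is lexicographically smallest, for determinism.

## Metric backbone

Scores map to distances by the isomorphism `d = 1/s − 1` (strictly
decreasing, `d(1) = 0`), the standard choice in the metric-backbone
literature; `−log s` and `1 − s` are available behind a flag.  An edge
(u, v) is metric iff `d_uv ≤ D(u, v)·(1 + rel_tol)` where `D` is the
all-pairs shortest-path distance; since `D ≤ d_uv` always, exact ties
count as metric.  Keeping ties makes the operator idempotent and
guarantees the backbone realizes at least one shortest path per pair.
The relative tolerance defaults to 1e-9 — distances are only a few
arithmetic operations deep, so anything beyond float noise is a genuine
inequality.  Distances are computed by batched single-source Dijkstra
(scipy's C implementation, 512 sources per batch to bound memory); the
test suite checks the classification against an independent dense
Floyd–Warshall oracle.  `verify_distance_preservation` re-derives
all-pairs distances on the backbone and reports the maximum relative
deviation; a pair disconnected only in the backbone yields an infinite
deviation.

## orthoBackbone

Interlayer links connect genes of different layers sharing an
orthogroup (one-to-many, so a gene may link to several paralogs).  A
node is flagged conserved iff its orthogroup has members present in
every layer.  A backbone edge (a, b) of layer L is retained iff for
every other layer L′ there exist orthologs a′ of a and b′ of b with
a′ ≠ b′ and (a′, b′) a backbone edge of L′ — the one-to-many rule: one
analogous backbone edge suffices.  The a′ ≠ b′ requirement covers the
degenerate case where a and b share an orthogroup whose other-layer
membership is a single gene: an edge cannot map onto a node.  The text
this implements requires the analog in the other layer's *backbone*,
not its orthoBackbone; a fixed-point variant (analog must itself be
retained) would be a strictly stronger condition and is deliberately
not built.  Because the retention test is per-layer and refers only to
the other layers' backbones, the result is independent of layer
processing order; adding layers can only shrink each layer's
orthoBackbone (every pairwise orthoBackbone contains the all-species
one), and both properties are asserted against an enumeration oracle in
the tests.  Nodes left without retained edges are removed, so the
orthoBackbone usually has fewer nodes than its layer and is not itself
a metric backbone.

Core selection takes two annotation sets and keeps edges with at least
one endpoint in their intersection (a gene carrying both annotations);
requiring one endpoint per set is available as a mode.  Edge disruption
counts edges with ≥ 1 endpoint in a DEG set; two edge sets are compared
with a two-sided Fisher exact test on the disrupted/intact 2×2 table.

## Node features, rewiring and classification

Features are computed on the unweighted topology: degree centrality
(degree/(n−1)) and PageRank with damping 0.85 (the standard default);
clustering coefficient and core number are optional extras.
Distributions are compared with the two-sample, two-sided
Kolmogorov–Smirnov test (asymptotic p).

The rewiring control removes ⌈fraction·|E|⌉ randomly chosen edges and
replaces each with a uniformly drawn node pair, rejecting self-loops
and duplicates, carrying the removed edge's score over.  Endpoint
resampling is deliberately **not** degree-preserving: the control's
purpose is to dilute degree differences themselves, which a
degree-preserving swap cannot do.  Node set, edge count, the
simple-graph property and the score multiset are preserved; the result
is deterministic given the seed.

Classification uses stratified 4-fold cross-validation with a fixed
seed and records the fold assignment.  Defaults: random forest with 100
trees and default depth; linear SVM with hinge loss, C = 1 and
per-training-fold standardization.  The feature vector defaults to
{degree centrality, PageRank}.  AUC is computed per fold from
out-of-fold scores; the precision–recall curve pools all out-of-fold
scores.

## Synthetic generator

`SimulationConfig` defaults describe the emulated study conditions:
3 layers × 2000 genes, conserved fraction 0.5, background mean degree
20 with the conserved core 3× as connected, paralog rate 0.2,
Beta(4, 2) confidence scores (most mass above the 0.5 threshold), a
16-rank caterpillar species tree with conserved genes planted uniformly
in ranks 1–5, three stages × 3 samples with age-slope 0.5, and a 20%
DEG fraction.  These sizes keep a complete pipeline run within seconds
while preserving every statistical contrast the pipeline measures.

Each layer is a Chung–Lu-style expected-degree graph: pair (i, j) is an
edge with probability `w_i·w_j / Σw` (capped at 1).  Conserved
orthogroups designate one *primary* copy per layer; primary–primary
pairs replicate a single shared ancestral adjacency across layers
(interologs — this is what gives the orthoBackbone something to find),
while every other pair (involving paralog copies or background genes)
is drawn independently per layer with the same probability formula.
Two consequences matter: at `degree_multiplier = 1` all nodes have
identical edge probabilities, so conserved and background genes are
statistically exchangeable and any classifier's AUC is 0.5 in
expectation; and paralog copies exercise the one-to-many orthology rule
without distorting degree statistics.  Edge scores are i.i.d. across
layers, so a shared core edge may be metric in one layer and
semi-metric in another — the orthoBackbone is a genuine intersection,
not a copy of the core.

Expression is log-normal (baseline ln-mean log 5, sigma 1.2,
multiplicative noise sigma 0.3) with stage s scaling gene i by
`exp(slope·s·z_i)`, `z_i` the centred rank / K, so the expression share
of young genes — and the TAI — rises across stages when the slope is
positive.  DEG sets are drawn without replacement, with an optional
odds-ratio bias toward the conserved core.  One global seed spawns
per-component child generators (seeded `(seed, component tag)`), so any
stage is reproducible in isolation.

What the generator does **not** emulate: community structure and
functional modules, degree–degree correlations, score heterogeneity by
evidence channel, orthogroup size distributions beyond 1–2 copies,
duplication–divergence growth, or biologically structured DEG sets.
Passing tests therefore demonstrate the pipeline's correctness and its
ability to recover planted contrasts, not the effect sizes expected on
real interaction databases — whose conserved-gene coverage and edge
fractions depend on evidence ascertainment the null model deliberately
omits.

## Numerical and degenerate-input choices

* Edge keys are canonical (lexicographically ordered) pairs throughout;
  all writers sort their output, so reruns are byte-identical.
* Backbone tolerance is relative (1e-9); distances must be finite and
  non-negative; an empty graph has an empty, trivially valid backbone.
* Jaccard similarity of two empty edge sets is 0 with a warning; edge
  disruption of an empty edge set is an error (the fraction is
  undefined).
* `tai` raises "empty transcriptome" when no gene passes the cutoff,
  and refuses to silently drop expressed genes lacking a rank.
* Gene identifiers are opaque case-sensitive strings; no namespace
  mapping is attempted.

## Test and script problem sizes

The oracle suites use 200 random graphs (≤ 50 nodes) for the backbone,
100 random 2–3-layer toys (≤ 30 genes/layer, paralog rate 0.3) for the
orthoBackbone, and 100 random trees (≤ 12 leaves) for phylostratigraphy.
Classification recovery runs at the default 2000 genes/layer; the
rewiring dilution trend uses 2-layer, 600-gene networks over 20 seeds;
the CLI smoke test uses 120-gene layers.  `scripts/acceptance.py` runs
the default configuration end to end (≈ 15 s on one CPU).

## Known limitations

* The orthoBackbone retention scan is quadratic in paralog-set size per
  edge pair; fine for realistic orthogroups, slow for huge gene
  families.
* All-pairs distance verification is O(n·m log n) and intended for
  graphs up to a few thousand nodes.
* The Mann–Whitney and KS comparisons use asymptotic p-values; very
  small sample counts (< ~5 samples per group) deserve exact tests.
* Linear-SVM AUCs use the signed decision function; probability
  calibration is out of scope.
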