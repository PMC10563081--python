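# Methods

`hnscnet` re-implements, as a tested and reusable pipeline, an integrative
analysis of differentially expressed genes (DEGs) and miRNAs in a
tumor/control bulk RNA-seq cohort (the head-and-neck squamous cell
carcinoma setting): differential expression, bipartite miRNA–target
networks with degree-threshold selection, protein–protein interaction
(PPI) topology with a nine-centrality suite, composite hub selection
validated against degree-preserving random networks, a targeting-count
distribution contrast, gene-set over-representation, and miRNA-stratified
survival analysis. A synthetic cohort generator supplies every input with
the statistical structure the analysis assumes, so each stage can be
scored for recovery of planted signal.

## Differential expression

Counts are normalized with median-of-ratios size factors
`s_j = median_f counts[f, j] / geomean_f`, the median taken over features
whose geometric mean across samples is positive. The tumor-vs-control
contrast is a negative-binomial Wald test:

- `log2FC = log2((mean_a + pc) / (mean_b + pc))` on normalized counts with
  pseudocount `pc = 0.5` (stability at zero means);
- per-feature dispersion `α` by method of moments under
  `Var = μ + αμ²`, pooled across the two groups by residual degrees of
  freedom and floored at 1e-8;
- the standard error by the delta method,
  `SE² = [Var(mean_a)/(mean_a+pc)² + Var(mean_b)/(mean_b+pc)²] / ln²2`;
- two-sided p from the standard normal, Benjamini–Hochberg adjustment
  over all tested features.

This is a deliberately simple test, with no GLM covariates and no
dispersion shrinkage across features. It is **not** numerically
interchangeable with a full GLM implementation; the pipeline's claims are
calibrated instead: on synthetic data the null raw-p ≤ 0.05 fraction is
≈ 0.05, BH-called features at adjP ≤ 0.01 have empirical FDR well under
0.05, and planted |log2FC| = 2 effects at 40 vs 40 samples are recovered
with recall > 0.9 (both recomputed by the acceptance script).

Selection thresholds follow the analysis conventions: DEG list
adjP ≤ 0.01 and |FC| ≥ 1.5; network seeding adjP ≤ 0.01 and |FC| ≥ 2;
miRNA volcano cut |FC| ≥ 2 and raw p ≤ 1e-5 (raw vs adjusted is
configurable; the convention in published volcano plots is often
ambiguous, so the default is raw). Fold change uses the signed convention
`FC = 2^log2FC` for up, `−2^|log2FC|` for down, so `|FC|` thresholds read
naturally in both directions. Stage-level analysis runs one-way ANOVA on
`log2(normalized + 1)` across tumor stages, dropping any stage group with
fewer than `stage_min_n = 15` samples (generalizing the exclusion of the
rare IVb stage in cohorts of this shape); both raw and BH-adjusted stage
p-values are emitted since conventions differ.

## Bipartite miRNA–target networks

One directed miRNA→gene network per direction class (up/down in tumor),
built from an input target table (live database retrieval is out of
scope; the table is the contract). miRNA identifiers are matched
case-insensitively with the organism prefix stripped. Isolated DE miRNAs
are retained with out-degree 0 and included in averages. Selection rules
are recomputed from each network, never hard-coded: miRNAs with
out-degree strictly above the average; genes with in-degree ≥ 2× the
average in-degree ("most targeted"). The cross-class partition assigns a
gene to the up-specific set iff `in_up ≥ 2·avg_up` and `in_down <
avg_down` (mirrored for down-specific); genes strongly targeted by both
classes are dropped, making the outputs disjoint by construction. The
"degree" in these rules is bipartite in-degree (number of targeting
miRNAs); an interpretation against PPI degree is possible but not the
default.

## PPI assembly and centrality suite

Edges carry two evidence-channel scores in [0, 1] ("experimental",
"database"); an edge survives iff both endpoints are seed genes and
`experimental > 0.1 OR database > 0.3` (strict, "higher than"; both
configurable, with a `--string-scale` flag dividing 0–1000 integer scores
by 1000 — scores outside [0, 1] otherwise are a hard error). Path
statistics are computed on the largest connected component, component
sizes logged.

The centrality suite is implemented from scratch on unweighted undirected
graphs (exact, no sampling), with deterministic sorted-node iteration:

- betweenness, stress and edge betweenness by Brandes' dependency
  accumulation over unordered pairs, raw (unnormalized) values;
  stress uses a parallel accumulation of geodesic continuation counts so
  that `stress(v) = Σ_s σ_sv · x_s(v)`;
- closeness `1/Σ_w d(v,w)` and eccentricity `1/max_w d(v,w)` in their
  reciprocal forms — the published network-average values this style of
  analysis reports (e.g. closeness ≈ 5e-4 on a ~600-node graph) are only
  consistent with reciprocals, and both then lie in (0, 1];
- radiality `Σ_{w≠v}(Δ + 1 − d(v,w))/(n−1)` with Δ the component
  diameter; its node average equals `Δ + 1 − average distance`
  identically, which the tests verify;
- centroid `min_{w≠v} [γ_v(w) − γ_w(v)]`, where `γ_v(w)` counts nodes
  strictly closer to v than to w, endpoints excluded and distance ties
  counting for neither side (the two endpoint boundary terms cancel in
  the difference, which the vectorized implementation exploits);
- eigenvector: the principal (Perron) eigenvector of the adjacency
  matrix, computed by power iteration on `A + I` (same eigenvectors, a
  strictly dominant top eigenvalue even on bipartite graphs) to relative
  tolerance 1e-12, returned nonnegative with unit Euclidean norm;
- bridging `betweenness(v) · BC(v)` with bridging coefficient
  `BC(v) = (1/deg v) / Σ_{u∈N(v)} 1/deg(u)`.

Every quantity is cross-checked against independent brute-force oracles
(exhaustive geodesic enumeration, cubic centroid loop, dense
eigendecomposition) on hundreds of random graphs to 1e-9, and against
igraph for betweenness/closeness at larger scale.

## Hubs and degree-preserving null models

A node is a hub when its betweenness, centroid and bridging are all
strictly above the component-wide means; hubs are ranked by betweenness
(ties by node id). Hub selection is validated against randomized
networks: each replicate applies `10 · |E|` successful double-edge swaps
(rewire (a,b),(c,d) → (a,d),(c,b), rejecting self-loops and duplicates),
which preserves every node's degree exactly. Graphs admitting no legal
swap (stars) come back identical and flagged; a run where >10% of
replicates are flagged is an explicit error rather than a silent p-value.
Mixing is diagnosed by the edge-Jaccard overlap with the original
(typically < 0.05 at 10 swaps/edge). The replicate statistic (average
betweenness of the largest component) is computed via igraph for speed;
it is verified against this package's own centrality module in the tests.
The empirical two-sided p uses the add-one formula
`(1 + #{|null_i − mean| ≥ |ref − mean|}) / (n_random + 1)`, so it is
never 0; the exact test form is this package's choice.

## Integration and enrichment

For genes differentially expressed in one direction, the per-gene counts
of down-regulated and up-regulated targeting miRNAs are compared with the
two-sample Kolmogorov–Smirnov test (asymptotic p by default, exact
optional; ties from integer counts are handled by the ECDF sup over
observed points). Which gene universe and pairing such a contrast uses is
genuinely open; this implementation conditions on the DEG direction and
reports both the up-DEG and the mirrored down-DEG contrast.
Over-representation of a query gene set in user-supplied GMT collections
uses the upper-tail hypergeometric test with BH adjustment across sets —
a generic replacement for app-specific enrichment services, whose exact
term databases are out of scope.

## Survival

Tumor samples are stratified by a miRNA's normalized expression — median
split (ties to the low group) by default; tertile extremes and a
log-rank-maximizing "optimal" cut behind flags, the latter reported with
a permutation p because the maximized statistic is not χ²-distributed.
The published analyses this emulates do not state their cut, so the
median default is flagged prominently. Groups are compared with
Kaplan–Meier curves and the log-rank test (lifelines); controls and
samples missing time/event are excluded and counted. Times are in days.

## Synthetic cohort generator

The generator emulates a large tumor/control cohort (defaults: 200 tumor
+ 44 control samples, 2 000 genes, 300 miRNAs — desk-scale stand-ins for
a 523 + 44 cohort; stage mix I/II/III/IVa/IVb =
0.042/0.193/0.211/0.534/0.020 so the rare IVb group exercises the
minimum-group-size rule):

- **Counts**: negative binomial with mean
  `baseline · sizefactor · 2^(log2FC · is_tumor)`, one common dispersion
  (0.2), log-normal baselines (median 100, log-sd 1.5) and size factors
  (log-sd 0.2). Exactly `round(frac_de · n)` features carry planted
  |log2FC| = 2, half up / half down (ties to up).
- **Target map**: each miRNA–gene pair is drawn with base probability
  0.05 (~100 targets per miRNA, in the range of curated validated-target
  collections; realized in-network average in-degrees land near the 4–5
  published for such bipartite networks). For (down-miRNA, up-gene) pairs
  the odds are multiplied by `repression_enrichment = 5`, planting the
  repression signal the KS contrast detects.
- **Interactome**: the dense core covers the disease-relevant genes (DE
  genes plus genes strongly targeted by DE miRNAs) — real interactomes
  concentrate density in disease modules, and this keeps the DEG-induced
  subnetwork connected the way curated networks are. The core is split
  into 5 preferential-attachment modules; each planted hub (5 by
  default, sampled from the DE genes) is wired as an inter-module
  connector with total degree `hub_boost × ba_attachment = 30`,
  neighbors drawn degree-weighted from every module. Connectors carry
  high degree, betweenness, centroid **and** bridging simultaneously —
  the signature the composite hub rule selects. A single plain
  scale-free graph with boosted-attachment nodes does not have this
  property: the bridging coefficient decays like 1/deg² for
  dominant-degree nodes, so pure-BA mega-hubs rank at the bottom on
  bridging and can never satisfy the three-way rule. With no planted
  hubs the generator degenerates to one plain preferential-attachment
  graph (a tree at `ba_attachment = 1`). Edge evidence scores are
  independent uniform [0, 1] per channel.
- **Survival**: exponential times with hazard
  `h0 · exp(hazard_log_hr · z)`, `h0 = 1e-3`/day and `z` the
  standardized log2 library-size-normalized expression of the designated
  prognostic miRNA (one by default, drawn from the up-regulated planted
  miRNAs); censoring uniform on `[0, 3.1/h0]`, giving ≈30% censoring at
  average expression.

All randomness flows from one seed through named per-sub-generator
streams; regeneration with the same seed is byte-identical.

What the generator does **not** emulate: per-gene dispersion variation and
shrinkage, batch effects, paired-sample structure in the controls,
sequence-driven target specificity, evidence-score correlation with true
interactions, non-proportional hazards. Passing recovery tests therefore
shows the pipeline's logic and calibration are sound under the assumed
generative model, not that any particular biological claim reproduces on
real cohort data — the published headline numbers (DEG counts, network
sizes, specific survival p-values) depend on external database versions
and are out of reach by design.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the
package's own defaults: oracle checks on 50–200 random graphs (n ≤ 25),
DE calibration on 10–20 cohorts of 2 000 features × 80 samples, null
models with 100–1 000 replicates, recovery runs over 10–12 seeds at the
default cohort size. Degenerate inputs degrade explicitly: empty
selections propagate as skipped stages recorded in the run manifest;
zero-variance features get p = 1; constant-expression stratification
returns no test with a warning; graphs with no legal swap are flagged.
Iteration order is deterministic everywhere (sorted node ids, stable
sorts by (p, feature id) in BH ranking), so results are bit-reproducible
on one platform.
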