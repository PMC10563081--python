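# hnscnet

Integrative network analysis of differentially expressed genes (DEGs) and
miRNAs in tumor/control RNA-seq cohorts, of the kind used to study head
and neck squamous cell carcinoma: which genes and miRNAs move with the
disease, which genes are hammered by many dysregulated miRNAs, which
nodes of the protein–protein interaction (PPI) network are topological
hubs, and whether miRNA expression stratifies patient survival.

The pipeline chains seven stages, each usable on its own:

1. **Differential expression** — median-of-ratios normalization, a
   negative-binomial Wald test for tumor vs control
   (`log2FC = log2((μ̂_t + ½)/(μ̂_c + ½))`, method-of-moments dispersion,
   delta-method SE, Benjamini–Hochberg FDR), one-way ANOVA across
   disease stages, and threshold selection (DEG list: adjP ≤ 0.01,
   |FC| ≥ 1.5; network seed: |FC| ≥ 2; miRNA volcano: |FC| ≥ 2,
   p ≤ 1e-5).
2. **Bipartite miRNA→target networks**, one per direction class, ranked
   by degree with whole-network-average thresholds and a cross-class
   partition (up-specific iff `in_up ≥ 2·avg_up` and `in_down < avg_down`,
   mirrored for down).
3. **PPI assembly** from an evidence-scored edge table
   (`experimental > 0.1 OR database > 0.3`, both endpoints in the seed
   set).
4. **Topology** — a from-scratch exact centrality suite: degree,
   betweenness, stress, closeness `1/Σd`, eccentricity `1/max d`,
   radiality `Σ(Δ+1−d)/(n−1)`, centroid
   `min_w [γ_v(w) − γ_w(v)]`, eigenvector (Perron vector, unit norm),
   bridging `betweenness × BC`, edge betweenness, plus network diameter
   and average distance.
5. **Hub selection** — betweenness, centroid and bridging all strictly
   above the network averages — validated against degree-preserving
   random networks (double-edge-swap, empirical two-sided p).
6. **Integration** — Kolmogorov–Smirnov contrast of how many down- vs
   up-regulated miRNAs target each DEG, and generic hypergeometric
   gene-set over-representation (GMT input).
7. **Survival** — Kaplan–Meier curves and the log-rank test on tumor
   samples split by miRNA expression (median split by default).

A synthetic cohort generator produces all inputs (counts with planted
fold changes, a target map with planted repression enrichment, a modular
scale-free interactome with planted connector hubs, survival times with a
planted prognostic miRNA) together with truth tables, so every selection
stage is scored for recovery without any external download.

## Worked example

Run the whole pipeline on a synthetic cohort (2 000 genes, 300 miRNAs,
200 tumor + 44 control samples) from one seed:

```python
from hnscnet.config import PipelineConfig, NullModelConfig
from hnscnet.pipeline import run_pipeline

cfg = PipelineConfig(outdir="run1", seed=1,
                     nulls=NullModelConfig(n_random=100, seed=1))
manifest = run_pipeline(cfg)
for stage, info in manifest["stages"].items():
    print(stage, info)
```

Key lines of the output (seed 1):

```
diffexpr     {'deg_list': 200, 'deg_network': 200, 'de_mirnas_up': 30, 'de_mirnas_down': 30, ...}
bipartite    {'up_edges': 2995, 'down_edges': 3514, 'avg_in_up': 1.91, 'avg_in_down': 2.19,
              'up_specific_targets': 93, 'down_specific_targets': 66, ...}
network_deg  {'nodes': 200, 'edges': 558, 'diameter': 6, 'average_distance': 3.36,
              'n_hubs': 35, 'null_p': 0.0099, 'null_z': 10.40, ...}
integration_up   {'ks_statistic': 0.85, 'ks_p': 1.4e-11, 'n_genes': 100}
integration_down {'ks_statistic': 0.06, 'ks_p': 0.99, 'n_genes': 100}
survival     {'n_tested': 60, 'n_significant_005': 6}
```

Reading it: all 200 planted DEGs are recovered at adjP ≤ 0.01 and
|FC| ≥ 1.5; the DEG interaction network (200 nodes, 558 edges) yields 35
composite-rule hubs, and its average betweenness sits 10 standard
deviations above the degree-preserving null (empirical p ≈ 0.01 at 100
replicates) — the modular structure is real, not a degree artifact. The
up-regulated DEGs are targeted far more heavily by down-regulated miRNAs
than by up-regulated ones (KS D = 0.85, p ≈ 1e-11) — the planted
repression signal — while the mirrored contrast on down-DEGs is null, and
6 of 60 DE miRNAs (including the planted prognostic one) stratify
survival at p ≤ 0.05. `manifest["recovery"]` reports
precision/recall of each stage against the planted truth
(`hubs: recall 0.8` for this seed).

The same run from the shell:

```sh
hnscnet run-all --seed 1 --outdir run1
hnscnet simulate --outdir data --seed 1          # just the synthetic inputs
hnscnet ppi --edges data/ppi_edges.tsv --seed-genes seeds.txt --out-prefix net
```

Every stage writes TSV tables (DE records, degree tables, centralities,
hub flags, null distributions, KM inputs), SIF/GraphML graphs, and a
`manifest.json` with per-stage counts, seeds and timings. Empty
intermediate results skip downstream stages explicitly and are listed in
the manifest, never silently passed.

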