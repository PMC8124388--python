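# luadstrat

Essential-gene-based stratification of lung adenocarcinoma (LUAD) cohorts.

Lung adenocarcinomas are commonly stratified by expression subtypes (TRU /
PP / PI) built from genes with variable expression, regardless of whether
those genes drive the tumor.  `luadstrat` implements the alternative:
stratify patients by *cancer essential genes* — genes whose knockout
depletes most LUAD cell lines in genome-wide CRISPR screens (CERES score
< −1 in ≥ 75% of lines) *and* that are upregulated in tumors versus paired
normals (BH q < 0.01, log2FC > 1 by a paired moderated t test).  Patients
are clustered on that panel by feature-resampled consensus clustering over
PAM (k-medoids), clusters are ordered by panel expression (cluster 1
highest), and a median-centered nearest-centroid classifier carries the
strata to external cohorts and cell lines, where the package quantifies:

- survival differences (Kaplan–Meier, log-rank, multivariate Cox with
  Efron ties and stage as covariate, 5-year truncation),
- pathway / transcription-factor / immune activity per sample (ssGSEA with
  α = 0.25; analytic signed-regulon NES), screened across clusters by
  Kruskal–Wallis + Dunn at p < 10⁻³,
- mutation, copy-number-flag and pathology enrichment (Fisher exact),
  tumor mutation burden (non-silent count / 38 Mb), stage logistic models,
  and drug-response AUC comparisons (compounds tested on > 75% of lines,
  KW at α = 0.05).

Every stage runs end-to-end on synthetic cohorts that emulate the study's
data structure (a correlated essential-gene block with median pairwise
Pearson r ≈ 0.62, a planted 3-cluster gradient, cluster-dependent hazards /
TP53 frequency / TMB / stage, and planted-sensitive compounds), so the
whole pipeline is testable without any external download.  It is aimed at
computational-biology users who want a reproducible, dependency-light
re-implementation of this stratification strategy to run on their own
expression / clinical / mutation tables.

## Worked example

```python
from luadstrat import (SimulationConfig, simulate_cohort, call_essential,
                       paired_moderated_ttest, build_panel,
                       median_pairwise_correlation, consensus_cluster,
                       canonical_order, build_centroids, predict,
                       cluster_cox)
from luadstrat.cohort_stats import binarize_stage

cohort = simulate_cohort(SimulationConfig(seed=0))

hits = call_essential(cohort.dependency)            # CERES < -1 in >=75% of lines
deg = paired_moderated_ttest(cohort.tumor, cohort.normal, cohort.pairs)
panel = build_panel(hits, [deg])                    # intersect with q<0.01, log2FC>1
print(len(hits), len(panel.genes),
      round(median_pairwise_correlation(cohort.tumor, panel.genes), 3))
# 36 36 0.618

res = consensus_cluster(cohort.tumor, panel.genes, range(2, 7),
                        n_iter=200, seed=0)
labels = canonical_order(res.labels[res.chosen_k], cohort.tumor, panel.genes)
print(res.chosen_k, labels.value_counts().sort_index().tolist())
# 3 [115, 192, 193]

clin = cohort.clinical.data
cox = cluster_cox(clin["os_time"], clin["os_event"], labels,
                  binarize_stage(clin["stage"]))
print(round(cox.table.loc["cluster_1_vs_3", "hr"], 3),
      round(cox.table.loc["cluster_1_vs_3", "p"], 3))
# 1.251 0.189
```

36 genes are dependency-essential, all 36 survive the paired-DEG
intersection (they were planted that way), and their median pairwise
Pearson correlation is 0.62 — the coordinated proliferation program the
stratification rests on.  Consensus clustering picks k = 3; after
canonical ordering, cluster 1 (highest panel expression) has the highest
estimated hazard versus cluster 3 in a Cox model adjusted for stage.  This
cohort was simulated with a true cluster-1-vs-3 hazard ratio of 1.6; any
single cohort of 500 with ~50% censoring estimates it noisily (here 1.25),
which is why the acceptance script also reports the mean over 50 repeated
cohorts (≈ 1.58).

A held-out cohort from a new seed is classified by the trained centroids
with near-perfect agreement to its planted labels:

```python
model = build_centroids(cohort.tumor, labels, panel.genes)
held_out = simulate_cohort(SimulationConfig(seed=900))
print((predict(model, held_out.tumor).labels == held_out.true_labels).mean())
# 0.998
```

## Command line

```bash
luadstrat simulate --seed 0 --outdir cohort/          # write all tables as TSV
luadstrat essential --dependency cohort/dependency.tsv --out hits.tsv
luadstrat cluster --expression cohort/expression_tumor.tsv \
    --panel panel.txt --fixed-k 3 --outdir clusters/
luadstrat classify --model clusters/centroid_model.tsv \
    --expression new_cohort.tsv --out predictions.tsv
luadstrat run --seed 0 --outdir run/                  # full pipeline + manifest
```

`luadstrat run` executes simulate → essential → cluster → classify → score
→ stats → survive from one YAML config and writes every result table plus
a `manifest.json` recording the config hash, per-stage seeds and row
counts; the same config and seed reproduce the tables byte for byte.

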