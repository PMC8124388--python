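# Methods

`luadstrat` re-implements, as a tested and reusable pipeline, an
essential-gene-based stratification of lung adenocarcinoma (LUAD):
CRISPR-dependency screens nominate genes whose knockout depletes most LUAD
cell lines, paired tumor/normal differential expression keeps the subset
upregulated in tumors, consensus clustering over that panel stratifies
patients, a nearest-centroid model transfers the strata to external
cohorts and cell lines, and survival, genomic, activity and drug-response
statistics characterise the strata.  Because the pipeline is exercised on
synthetic cohorts, this note states exactly what the generator emulates,
what each stage assumes, and where design choices were genuinely open.

## Essential-gene calling and the DEG intersection

A gene is *dependency essential* when its CERES score (copy-number-corrected
dependency from genome-wide CRISPR knockout screens; more negative = more
essential) is strictly below `score_threshold` (default −1) in at least
`line_fraction` (default 0.75) of the cell lines with a non-missing score.
The boundary rules matter: −1 exactly does not count, 3 of 4 lines does.
Genes with no non-missing scores are dropped with a warning, not an error.

Tumor-vs-paired-normal differential expression is a paired moderated t
test.  Per gene, the paired differences d_i give the log2 fold change
(their mean) and a sample variance s².  Variances are shrunk toward a
common prior s₀² with d₀ degrees of freedom under a scaled
inverse-chi-square working model; (d₀, s₀²) are estimated by
method-of-moments on log s² (the excess variance of log s² over the
trigamma sampling term is inverted through the trigamma function by Newton
iteration).  The moderated t = log2FC / (s_post/√n) is referred to a t
distribution with n−1+d₀ degrees of freedom; q-values are
Benjamini–Hochberg.  This is an approximation to the full marginal-likelihood
empirical-Bayes fit; its fixed point is exact: when all gene variances are
equal the moderated statistic equals the ordinary paired t (checked in the
tests, along with uniformity of the null p-values).  The fold-change filter
reads "upregulated" as log2FC > 1 (i.e. > 2-fold); the natural-scale
reading (FC > 1) is vacuous as an upregulation filter and is available only
as explicit configuration (`log2fc_min`).

The essential panel is the intersection: dependency-essential AND q < 0.01
with log2FC > 1 in *every* supplied DEG cohort.

## Consensus clustering

Patient stratification is feature-resampled consensus clustering over PAM:
each of `n_iter` iterations draws ⌈0.95·|panel|⌉ panel genes without
replacement, computes sample–sample distances on that subset, and
partitions with PAM for every k in `k_range`.  The consensus matrix entry
M_k[i,j] is the fraction of iterations in which i and j co-clustered (all
samples participate in every iteration, so the denominator is `n_iter`;
optional sample resampling is available but off by default, matching the
genes-only scheme).  Final per-k labels come from average-linkage
hierarchical clustering of 1 − M_k cut into k groups — the usual
consolidation for this algorithm family.

Panel genes are median-centered across samples before distances
(`center_genes=True`), standard preprocessing without which between-gene
baseline differences drown the between-sample structure.  The default
distance is 1 − Pearson between samples; Euclidean is available by flag.

**PAM.**  BUILD seeds medoids greedily (first medoid minimises total
distance, each addition maximises the cost reduction); SWAP repeatedly
applies the single best cost-reducing (medoid, non-medoid) exchange until
none remains, ties breaking toward the lowest index.  SWAP is a local
search: on small random instances both this implementation and the
reference R `cluster::pam` occasionally converge to the same non-global
local optimum.  `pam` therefore re-runs the descent from additional seeded
random starts and keeps the cheapest solution — by default 10 starts when
n ≤ 50 (restarts are nearly free there, and small instances are where a
local optimum distorts results most) and the single BUILD start at cohort
scale, where BUILD is reliable and restarts would multiply the consensus
runtime.

**Choosing k.**  For each k the empirical CDF of the upper-triangle
consensus entries is integrated (trapezoid) into an area A(k); the relative
delta area is Δ(k) = (A(k) − A(k−1))/A(k−1) (Δ at the smallest k is A
itself).  The chosen k is the largest k with Δ(k) ≥ `delta_min`, unless a
fixed k is supplied (the pipeline default pins k = 3).  `delta_min`
defaults to 0.2: with feature-only resampling at a 0.95 fraction the base
partition is nearly deterministic, so consensus matrices are near-binary at
every k and A(k) ≈ 1 − Σ p_i² is pure partition arithmetic; spuriously
splitting a stable cluster of proportion q then inflates the area by up to
~q²/2 relative (≈ 0.12 for q = 0.4, < 0.2 for any q ≤ 0.5).  A threshold
below that floor can never reject k+1 on clean data; 0.2 sits above the
floor and well below the deltas produced by genuine additional structure
(~0.35 on the synthetic cohorts).

Clusters are renumbered canonically so cluster 1 has the highest mean panel
expression and the last cluster the lowest (expression rises in the order
cluster 3, 2, 1); ties break by cluster size.

## Nearest-centroid classification

Training: each panel gene is median-centered across the training cohort;
the centroid of cluster c is the mean centered profile of its members.
Prediction: the new cohort's panel genes are median-centered on the new
cohort's *own* medians by default (`cohort_median`), which removes platform
location shifts between RNA-seq and microarray cohorts; centering on the
stored training medians is retained for ablation.  Each sample is assigned
to the centroid with the highest Pearson correlation; exact ties go to the
lowest cluster index with a flag, zero-variance samples are flagged
unclassified rather than erroring.  The same mechanics serve user-supplied
published subtype centroids (e.g. the TRU/PP/PI LUAD subtypes); a reduced
panel is produced by subtracting a user-supplied overlap list from the
essential panel.  Pearson invariance makes predictions unchanged under any
per-sample affine rescaling a·x + b with a > 0 (tested).

## Activity scores

**ssGSEA.**  Per sample, genes are ranked by expression (average ranks on
ties); walking the genes in descending order, the score is the integrated
difference between the rank-weighted in-set ECDF (weights |rank|^α,
α = 0.25 by default) and the unweighted out-of-set ECDF.  When a set spans
all genes the empty complement contributes 0 and the score is maximal
positive.  With `normalize` the whole signature × sample matrix is rescaled
by its range (max − min).  Scores depend on ranks only, hence are invariant
to strictly monotone transforms of a sample's expression.

*Compositionality caveat:* because scores are functions of within-sample
ranks, a strong planted (or real) expression program displaces the ranks of
every other gene; gene sets drawn from "null" background genes therefore
show systematic cluster differences when compared across the very clusters
that the program defines.  This is a property of rank-based single-sample
scoring, not a defect of the screen; type-I calibration is accordingly
assessed with labels independent of expression.

**Regulon (TF) activity.**  An analytic rank-based score: per sample the
ascending average ranks r_g over n present genes map to standard-normal
quantiles t_g = Φ⁻¹(r_g/(n+1)); a signed regulon R of size m scores
NES = Σ_{g∈R} sign_g · t_g / √m.  Under random ranks this is asymptotically
standard normal, so the score is reported directly as an NES (Monte-Carlo
null: mean ≈ 0, sd ≈ 1 at m = 20; exactly antisymmetric under rank
reversal or sign flip).  This is the one-tail signed-rank form with an
analytic null; likelihood-weighted two-tail scoring and pleiotropy
correction are out of scope.  Regulons below 5 matched genes are skipped.

**Immune infiltration** is the ssGSEA score of user-supplied immune
signatures summed per sample.

## Association statistics

- Kruskal–Wallis H (tie-corrected, χ² reference) with post-hoc Dunn z
  tests, z = (mean-rank difference)/√[(N(N+1)/12 − tie term)(1/n_i + 1/n_j)];
  Dunn p-values are unadjusted by default, Holm by flag.  The activity
  screen keeps signatures with KW p < 10⁻³, ranked by p.
- Fisher exact tests (two-sided, hypergeometric enumeration as implemented
  in scipy) for enrichment of binary categories — non-silent mutation
  carriers, precomputed focal copy-number flags, pathology labels — in each
  cluster; the *sample* odds ratio (ad)/(bc) is reported, with ∞/0 flagged
  on zero cells (the conditional-MLE OR is a documented alternative).
- Logistic regression of binary stage (III/IV vs I/II; cohorts without
  high-stage patients fall back to II vs I) on cluster indicators against
  the reference cluster 3 (the best-prognosis cluster, matching every
  printed contrast), Wald p-values; perfect separation refuses the fit.
- OLS of an activity on cluster contrasts with binary stage as covariate;
  rank-deficient designs are refused naming the collinear columns, and a
  zero-variance response returns an all-zero fit with p = 1.
- TMB = non-silent mutation count / 38 Mb of exome, exactly; silent records
  never count, samples without records get 0, and counts are additive over
  concatenated tables.
- Drug response: compounds tested on more than 75% of the labeled cell
  lines are compared across predicted clusters by Kruskal–Wallis at
  α = 0.05, reporting the cluster with the lowest median AUC (lower AUC =
  more sensitive).

## Survival

Cluster comparisons default to 5-year overall survival: subjects beyond 60
months are administratively censored at 60, uniformly for Kaplan–Meier,
log-rank and Cox (the flag applies to all three, since the comparison the
truncation defines should not change mid-pipeline).  Kaplan–Meier is the
product-limit estimate; the log-rank test is the standard
observed-minus-expected χ² over pooled event times; the multivariate Cox
model uses Efron tie handling by default (Breslow by flag) with Wald CIs
and p-values.  Estimation is delegated to lifelines; the module owns the
truncation rule and the contrast coding (cluster indicators vs the
best-prognosis reference plus binary stage).  For a single binary covariate
the partial-likelihood score test at β = 0 equals the log-rank statistic
(verified numerically in the tests).

## The synthetic-data generator

The generator emulates the *structure* of the study's data, not its
content.  For sample s in cluster c(s), essential gene g:

    x_gs = b_g + δ_c(s) + η_{g,c(s)} + β·f_s + ε_gs

- b_g ~ N(5, 1): gene baseline (log2 units);
- δ_c = (+1.5, 0, −1.5): the cluster gradient, so expression rises in the
  order cluster 3, 2, 1;
- η_{g,c} ~ N(0, 1.0): fixed per-gene per-cluster effects giving each
  cluster its own profile direction.  Without them the block is rank one
  and a correlation-based sample distance — which subtracts each sample's
  mean profile — cannot see the clusters at all;
- f_s ~ N(0,1) with loading β = 1.09: the shared program driving the
  gene–gene correlation block;
- ε_gs ~ N(0, 1).

Background genes are baseline plus noise.  The expected pairwise Pearson r
between essential genes is (var δ + β²)/(var δ + (1−Σp²)·var η + β² + σ²)
≈ 0.62 at the defaults, emulating the reported co-expression of the panel;
the simulated median over 20 seeds is 0.63 (range 0.59–0.66).  Gene-level
truth (b, η) is drawn from a separate `biology_seed` (default 7) so that
cohorts drawn with different cohort seeds share the same biology — the
condition under which cross-cohort classification is even meaningful.

Paired normals subtract `deg_log2fc` (default 1.5) from the essential genes
of the first `n_pairs` (default 50) tumors plus fresh noise, so planted
genes carry a true paired log2FC of 1.5 and background genes are null.
Survival is exponential with multiplicative cluster hazards on a geometric
ladder from 1 (cluster 3, baseline 0.012/month) to the configured
cluster-1-vs-3 hazard ratio (default 1.6), censored by an independent
uniform time over a 120-month follow-up window.  Stage is Bernoulli on a
logit ladder (cluster-1-vs-3 log odds 1.0 over a 0.25 base rate); TP53
non-silent mutations have per-cluster probabilities 0.70/0.45/0.20;
passenger mutation counts are Poisson with per-cluster means of 9/6/3
mutations/Mb × 38 Mb, plus 30% extra silent records to exercise the
non-silent filter.  The dependency matrix gives planted genes CERES ~
N(−1.5, 0.2) over 31 cell lines and all others N(0, 0.2).  Cell lines get
cluster labels and expression from the same model; the drug table lowers
the AUC of planted-sensitive compounds by 0.3 in cluster-1 lines and blanks
10% of entries so the tested-fraction filter has work to do.

What the generator does *not* emulate: batch and platform effects between
RNA-seq and microarray, gene-length and GC biases, probe-to-gene
collapsing, copy-number-driven expression, non-proportional hazards, and
clonal structure in mutations.  Passing tests therefore demonstrate that
the pipeline's logic recovers planted structure under its stated model —
not that it is robust to those real-data complications.

## Problem sizes and numerical choices

Simulation-based checks run at the study's structural scale: cohorts of
n = 500 with a 36-gene panel over ~1000 background genes, consensus at 200
iterations over k = 2…6 across 10 seeds, hazard-ratio recovery as the mean
over repeated clinical draws at n = 500, and null calibrations at 1000
signatures / 200 compounds / 2000 replicate samples.  The clinical-only
sweeps shrink the irrelevant expression and mutation tables, which leaves
the survival model untouched.

Determinism: all randomness flows through numpy's PCG64 generator from
explicit seeds; the pipeline derives per-stage seeds by hashing the stage
name with the global seed (CRC32, below 2³¹), so stages can be rerun in
isolation.  Rank ties use average ranks everywhere.  PAM ties break toward
the lowest index.  Newton inversions (trigamma; Cox partial likelihood via
lifelines) run to relative tolerances of 1e-10/1e-7.  Degenerate inputs
follow the contracts above: warn-and-continue where a quantity is still
well defined (missing genes, empty panels at intersection time,
unclassifiable samples), hard errors where it is not (duplicate
identifiers, non-bijective pairings, rank-deficient designs, empty
groups).

## Known limitations

- The moderated-t prior is a method-of-moments approximation; heavy-tailed
  variance distributions will differ slightly from a full
  marginal-likelihood fit.
- The delta-area rule assumes the consensus CDF areas behave as described
  under feature-only resampling; with sample resampling enabled the 0.2
  default is conservative.
- The aREA-style NES uses the analytic normal null; for regulons smaller
  than ~10 genes the normal approximation is loose.
- Fisher sample odds ratios are reported as ∞/0 on zero cells rather than
  continuity-corrected.
- The published 506-gene subtype centroids and curated gene-set/regulon
  collections are data, not code: the package ships only small synthetic
  fixtures and reads user-supplied files for real analyses.
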