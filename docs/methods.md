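# Methods

`neutropipe` re-implements, as a single tested pipeline, the computational
analysis of a three-group blood-neutrophil study of community-acquired
pneumonia (CAP): healthy controls, patients sampled at hospital admission,
and the same patients about one month later (recovery). The pipeline
covers differential expression, per-sample pathway activity scoring,
gene-set enrichment, weighted co-expression network analysis, trajectory
clustering, metabolite effect sizes, and pathway–phenotype association.
Because the original cohort data are not public, a seeded synthetic
generator reproduces the statistical structure the analysis assumes; every
stage is validated against closed-form oracles, null calibration, and
planted-effect recovery on that generator.

## Differential expression

Counts are normalized with median-of-ratios size factors: for sample *j*,
`s_j = median_g (count_gj / geomean_g)` over genes with a positive
geometric mean. Factors are defined up to a common constant. Per gene we
fit the NB log-linear model

    log mu_gj = log s_j + b0_g + b1_g * 1[j in case group]

by iteratively reweighted least squares with variance `mu + phi mu^2`.
Dispersion is estimated per gene by Cox–Reid adjusted profile likelihood
on a log-spaced grid (the adjustment `−½ log det(XᵀWX)` removes most of
the downward bias from the two fitted mean parameters), then shrunk 50/50
on the log scale toward a fitted mean-dispersion trend `phi(mu) = a/mu +
phi0`, and clamped to `[1e-8, 10]`. The Wald statistic `b1/se(b1)` is
referred to a t distribution with `n − 2` degrees of freedom — at cohort
sizes this is indistinguishable from the normal reference, while keeping
the test honest in very small groups. Genes with fewer than 3 nonzero
counts (configurable) are excluded before testing and carry NaN p values;
Benjamini–Hochberg runs over the tested genes only.

Deliberately *not* reproduced from full-featured DE tools: empirical-Bayes
fold-change shrinkage, outlier count filtering, and independent filtering.
The stage aims to be a sound, transparent NB Wald test. On effect-free
synthetic cohorts (29/64/34 samples, 2000 genes) its type-I error at
p < 0.05 is within 0.05 ± 0.02, and a planted log2 fold change of 2
(mu = 100, phi = 0.1, 30 vs 30) is recovered within ±0.2 in the median.
One caveat worth knowing: with strongly one-directional planted DE,
median-of-ratios absorbs a few percent of the effect into the size
factors; balanced up/down regulation is estimated without this bias.

## Pathway activity scores

The per-sample score is the pipeline's centerpiece. Each gene's normalized
log expression `x` (log2 of median-of-ratios-normalized counts + 1) is
squashed into (−1, 1) by a shifted logistic map

    f(x) = 2 / (1 + exp(−beta (x − center))) − 1 = tanh(beta (x − center) / 2),

and a pathway's score in a sample is the mean of `f(x)` over the pathway's
measured genes. `beta` is the absolute slope of a univariate weighted
logistic regression of group (admission = 1, control = 0) on the gene's
standardized expression; `center` is the weighted mean expression of the
fitting samples. Choices the published description leaves open, and how
this package resolves them:

- **Expression scale**: `log2(normalized + 1)`; a logistic on raw counts
  has no usable operating range.
- **Weights**: inverse class frequency ("balanced"), so the 64-patient
  class does not dominate the 29-control class; `uniform` is available.
- **Centering**: the weighted mean of the fitting samples. Without
  centering a logistic of non-negative expression could never produce
  negative scores.
- **Fitting cohort**: coefficients are fit on admission vs control only;
  recovery samples are scored with the frozen coefficients, never refit.
- **Separable genes**: strong DE genes separate the groups perfectly and
  the unpenalized slope diverges; a ridge penalty (λ = 1e-4) plus a cap of
  25 on the standardized slope keeps every score finite.

Scores are compared between groups with a two-sided Wilcoxon rank-sum test
(exact null for groups of ≤ 25 without ties, normal approximation with tie
and continuity correction otherwise) and BH adjustment across pathways.
**Caveat**: because `beta` is fit on the same samples the test then
compares, the group test on in-sample scores is anticonservative under the
null — this is a property of the published construction itself, not of
this implementation. Interpret score Wilcoxon p values as descriptive when
the scoring cohort equals the fitting cohort; the planted-effect tests
show the procedure reliably detects a 1-SD pathway shift at the study's
sample sizes.

## Gene-set enrichment and over-representation

Preranked GSEA uses the classic weighted running-sum enrichment score
(hit steps ∝ |stat|^w with w = 1 by default, miss steps 1/(N−K)) on the DE
Wald ranking, with ties broken by gene ID for determinism. The null is
gene permutation: `n_perm` random same-size sets drawn from the ranked
universe (cached per set size). The two-sided p carries a +1 pseudocount,
so min p = 1/(n_perm + 1); NES divides ES by the mean |null ES| of
matching sign. Adaptive multilevel p refinement is not reproduced; at
desk scale a plain permutation null is transparent and sufficient, and
null query sets yield uniform p (KS test in the acceptance suite).
Over-representation is the standard upper-tail hypergeometric test,
verified against exhaustive enumeration on universes of ≤ 12 genes.

## Co-expression network

The network stage follows the classical WGCNA recipe on
`log2(normalized + 1)` expression:

1. **Variance filter**: top 10% most variable genes (ties broken by ID).
2. **Sample outliers**: average-linkage clustering on Euclidean distance;
   a sample is flagged (never auto-removed) when its leaf joins the tree
   above mean + 2.5 SD of all merge heights.
3. **Soft threshold**: for β = 1..20, adjacency `|cor|^β` (unsigned
   default; `signed` available), connectivity binned into 10 bins, and the
   signed scale-free fit R² computed from the log-log regression. The
   chosen β is the smallest with R² ≥ 0.9. When no power reaches the
   target — typical for strongly blocked data, whose bimodal connectivity
   is not scale-free at any power — the scan falls back to the
   conventional default (6 unsigned, 12 signed) rather than chasing the
   R² argmax into extreme powers that erase weak modules.
4. **TOM**: `TOM_ij = (L_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij)`, verified
   against a brute-force O(n³) oracle.
5. **Modules**: average-linkage on 1 − TOM; a static cut at 0.99 × the top
   merge height yields candidate branches, which are recursively split
   while both children (≥ 40 genes each) are internally twice as similar
   as they are to each other. A branch becomes a module only if its mean
   within-TOM exceeds 1.5 × its mean TOM to the rest of the network;
   everything else is `grey`. This contrast-guided descent replaces the
   full hybrid dynamic tree cut algorithm; what the analysis relies on —
   planted-partition recovery and near-total grey under a structureless
   null — is verified directly.
6. **Eigengenes**: first right singular vector of the gene-standardized
   module submatrix, unit variance, oriented to correlate positively with
   the module mean. Modules with eigengene correlation > 0.75 are merged
   (largest member's color kept).
7. **Membership gating**: MM(g,m) = cor(expr_g, ME_m); each gene goes to
   its best module only if |MM| ≥ 0.7, else grey.
8. **Module–trait statistics**: point-biserial cor(ME, CAP), Wilcoxon
   rank-sum on the eigengene, and mean |GS| with GS(g) = |cor(expr_g,
   trait)| (control = 0, CAP = 1).
9. **Hub genes**: the module subgraph is binarized at the within-module
   TOM 0.95 quantile (zero-overlap pairs never become edges), maximal
   cliques are enumerated, and MCC(v) = Σ_{C∋v} (|C|−1)! with isolated
   vertices scoring 0! = 1; top 20 reported, ties broken by gene ID.

Under the planted regime (3 modules of 60–80 genes, loading 1.0 on the
log2 scale, 127 samples) the full stage recovers the truth with adjusted
Rand index ≥ 0.93 across seeds.

## Trajectory clustering

Admission-significant genes are reduced to a 3-point profile — mean
z-scored log expression per group in the order control → admission →
recovery — and clustered by average linkage on 1 − Pearson between
profiles. The cluster count is chosen by silhouette, with two guards the
bare criterion needs: silhouette is scale-invariant and will happily split
a single noisy blob, so (a) the smallest k within 0.1 of the best
silhouette is preferred, and (b) clusters whose mean profiles correlate
above 0.9 describe the same trend and are merged. Clusters under 15 genes
dissolve into `unclustered`. Two planted antiphase patterns are recovered
with ARI = 1; a single noisy pattern collapses to one dominant cluster.

## Metabolomics

Per metabolite (intensities assumed internal-standard-normalized
upstream): a Box-Cox transform with λ chosen by maximum profile
log-likelihood on a grid over [−2, 2] (step 0.05) of the pooled two-group
values — pooling avoids group-specific transforms that would invalidate
the t test; a two-sided Student's t test with pooled variance (Welch
optional); Hedges' g = J·d with J = 1 − 3/(4n − 9), computed on the
transformed scale (raw scale available); BH across metabolites. Values
≤ 0 are shifted above zero before the transform. Five metabolites planted
at a 1.5 SD log-scale shift (26 vs 50 samples) carry the five largest |g|
in ≥ 90% of simulations, and effect-free panels stay within the BH bound.

## Phenotype association

Ex vivo degranulation is summarized as Δ = stimulated MPO − vehicle MPO
per sample (LPS and *K. pneumoniae* separately); samples without a vehicle
measurement are excluded with a log entry. Associations use Spearman's rho
on pairwise-complete observations (different assays cover different sample
subsets), with exact permutation p for n ≤ 10 and the t approximation with
midranked ties otherwise. Matrices can be stratified by group; strata
below 3 samples are omitted.

## Limit-of-quantification handling

Biomarker values below the LLOQ are imputed as LLOQ/2; values above the
ULOQ are set to the ULOQ; flags record which rule fired and survive
re-cleaning, making the operation idempotent.

## The synthetic cohort

The generator emulates the analyzed structure, not raw sequencing: NB
counts (`variance = mu + phi mu^2`, trend `phi = 3/mu + 0.1` — standard
bulk RNA-seq shape, chosen here since no distributional facts about the
original counts are available), lognormal library sizes (median ≈ 1e6,
log-SD 0.3, a desk-scale stand-in for ~40M-read libraries), lognormal
per-gene baselines, and the study's group sizes (29/64/34 transcriptomes,
26/50 metabolomes) as defaults. Planted co-expression modules are blocks
of genes sharing a standard-normal latent factor added on the log2-mean
scale with per-gene loading; the factor mean shifts in admission samples
and recovery effects are admission effects × 0.1 (`recovery_attenuation`).
Planted DE lives in named pathways (default: glycolysis up 1.5,
amino-acid metabolism down 1.5, in 80% of their genes, echoing the study's
direction of findings). The gene-set collection contains the planted
pathways plus random null sets. Metabolites are lognormal with additive
log-scale group shifts (5 of 40 at 1.5 SD by default). One biomarker
("il6") is a monotone transform of `rho·f + sqrt(1−rho²)·noise` with the
first module's latent factor f and planted rho = 0.7, so the
pathway-score–biomarker Spearman correlation has a known target;
stimulated MPO deltas load weakly on the same factor plus a group effect.
A single seeded generator drives every draw, so equal seeds give
bit-identical output files.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: cell-type composition shifts, batch and
library-preparation effects, gene-length and GC biases, count outliers,
correlated gene-gene structure beyond the planted factors, missing
metabolite values, and assay drift. Results on real cohorts additionally
depend on preprocessing choices out of scope here (alignment,
quantification, metabolite annotation).

## Problem sizes in the shipped checks

The test suite and acceptance script size their simulations for quick,
repeatable runs: 2000-gene cohorts for null calibration (20 seeds),
900-gene cohorts for module recovery (5 seeds), 600-gene cohorts for
score-shift detection (25 seeds), a 4000-gene cohort for the end-to-end
acceptance run, and a 500-gene miniature for pipeline determinism. All
magnitudes (group sizes, effect sizes, loadings) stay at their study-scale
defaults.

## Known limitations

- Exact reproduction of the original cohort's numbers (DEG counts,
  module–trait correlations, specific rho values) is impossible without
  the patient data, which were never deposited; the pipeline validates
  against planted ground truth instead.
- The DE stage is a simplified NB Wald test (see above); on real data its
  calls will differ from shrinkage-based tools near the significance
  boundary.
- The score group test is descriptive when fit and test cohorts coincide
  (see pathway scores above).
- The dynamic-tree-cut replacement and the GSEA permutation null are
  deliberate simplifications whose acceptance surface is planted-structure
  recovery, not internal equivalence with the original tools.
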