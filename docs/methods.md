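# Methods

`cogimmune` implements a two-view analysis linking cognitive functioning to
plasma inflammatory/immune markers in a transdiagnostic psychiatric cohort
(schizophrenia spectrum, SZ; bipolar spectrum, BD; healthy controls, HC),
together with a synthetic-cohort generator that plants the same statistical
structure so the whole pipeline can be verified end to end without access
to clinical data.

## The analysis pipeline

### Preprocessing

Cognitive domain scores are handled complete-case (any row missing a
cognitive value is dropped) and z-scored.  Marker columns are z-scored,
then cells beyond the Tukey fences `Q1 − 1.5·IQR` / `Q3 + 1.5·IQR`
(quartiles by linear interpolation, the R type-7 convention) are set
missing, and the holes are filled by multiple imputation with chained
equations using predictive mean matching (PMM): each incomplete column is
regressed (OLS) on all other columns among its observed rows, and every
missing cell receives the observed value of one of the 5 donors whose
predictions are closest, chosen at random.  Ten chained cycles are run and
m = 5 completed tables produced.

Order matters and is fixed: standardize → fence → impute, with the fence
applied exactly once (iterating the fence would cascade removals, and
re-standardizing after imputation would silently move the fences).
PMM guarantees every imputed value lies in the observed support of its
column.  The m completed tables are pooled cell-wise (mean) before the
CCA; a spread-over-imputations analysis is available by running the m
tables individually.  Pooling data rather than estimates is a pragmatic
choice — Rubin's rules do not apply cleanly to canonical correlations —
and is recorded as a known approximation.

### Canonical correlation analysis

Classical CCA: with block covariances `Sxx`, `Syy` and cross-covariance
`Sxy`, the singular values of `Sxx^{-1/2} Sxy Syy^{-1/2}` are the
canonical correlations `r_1 ≥ … ≥ r_K`, `K = min(p, q) = 9`.  A ridge of
`1e-10·trace/p` stabilizes the inversions and is numerical only (results
agree with the unridged solution to well below 1e-6 on full-rank data).
Participant variate scores are scaled to sample SD 1 so that distances in
score space are comparable across modes; this scaling is a convention and
affects nothing downstream except the absolute scale of regression
coefficients.  Reported "loadings" are structure correlations (variable
vs own-block variate), which is what the field usually plots; raw weights
are retained alongside.

CCA modes are defined up to reflection.  `sign_align` fixes the
orientation: verbal learning's structure loading is made positive, then
the marker side is flipped so the score correlation is non-negative.
Under this convention the planted (and reported) biology reads: low
cognitive variate ↔ low marker variate ↔ **high** IL-18, IL-18BP and
BD-2 and **low** VCAM-1 — so those three markers load negatively and
VCAM-1 positively.

### Mode inference

*Permutation test.*  The marker block's rows are shuffled (n_perm =
10,000) and the CCA refit; `p_k` compares the k-th observed correlation
against the k-th null correlations with the add-one rule
`p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1)`.  Row shuffling leaves both
within-block covariances unchanged, so the implementation reuses the
whitening matrices and recomputes only the cross-covariance — numerically
identical to a full refit, roughly 100× faster.

*Cross-validation.*  Repeated k-fold (default 10 folds × 100
repetitions): fit on the training folds, project the held-out rows
through the training weights, and correlate the projected variate pair.
Projected scores are deliberately not re-standardized.  Two numerical
facts are worth knowing.  First, held-out correlations are attenuated
even for a real mode: with noisy indicators the measurable ceiling is
`rho · R_x · R_y` (R = multiple correlation of the latent with its
block), and weight-estimation noise lowers it further — a test
correlation visibly below the training one is expected, not a defect.
Second, on null data the held-out correlation has a small *negative*
bias (≈ −0.1 at n = 200, p = q = 9): the direction chosen on the
training fold anti-correlates in its complement.  The generalization
screen therefore asks whether `mean_test / mean_train` exceeds a
configurable fraction (default 0.5), not whether `mean_test` is near the
training value.

*Jackknife.*  Delete-one refits, sign-matched to the full-sample solution
by the dot product of loading vectors, summarized as per-variable SD and
min–max envelopes.  Structure loadings are sample correlations, so even a
perfectly deterministic relation shows a small spread unless the
construction is fully degenerate.

*Mode retention.*  A mode propagates to clustering when its permutation
p < 0.05 **and** it passes the generalization screen.  On synthetic
cohorts both planted modes are genuinely present, so both typically pass;
clustering always uses the first retained mode's score pair, and the rule
thresholds are configuration, not constants.

### Clustering

Hierarchical agglomeration (scipy's Lance–Williams implementations) on
the Euclidean distance matrix of the 2-D mode-1 score pairs.  Four
linkages (average, single, complete, Ward) are compared by the
agglomerative coefficient `AC = mean_i (1 − m(i)/h_final)` (`m(i)` =
height of i's first merge); Ward dominates on these clouds with AC ≈
0.99.  Ward heights are on the distance scale; AC depends only on height
ratios and is therefore scale-invariant (tested).  The cluster count is
chosen by maximal average silhouette over k = 2…10; dendrogram and
elbow (within-cluster SS) outputs are advisory.  Cluster labels are
canonicalized so cluster 1 is lowest on the score diagonal (the "low
cognition / high innate-immune activation" subgroup).

*Silhouette significance.*  The null model is a single bivariate normal
with the sample mean/covariance of the scores; each of n_sim = 1000
draws of size n runs the full linkage + k-selection procedure and
records its best silhouette; add-one p.  A forced 2-split of a single
2-D Gaussian already scores ≈ 0.33–0.36, so observed silhouettes in the
high 0.3s are inherently borderline — the procedure asks whether the
data beat that baseline, and p-values near 0.05 should be read as the
marginal evidence they are.

*Bootstrap stability.*  Cluster-wise Jaccard stability in the spirit of
clusterboot: resample n rows with replacement, re-cluster at the same k,
and score each reference cluster by its best Jaccard overlap with a
bootstrap cluster, computed on the universe of resampled original
indices with duplicates counted once (a perfectly re-found cluster
scores 1).  Mean Jaccard > 0.7 is the customary stability yardstick.

### Group statistics

Welch t statistics with label-shuffle permutation nulls (add-one p) for
two-group comparisons, permutation one-way ANOVA (F statistic) across
the three diagnostic groups, and Pearson chi-squared for categorical
tables.  The 95% interval attached to a mean difference is a
within-group bootstrap percentile interval: a label-permutation
distribution is centered at zero by construction and cannot
interval-estimate the difference, so "Monte-Carlo percentile CI" is read
as the bootstrap.  Bonferroni families follow the reporting layout: 5
sample-characteristic tests, 15 clinical tests, and the feature block
(9 + 24 variables) as its own family.  Note the attainable adjusted-p
floor: with 10,000 permutations and a family of 33, no adjusted p can be
below 33/10,001 ≈ 0.0033.

Covariate-adjusted models are OLS of a mode-1 score on diagnosis dummies
(HC reference) plus age, sex and the four medication defined-daily-dose
(DDD) columns; the immune-side model additionally adjusts for CRP, BMI
and freezer storage time.

## The synthetic cohort generator

The generator emulates the study conditions: n = 1402 (SZ 343, BD 289,
HC 770), two latent modes of covariation with pooled correlations 0.34
and 0.22, a two-component participant mixture of sizes 625/777 with the
reported per-cluster diagnosis composition (SZ 264/79, BD 160/129, HC
201/569), ≤15% MCAR marker missingness (default rate 0.05 per cell) and
injected outliers (default 1% of observed marker cells) displaced to
`fence ± (0.05 + |N(0,1)|)·IQR` so every injected cell trips the fence
rule.

Latent model: the mode-1 pair (u1, v1) is bivariate normal around
cluster-specific means at `±(separation/2)·(1,1)/√2` — cluster 1 jointly
low — with within-cluster correlation `rho_w` chosen analytically from
the mixture identity

    pooled covariance = within covariance + between-means covariance
    ⇒ rho_pooled = (rho_w + b) / (1 + b),   b = π1·π2·separation²/2

so the pooled correlation equals the configured 0.34 exactly in
population.  `rho_w` may be negative — at the shipped calibration the
between-cluster shift carries the entire pooled correlation
(`rho_w ≈ −0.19`).  The mode-2 pair has correlation 0.22 and no cluster
structure.  Observed blocks are noisy linear expansions: unit-norm
mode-1 loading vectors concentrated on verbal learning and psychomotor
processing speed (cognitive side) and on IL-18, IL-18BP, BD-2 (negative)
and VCAM-1 (positive) on the marker side; mode-2 vectors are
orthogonalized, scaled to norm 0.7, and concentrate on working
memory/attention and the chemokines.  Residual noise is i.i.d. Gaussian,
SD 0.40 per column in both blocks.

Two generator constants are calibrations rather than arbitrary choices,
fixed once by simulating the full pipeline at n = 1402:

- `noise_sd = 0.40` balances attenuation (noise shrinks the population
  canonical correlation of the observed blocks below the latent 0.34)
  against finite-sample inflation (fitting 9 + 24 weights at n = 1402
  inflates sample canonical correlations; the null first correlation is
  already ≈ 0.2), so the pipeline's estimates center on the configured
  mode correlations.
- `separation = 2.55` is the output of `calibrate_separation`, which
  targets the 2-cluster Ward silhouette 0.37 on the estimated mode-1
  scores.  The calibration simulates generation, preprocessing, CCA and
  clustering, because that is the quantity the analysis reports.  At
  this point the bootstrap Jaccard stability of the two clusters
  averages ≈ 0.75/0.77, matching the regime the analysis is designed to
  probe (clearly present but heavily overlapping subgroups).

Cluster and diagnosis counts are exact permutations of fixed label
vectors, not multinomial draws, so composition tables reproduce
deterministically.  Covariates and clinical scores are drawn per
(group, cluster) cell as independent clipped Gaussians: group means/SDs
follow the demographic table, and an additive cluster offset reproduces
the subgroup margins.  Clinical scores exist only for SZ/BD rows; DDD
columns are zero for HC; CRP is clipped below the 20 mg/L exclusion
threshold; freezer storage time averages ≈ 6 years, shorter for HC.
Everything is drawn from a single `numpy` Generator, so a seed
reproduces the table bit-for-bit.

### What the generator does not emulate

Marker–marker and domain–domain residual correlations beyond the planted
modes (no published covariance structure exists for them); covariate–
covariate dependence within a (group, cluster) cell; non-Gaussian marker
distributions (real immunoassay data are right-skewed); assay chemistry,
diurnal or storage-degradation effects; longitudinal structure.  Passing
tests therefore demonstrate that the pipeline recovers planted structure
of the stated form and size — not that the clinical findings themselves
are reproduced, since the raw cohort is not publicly deposited.

## Numerical choices and degenerate inputs

- Quantiles: linear interpolation (type 7); configurable `k` for the
  fence rule; the fence boundary itself is inside (a constant column
  flags nothing).
- Zero-variance columns are rejected by name in z-scoring and CCA;
  collinear blocks raise with the columns most involved.
- A permutation/bootstrap/jackknife result is bit-reproducible given its
  seed; pipeline stages derive their seeds from a master seed by fixed
  offsets.
- Bootstrap resamples with fewer distinct points than k are redrawn (and
  counted); a cluster absent from a resample contributes no evidence for
  that draw.
- `p = 1` by convention when both groups are constant and equal in the
  permutation t-test; AC is defined as 0 when all points coincide.

## Problem sizes used in the test suite

Full study scale (n = 1402, 10,000 permutations, 1000 bootstrap
resamples) is used for the end-to-end recovery tests.  Distributional
property checks (type-I error, null calibration of the silhouette test,
cross-validation on noise, imputation unbiasedness) run at reduced sizes
(n ≈ 60–300, 39–199 resamples, 10–300 Monte-Carlo repetitions) — large
enough for the binomial/KS bounds asserted, chosen so the whole suite
stays quick to run.
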