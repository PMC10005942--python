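# cogimmune

Two-view canonical correlation and cluster-biotyping pipeline for
cognitive and inflammatory/immune marker data.

Severe mental illness (schizophrenia and bipolar spectrum disorders) is
accompanied in many — but not all — patients by both cognitive impairment
and low-grade immune activation.  `cogimmune` is for researchers who want
to ask whether those two layers covary, and whether the covariation
defines transdiagnostic subgroups: it links a block of **9 cognitive
domain scores** to a block of **24 plasma inflammatory/immune markers**
per participant, finds their shared modes, and clusters participants in
the resulting latent space.

The pipeline:

1. **Preprocessing** — complete-case filtering of the cognitive block,
   z-scoring, 1.5×IQR fencing of marker outliers to missing, and chained
   multiple imputation with predictive mean matching (m = 5).
2. **Canonical correlation analysis** — classical CCA via the SVD of the
   whitened cross-covariance `Σxx^{-1/2} Σxy Σyy^{-1/2}`; canonical
   correlations `r_k`, structure loadings, and SD-1 participant variate
   scores.
3. **Mode inference** — permutation significance (10,000 row shuffles of
   the marker block), repeated 10-fold cross-validation of out-of-sample
   variate correlations, and delete-one jackknife loading stability.
4. **Clustering** — Ward hierarchical clustering of the 2-D mode-1 score
   pairs, linkage comparison by agglomerative coefficient, silhouette-based
   selection of k, Gaussian-simulation significance of the silhouette, and
   bootstrap Jaccard cluster stability.
5. **Group statistics** — permutation t-tests/ANOVA, chi-squared tests,
   Bonferroni adjustment, bootstrap percentile CIs, and covariate-adjusted
   OLS models of the variate scores (diagnosis with HC reference, age,
   sex, medication DDD; plus CRP/BMI/freezer time on the marker side).

Because cohorts of this kind are not publicly deposited, the package
ships a first-class **synthetic cohort generator** that plants the full
structure — two latent modes (pooled correlations 0.34 / 0.22), a
two-component participant mixture (625/777 with realistic diagnosis
composition), calibrated covariate tables, MCAR missingness and injected
outliers — so every stage of the pipeline is testable end to end.  See
`docs/methods.md` for the model and its calibration.

## Worked example

```python
import numpy as np
from cogimmune import (
    default_config, generate_cohort, preprocess_cohort,
    fit_cca, sign_align, variance_explained, permutation_test,
    cluster_scores, COGNITIVE_DOMAINS, MARKERS,
)

table = generate_cohort(default_config(seed=1))          # 1402 participants
clean, report = preprocess_cohort(table, COGNITIVE_DOMAINS, MARKERS, seed=101)
res = sign_align(fit_cca(clean[COGNITIVE_DOMAINS], clean[MARKERS]))
print(f"r1 = {res.correlations[0]:.3f}  "
      f"({variance_explained(res.correlations[0]):.1f}% shared variance)")
print(f"r2 = {res.correlations[1]:.3f}")

perm = permutation_test(clean[COGNITIVE_DOMAINS], clean[MARKERS],
                        n_perm=10_000, seed=202)
print(f"mode-1 permutation p = {perm.p_values[0]:.2g}")

pts = np.column_stack([res.x_scores[:, 0], res.y_scores[:, 0]])
sol = cluster_scores(pts, method="ward", n_sim=200, n_boot=200, seed=404)
print(f"k = {sol.k}, silhouette = {sol.avg_silhouette:.3f}, "
      f"Jaccard = {np.round(sol.jaccard, 2)}")
```

Output:

```
r1 = 0.344  (11.9% shared variance)
r2 = 0.244
mode-1 permutation p = 0.0001
k = 2, silhouette = 0.403, Jaccard = [0.77 0.79]
```

Read: the first canonical mode links low verbal learning / psychomotor
processing speed to high IL-18, IL-18BP and BD-2 with low VCAM-1 (about
12% shared variance here), is far beyond anything produced by shuffling
the marker rows (p = 1/10,001), and the participant scores split into
two moderately separated but bootstrap-stable subgroups — cluster 1
being the low-cognition / high-innate-immune-activation group.

The same run is available from the shell:

```bash
cogimmune generate --seed 1 --out cohort.csv
cogimmune preprocess --in cohort.csv --out clean.csv --report report.json --seed 101
cogimmune cca --in clean.csv --out-prefix cca
cogimmune cluster --scores cca.scores.csv --seed 404 --out clusters.json
cogimmune run-all --seed 1 --out run/        # everything, with a manifest
```

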