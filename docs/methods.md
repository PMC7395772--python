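# Methods

## The problem and the generative model

Regional grey-matter volumes (VOIs) scale with total intracranial volume
(TIV), and TIV differs strongly by sex. The package compares how adjustment
methods separate this gross-morphology effect from region-specific sex
effects. Because the suitable real cohorts are access-restricted, all
analyses run on synthetic cohorts from a generator whose structure makes the
methodological contrasts analytic rather than accidental.

The generator is multiplicative (log-normal):

```
TIV_i    ~ Normal(mu_sex, sigma_TIV), redrawn if more than 3 sd below mean
log V_ir = a_r + b_r (log TIV_i − log 1500) + beta_r · 1[male] + eps_ir
eps_ir   ~ Normal(0, sigma_r)
```

Under this model the PCP adjustment `V / TIV^b` is *exactly* correctly
specified — fitting `b` on log-log scale and dividing removes all TIV
dependence — while the proportions adjustment `V / TIV` is mis-specified
whenever `b_r ≠ 1`: for `b_r < 1` it over-corrects and *inverts* the TIV
dependence. The residuals method removes the best linear approximation of
the (locally nearly linear) power law. This gives the method comparison an
analytic ground truth. The intercept `a_r` is parameterized as the
log-volume at a fixed 1500 ml reference TIV so that a uniform intercept
range maps onto realistic region sizes regardless of the drawn exponent.

### Default parameters (units: ml; log-scale quantities dimensionless)

| parameter | default | rationale |
|---|---|---|
| n per sex | 444 | a large two-site-style cohort |
| regions | 116 | standard whole-brain parcellation size |
| TIV means (F, M) | 1339.9, 1552.7 | gap 212.8 ml |
| TIV sd | 114.4 | gap/sd = 1.86, the canonical standardized TIV gap |
| b_r | Uniform(0.5, 1.1) | allometric exponents below and slightly above 1 |
| sigma_r | Uniform(0.07, 0.18) | with the b range, TIV explains from a few % up to ~70% of raw volume variance and raw sex differences are uniformly M > F with d ≈ 0.3–1.5, mean near 1 |
| beta_r | Normal(0, 0.015) | after proper adjustment, per-region d values are small (mostly within ±0.35) and bidirectional, with a minority crossing p < 0.05 at n = 888 |
| a_r | Uniform(log 1.5, log 80) | region volumes ~1.5–80 ml at reference TIV |

These defaults are fixed once; all pattern-level tests run against them.
Region parameters can be drawn separately (`sample_region_params`) and shared
between cohorts, so an "original" and a "replication" study sample the same
population of regions with independent subjects. The built-in two-study
configuration gives the original study 171 + 185 subjects with a smaller TIV
gap (142.8 ml) and narrower TIV sd (0.85×), mimicking site differences: raw
effect sizes depend on the local TIV distribution and therefore travel badly
between such studies, while properly adjusted effects do not. That contrast
— not any tuned constant — is what the replication analyses measure.

What the generator does *not* emulate: between-region correlation beyond the
shared TIV factor, age structure, segmentation/measurement error in TIV, and
site effects other than the TIV distribution. Passing pattern tests
therefore show that the *pipeline* behaves as the theory predicts under a
clean allometric model, not that real cohorts would produce the same
numbers.

## Adjustment

All slopes/exponents are fitted pooled across sexes (a deliberate choice: the
diagnostic logic uses a single TIV–VOI line per region; a sex-stratified fit
would remove part of the sex effect itself). Natural logs are used for the
PCP fit — the slope is base-invariant. By default each cohort is adjusted
within itself; a `fit_cohort` argument provides the leakage-aware
fit-on-train mode for prediction workflows. Adjusted values keep their
natural scale (ratios for proportions/PCP, ml for residuals); no
re-multiplication by a reference TIV is applied, since every downstream
statistic is scale-free.

The image-space "scaling" normalization available in VBM pipelines cannot be
reproduced from volume tables; a labelled *surrogate* is provided instead,
multiplying volumes by `(TIV_ref / TIV)^gamma`. `gamma = 1` reproduces
proportions up to a constant; the default `gamma = 0.8` leaves a deliberate
residual TIV dependence (residual exponent `b − gamma`), matching the
qualitative behaviour of a partial correction.

## Univariate effects

Cohen's d uses the pooled sd; its 95% CI inverts the noncentral-t
distribution of `t = d·√(n₁n₂/(n₁+n₂))` at `df = n₁+n₂−2` (more accurate
than the normal approximation; a Hedges small-sample correction is available
behind a flag but off by default, since at n ≈ 900 the bias factor is
≈ 1.001). The mean-difference CI and p come from the equal-variance Student
t-test, so CI-excludes-zero and p < 0.05 are exactly dual. Benjamini–
Hochberg is labelled FDR and Bonferroni FWER. Overlap uses
`OVL = 2Φ(−|d|/2)` (shared area of two unit-variance normals) and the
probability of superiority `PS = Φ(d/√2)`; `ps_from_d` is strictly
increasing with `PS(d) + PS(−d) = 100%`, and reports use the favored-group
convention `ps_from_d(|d|)`. Because the published reference values for
these transforms are computed from d values themselves rounded to two
decimals, agreement is asserted to half a unit in the last printed decimal.

## TIV-dependence diagnostics

Per-region OLS of adjusted volume on TIV (slope, r², slope-test p), plus
Spearman correlations (average-rank ties, t-approximation p) between the
slopes and the per-region p, mean difference, and d. Raw p-values are used —
the diagnostic asks whether apparent effects track TIV leverage, not whether
they survive multiplicity control. On residuals-adjusted fit samples the
slopes are zero by OLS orthogonality (asserted to float tolerance).

## Replication and meta-analysis

The 95% prediction interval for a replication's d is
`d_orig ± t_{0.975, df_orig}·√(var(d_orig) + var(d_rep))` with the standard
large-sample `var(d) = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))` and
`df_orig = n₁+n₂−2`. The construction was validated by simulation: over
10,000 original/replication pairs drawn from a common effect at the default
study sizes, empirical coverage is within 1% of nominal (this simulation is
part of the test suite). PI bounds are inclusive. Rates are compared by
Pearson χ² on the replicated-vs-not 2×k table without continuity correction
(df = k−1), with all-pairs 2×2 χ² tests BH-adjusted.

Replicated effects are pooled by fixed-effect inverse-variance weighting —
with two studies a random-effects τ² is essentially unestimable, so the
fixed-effect model is the defensible default. The future-study PI around the
pooled estimate assumes a nominal future study the size of the smaller input
study and uses that study's t df; both choices are parameters, not claims
about any external convention.

A calibration fact worth knowing: with no region-specific sex effects
(β = 0) *and* a sex gap in TIV, the residuals-then-t-test procedure is
conservative (observed type-I ≈ 1% at α = 0.05 in simulation) because
residualizing on a covariate collinear with group absorbs part of the chance
group contrast. Under the exchangeable null (β = 0, no TIV gap) the rate is
the nominal 5%. The test suite asserts both.

## Classification harness

Features are z-scored with parameters fitted on the training subsample only
(fitting on each subsample separately is available by flag; train-only is
the leakage-safe default). Splits are stratified and sex-balanced —
`round(fraction × per-sex n)` per split, remainder to the last split, so a
70% split of 444 + 444 gives 311 + 311 train and 133 + 133 test.

Classifier conventions: KNN `k = round(√n_train)` (k = 25 at n = 622); random
forest 500 trees with 10 candidate features per split; SVMs tuned by
stratified 10-fold CV over `C ∈ {10⁻³…10³}` and
`γ ∈ {0.0001, 0.001, 0.01, 0.1, 0.5, 1, 2, 3, 4, 5}` with ties broken toward
smaller C then smaller γ; elastic-net logistic regression with mixing
parameter 0.5 and λ by 10-fold CV; the neural network is a single
logistic hidden unit (the minimal architecture, seeded); FDA is implemented
as LDA on a fixed cubic-spline basis expansion of each feature — a
documented surrogate for adaptive-spline FDA, which has no faithful
equivalent here. QDA with a singular within-class covariance (class n ≤ p)
raises an error advising the `reg_param` shrinkage flag rather than silently
regularizing. All stochastic learners take seeds derived stably from a
global seed plus the dataset and classifier names.

Accuracy CIs are exact (Clopper–Pearson); κ CIs use the large-sample
variance. For balanced evaluation sets κ = 2·accuracy − 1, asserted in the
tests. PAM (k-medoids, deterministic BUILD + SWAP with lowest-index
tie-breaks) is run for K = 2…5 on Euclidean distances between dataset
accuracy profiles; the max-silhouette K wins, and a separation ratio
(mean between- over mean within-cluster dissimilarity) is reported.
Identical profiles make the silhouette undefined; that case is flagged
degenerate rather than raised. Average-linkage hierarchical ordering is
provided for display; merge heights are non-decreasing by construction.

## Problem sizes and numerical choices

The shipped tests exercise the univariate and replication stages at the full
default scale (888 subjects × 116 regions) and the classification stage on a
reduced design (500 subjects × 40 regions, six classifiers with small SVM
grids) — the cluster structure of interest is already unambiguous there, and
`analysis/05_classification.py --full` runs the complete roster and grids.
Monte-Carlo checks use 10,000 replicates (PI coverage, d-variance) or
120–150 cohorts (error-rate calibration). SVC solves are capped at 200,000
libsvm iterations: on heavily overlapping data (TIV-free features, large C)
the solver's marginal iterations change the decision boundary negligibly but
can dominate runtime; capped fits are treated as converged for tuning. Degenerate inputs (zero TIV
variance, non-positive volumes, constant features, single-sex tables) raise
typed errors naming the offending subjects or features.

## Known limitations

* The scaling surrogate is a statistical stand-in, not image-space scaling;
  conclusions about "scaling" transfer only at the level of partial
  correction.
* The generator's independence of regions given TIV understates the
  between-region correlation of real morphometry; multivariate accuracies on
  synthetic data are therefore optimistic for the adjusted datasets relative
  to matched real data.
* Fixed-effect pooling and the future-study PI size are conventions; with
  k = 2 studies no data-driven alternative is identifiable.
* Only binary F/M labels are supported, matching the design of the analyses
  the package implements.
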