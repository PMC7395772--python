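# tivcompare

Head size is the single largest confound in volumetric brain morphometry:
males have, on average, much larger total intracranial volume (TIV) than
females (standardized gap around d ≈ 1.9), and every regional grey-matter
volume scales with TIV. Any claim about "sex differences" in a region's
volume therefore depends critically on how TIV is adjusted for — and the
commonly used adjustments are not interchangeable.

`tivcompare` is an analysis toolkit for comparing TIV-adjustment methods on
subject × region volume tables. It implements:

* **Adjustment methods** with a fit/apply separation:
  * *proportions*: `VOI / TIV`
  * *power-corrected proportions (PCP)*: `VOI / TIV^b`, with `b` the
    per-region OLS slope of `log(VOI) ~ log(TIV)`
  * *residuals*: `VOI − b·(TIV − mean TIV)`, with `b` the per-region OLS
    slope of `VOI ~ TIV`
  * a *scaling surrogate* — a partial power correction toward a reference
    TIV standing in for image-space scaling normalization (synthetic; no
    image processing is performed)
* **Univariate effect estimation** per region: Cohen's
  `d = (x̄_M − x̄_F)/s_pooled` with noncentral-t CIs, unstandardized mean
  differences with Student-t CIs and p-values (BH/FDR and Bonferroni/FWER
  adjusted), and the interpretability transforms
  `OVL = 2·Φ(−|d|/2)` (percent of distribution overlap) and
  `PS = Φ(d/√2)` (probability of superiority).
* **TIV-dependence diagnostics**: per-region regressions of adjusted volumes
  on TIV, and Spearman correlations of the TIV slopes with the sex-difference
  statistics.
* **Replication assessment**: 95% prediction intervals
  `d_orig ± t_{0.975, n₁+n₂−2}·√(var(d_orig) + var(d_rep))` with
  `var(d) = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))`, replication-rate χ² and
  pairwise comparisons, and fixed-effect (inverse-variance) meta-analysis of
  replicated effects with future-study prediction intervals.
* **A sex-prediction harness**: 12 classifiers (LDA, QDA, KNN with
  `k = round(√n_train)`, logistic regression, elastic-net logistic
  regression, FDA as LDA on a spline basis, classification tree, random
  forest with 500 trees × 10 features, a small neural network, and
  linear/RBF/cubic SVMs tuned by 10-fold CV), evaluated by accuracy with
  exact binomial CIs and Cohen's κ, with PAM clustering and average-linkage
  ordering of the dataset accuracy profiles.
* **A synthetic-cohort generator** with known allometric structure
  (`log V = a + b·log TIV + β·male + ε`), so the whole chain is testable
  without access-restricted MRI data.

## Worked example

```python
import tivcompare as tc

original, replication = tc.two_cohort_configs(seed=1)  # two synthetic studies
raw = tc.effect_table(tc.adjust(replication, "raw"))
pcp = tc.effect_table(tc.adjust(replication, "pcp"))
print(f"raw: d in [{raw.d.min():+.2f}, {raw.d.max():+.2f}], mean {raw.d.mean():+.2f}")
print(f"pcp: d in [{pcp.d.min():+.2f}, {pcp.d.max():+.2f}], mean {pcp.d.mean():+.2f}")

rec, rate = tc.assess_replication(
    tc.effect_table(tc.adjust(original, "raw")), raw)
print(f"raw effects replicated: {100 * rate:.1f}%")
```

prints

```
raw: d in [+0.31, +1.52], mean +0.90
pcp: d in [-0.22, +0.25], mean +0.00
raw effects replicated: 59.5%
```

Unadjusted volumes show large, uniformly male-favoring differences (they
conflate the TIV gap with region-specific effects) and those effects fail to
replicate in a second cohort with a different TIV distribution; after a PCP
adjustment the differences are small, bidirectional, and (in the same run)
replicate at 100%.

The numbered drivers under `analysis/` run the full workflow and write their
tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_univariate_effects.py
python analysis/03_tiv_dependence.py
python analysis/04_replication.py
python analysis/05_classification.py
```

A thin CLI wraps the same stages: `tivcompare --seed 1 --out results all`.

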