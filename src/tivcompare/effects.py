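"""Per-region univariate sex-difference estimation.

For each region the male-female contrast is summarized by:

* Cohen's d (pooled-sd standardized mean difference, positive = M > F) with a
  95% CI obtained by inverting the noncentral-t distribution;
* the unstandardized mean difference with its equal-variance Student-t 95% CI
  and two-sided p-value (the CI excludes zero exactly when p < 0.05);
* Benjamini-Hochberg (FDR) and Bonferroni (FWER) adjusted p-values;
* two interpretability transforms of d: the percent of overlap of two
  unit-variance normal distributions (Weitzman's delta, OVL = 2 Phi(-|d|/2))
  and the probability of superiority (PS = Phi(d / sqrt 2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .adjustment import AdjustedTable


class EffectError(ValueError):
    pass


@dataclass(frozen=True)
class EffectRecord:
    """Univariate sex-difference summary for one region (difference = M - F)."""

    region: str
    n_f: int
    n_m: int
    mean_f: float
    mean_m: float
    mean_diff: float
    mean_diff_lo: float
    mean_diff_hi: float
    d: float
    d_lo: float
    d_hi: float
    t: float
    p_raw: float
    overlap: float       # percent, of the favored-group contrast (symmetric in +-d)
    ps: float            # percent of superiority of the favored group
    p_bh: float = np.nan
    p_bonf: float = np.nan


def _pooled_sd(m: np.ndarray, f: np.ndarray) -> float:
    n1, n2 = len(m), len(f)
    return np.sqrt(((n1 - 1) * m.var(ddof=1) + (n2 - 1) * f.var(ddof=1)) / (n1 + n2 - 2))


def cohens_d(values_m, values_f, level: float = 0.95, hedges: bool = False):
    """Cohen's d (M - F, pooled sd) with a noncentral-t CI.

    The CI inverts the noncentral-t distribution of t = d * sqrt(n1 n2/(n1+n2))
    at df = n1+n2-2. With ``hedges=True`` the point estimate and CI are
    multiplied by the small-sample correction 1 - 3/(4 df - 1).
    """
    m = np.asarray(values_m, dtype=float)
    f = np.asarray(values_f, dtype=float)
    n1, n2 = len(m), len(f)
    if n1 < 2 or n2 < 2:
        raise EffectError("need at least 2 observations per group")
    sp = _pooled_sd(m, f)
    if sp == 0:
        raise EffectError("zero pooled standard deviation; d undefined")
    d = (m.mean() - f.mean()) / sp
    df = n1 + n2 - 2
    scale = np.sqrt(n1 * n2 / (n1 + n2))
    t_obs = d * scale
    alpha = 1 - level

    def cdf(nc):
        v = stats.nct.cdf(t_obs, df, nc)
        if np.isnan(v):  # scipy far-tail underflow; cdf is decreasing in nc
            return 1.0 if nc < t_obs else 0.0
        return v

    def nc_for(prob):
        # noncentrality nc with P(T_{df,nc} <= t_obs) = prob; the solution lies
        # within a few units of t_obs on the scale sqrt(1 + t^2/(2 df))
        width = 10.0 * np.sqrt(1.0 + t_obs * t_obs / (2.0 * df))
        lo, hi = t_obs - width, t_obs + width
        return optimize.brentq(lambda nc: cdf(nc) - prob, lo, hi)

    d_lo = nc_for(1 - alpha / 2) / scale
    d_hi = nc_for(alpha / 2) / scale
    if hedges:
        g = 1 - 3 / (4 * df - 1)
        d, d_lo, d_hi = g * d, g * d_lo, g * d_hi
    return d, (d_lo, d_hi)


def mean_diff_ci(values_m, values_f, level: float = 0.95):
    """Unstandardized difference (M - F) with equal-variance Student-t CI and p.

    Returns (diff, (lo, hi), t, p). The CI excludes zero iff p < 1 - level.
    """
    m = np.asarray(values_m, dtype=float)
    f = np.asarray(values_f, dtype=float)
    n1, n2 = len(m), len(f)
    if n1 < 2 or n2 < 2:
        raise EffectError("need at least 2 observations per group")
    diff = m.mean() - f.mean()
    sp = _pooled_sd(m, f)
    se = sp * np.sqrt(1 / n1 + 1 / n2)
    df = n1 + n2 - 2
    if se == 0:
        return diff, (diff, diff), np.inf if diff else 0.0, 0.0 if diff else 1.0
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf((1 + level) / 2, df)
    return diff, (diff - tcrit * se, diff + tcrit * se), t, p


def overlap_from_d(d: float) -> float:
    """Percent of overlap (Weitzman's delta) of two unit-variance normals, 2 Phi(-|d|/2) * 100."""
    return float(200.0 * stats.norm.cdf(-abs(d) / 2.0))


def ps_from_d(d: float) -> float:
    """Probability of superiority Phi(d / sqrt 2) * 100; strictly increasing in d.

    PS(d) + PS(-d) = 100. The favored-group convention used in reports is
    ``ps_from_d(abs(d))``.
    """
    return float(100.0 * stats.norm.cdf(d / np.sqrt(2.0)))


def adjust_pvalues(p, method: str):
    """BH ('bh', step-up FDR) or Bonferroni ('bonferroni') adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise EffectError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise EffectError(f"unknown method {method!r}")
    return multipletests(p, method=key)[1]


def effect_table(adjusted: AdjustedTable, hedges: bool = False) -> pd.DataFrame:
    """One :class:`EffectRecord` per region, as a DataFrame.

    Overlap and PS are reported for the favored-group contrast (|d|), matching
    the usual reporting convention; d and the mean difference keep their sign
    (positive = M > F).
    """
    male = adjusted.sex == "M"
    female = adjusted.sex == "F"
    if male.sum() < 2 or female.sum() < 2:
        raise EffectError("both sexes need at least 2 subjects")
    records = []
    for j, region in enumerate(adjusted.region_names):
        vm = adjusted.values[male, j]
        vf = adjusted.values[female, j]
        d, (d_lo, d_hi) = cohens_d(vm, vf, hedges=hedges)
        diff, (lo, hi), t, p = mean_diff_ci(vm, vf)
        records.append(
            EffectRecord(
                region=region,
                n_f=int(female.sum()),
                n_m=int(male.sum()),
                mean_f=float(vf.mean()),
                mean_m=float(vm.mean()),
                mean_diff=diff,
                mean_diff_lo=lo,
                mean_diff_hi=hi,
                d=d,
                d_lo=d_lo,
                d_hi=d_hi,
                t=t,
                p_raw=p,
                overlap=overlap_from_d(d),
                ps=ps_from_d(abs(d)),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in records])
    df["p_bh"] = adjust_pvalues(df["p_raw"].to_numpy(), "bh")
    df["p_bonf"] = adjust_pvalues(df["p_raw"].to_numpy(), "bonferroni")
    return df
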