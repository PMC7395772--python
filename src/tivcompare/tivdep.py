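"""Residual TIV-dependence diagnostics for (adjusted) volume tables.

Two questions are asked of every dataset: (1) how much of each region's
variance is still explained by a linear regression on TIV, and (2) whether the
per-region TIV slopes track the size and significance of the sex differences
(Spearman rank correlations of slopes against p-values, unstandardized mean
differences, and Cohen's d). In properly adjusted data both the slopes and
the correlations should be indistinguishable from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .adjustment import AdjustedTable


@dataclass(frozen=True)
class SlopeEffectCorrelation:
    target: str   # 'p_value' | 'mean_diff' | 'd'
    rho: float
    p: float


def tiv_regressions(adjusted: AdjustedTable, tiv=None) -> pd.DataFrame:
    """Per-region OLS of adjusted volume on TIV: slope, intercept, r², slope p-value."""
    tiv = adjusted.tiv if tiv is None else np.asarray(tiv, dtype=float)
    if len(tiv) < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(tiv) == 0:
        raise ValueError("TIV has zero variance")
    rows = []
    for j, region in enumerate(adjusted.region_names):
        res = stats.linregress(tiv, adjusted.values[:, j])
        rows.append(
            {
                "region": region,
                "slope": res.slope,
                "intercept": res.intercept,
                "r2": res.rvalue**2,
                "p": res.pvalue,
            }
        )
    return pd.DataFrame(rows)


def slope_effect_correlations(
    regressions: pd.DataFrame, effects: pd.DataFrame
) -> list[SlopeEffectCorrelation]:
    """Spearman rho of TIV slopes vs the per-region p, mean difference, and d.

    Ranks use average-rank tie handling; two-sided p-values come from the
    t-distribution approximation. Raw (unadjusted) p-values are correlated,
    matching the diagnostic as usually run.
    """
    if len(regressions) != len(effects):
        raise ValueError("regression and effect tables must cover the same regions")
    if len(regressions) < 5:
        raise ValueError("need at least 5 regions for a meaningful rank correlation")
    if not np.array_equal(regressions["region"].to_numpy(), effects["region"].to_numpy()):
        raise ValueError("region ordering mismatch")
    slopes = regressions["slope"].to_numpy()
    out = []
    for target, column in (("p_value", "p_raw"), ("mean_diff", "mean_diff"), ("d", "d")):
        rho, p = stats.spearmanr(slopes, effects[column].to_numpy())
        out.append(SlopeEffectCorrelation(target=target, rho=float(rho), p=float(p)))
    return out
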