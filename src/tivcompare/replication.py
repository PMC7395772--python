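"""Prediction-interval replication assessment and meta-analysis of effects.

An original study's Cohen's d defines a 95% prediction interval (PI) for the
d an exact replication of given size should observe if the two samples differ
only by sampling error:

    PI = d_orig +/- t_{0.975, n1+n2-2} * sqrt(var(d_orig) + var(d_rep))

with the standard large-sample variance var(d) = (n1+n2)/(n1 n2) + d²/(2(n1+n2)).
A region's effect "replicates" when the replication d falls inside the PI
(inclusive bounds). Replication rates across datasets are compared with a
Pearson chi-square test of independence on the replicated/not 2 x k table
(no continuity correction) and BH-adjusted pairwise 2 x 2 tests. Replicated
effects are pooled by fixed-effect (inverse-variance) meta-analysis, and a new
PI for a nominal future study (sized like the smaller input study) is derived
from the pooled estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class MetaEffect:
    """Fixed-effect pooled d with CI and a future-study prediction interval."""

    region: str
    d_meta: float
    ci: tuple[float, float]
    pi_future: tuple[float, float]


def d_variance(d: float, n1: int, n2: int) -> float:
    """Large-sample variance of Cohen's d: (n1+n2)/(n1 n2) + d²/(2(n1+n2))."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 per group")
    n1, n2 = float(n1), float(n2)
    return (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))


def prediction_interval_d(
    d_orig: float,
    n_orig: tuple[int, int],
    n_rep: tuple[int, int],
    level: float = 0.95,
) -> tuple[float, float]:
    """95% (by default) prediction interval for the replication study's d.

    Symmetric about d_orig; the t critical value uses the original study's
    degrees of freedom (n1 + n2 - 2); the width combines both studies'
    sampling variances and shrinks to zero as both sample sizes grow.
    """
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    df = n_orig[0] + n_orig[1] - 2
    half = stats.t.ppf((1 + level) / 2, df) * np.sqrt(
        d_variance(d_orig, *n_orig) + d_variance(d_orig, *n_rep)
    )
    return (d_orig - half, d_orig + half)


def assess_replication(
    original: pd.DataFrame, replication: pd.DataFrame, level: float = 0.95
) -> tuple[pd.DataFrame, float]:
    """Flag, per region, whether the replication d falls inside the original's PI.

    Both inputs are effect tables (see :func:`tivcompare.effects.effect_table`)
    over the same regions. Records are additionally classified as
    'difference' / 'no_difference' by whether the replication mean-difference
    CI excludes zero. Returns (record table, replication rate).
    """
    if not np.array_equal(original["region"].to_numpy(), replication["region"].to_numpy()):
        raise ValueError("original and replication tables must cover the same regions, in order")
    rows = []
    for o, r in zip(original.itertuples(), replication.itertuples()):
        lo, hi = prediction_interval_d(o.d, (o.n_f, o.n_m), (r.n_f, r.n_m), level)
        replicated = bool(lo <= r.d <= hi)  # inclusive bounds
        excludes_zero = (r.mean_diff_lo > 0) or (r.mean_diff_hi < 0)
        rows.append(
            {
                "region": o.region,
                "d_orig": o.d,
                "pi_lo": lo,
                "pi_hi": hi,
                "d_rep": r.d,
                "replicated": replicated,
                "classification": "difference" if excludes_zero else "no_difference",
            }
        )
    table = pd.DataFrame(rows)
    return table, float(table["replicated"].mean())


def replication_chi_square(counts, total: int):
    """Pearson chi-square of independence on the replicated-vs-not 2 x k table.

    No continuity correction; df = k - 1. Returns (chi2, df, p).
    """
    counts = np.asarray(counts, dtype=float)
    if total <= 0:
        raise ValueError("total must be positive")
    if np.any(counts > total) or np.any(counts < 0):
        raise ValueError("counts must lie in [0, total]")
    table = np.vstack([counts, total - counts])
    if (table.sum(axis=1) == 0).any():  # every dataset (non-)replicated everything
        return 0.0, len(counts) - 1, 1.0
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def pairwise_rate_tests(counts, total: int, method: str = "fdr_bh") -> pd.DataFrame:
    """All-pairs 2 x 2 chi-square tests of replication rates, BH-adjusted.

    Returns a symmetric k x k DataFrame of adjusted p-values with unit diagonal.
    """
    from statsmodels.stats.multitest import multipletests

    counts = np.asarray(counts, dtype=float)
    k = len(counts)
    if k < 2:
        raise ValueError("need at least 2 datasets")
    pairs, raw = [], []
    for i in range(k):
        for j in range(i + 1, k):
            if counts[i] == counts[j]:
                p = 1.0
            else:
                table = np.array(
                    [[counts[i], total - counts[i]], [counts[j], total - counts[j]]]
                )
                _, p, _, _ = stats.chi2_contingency(table, correction=False)
            pairs.append((i, j))
            raw.append(p)
    adj = multipletests(raw, method=method)[1]
    out = np.eye(k)
    for (i, j), p in zip(pairs, adj):
        out[i, j] = out[j, i] = p
    return pd.DataFrame(out)


def meta_fixed_effect(
    d1: float,
    n1: tuple[int, int],
    d2: float,
    n2: tuple[int, int],
    region: str = "",
    level: float = 0.95,
) -> MetaEffect:
    """Fixed-effect (inverse-variance) pooled d over two studies.

    The CI is the normal-theory interval of the pooled estimate. The future
    PI assumes a nominal future study the size of the smaller input study and
    uses that study's t degrees of freedom; it always contains the CI.
    """
    v1 = d_variance(d1, *n1)
    v2 = d_variance(d2, *n2)
    w1, w2 = 1.0 / v1, 1.0 / v2
    d_meta = (w1 * d1 + w2 * d2) / (w1 + w2)
    se = np.sqrt(1.0 / (w1 + w2))
    z = stats.norm.ppf((1 + level) / 2)
    ci = (d_meta - z * se, d_meta + z * se)
    n_future = min(n1, n2, key=lambda n: n[0] + n[1])
    df = n_future[0] + n_future[1] - 2
    half = stats.t.ppf((1 + level) / 2, df) * np.sqrt(
        1.0 / (w1 + w2) + d_variance(d_meta, *n_future)
    )
    return MetaEffect(region=region, d_meta=float(d_meta), ci=ci,
                      pi_future=(d_meta - half, d_meta + half))


def summarize_replication(records: pd.DataFrame, replication: pd.DataFrame) -> dict:
    """Direction-stratified summary of the replicated effects of one dataset.

    Returns replicated/difference/no-difference counts and, for each
    direction (M > F: d > 0; F > M: d < 0) among replicated 'difference'
    regions, the min/max/mean replication d with the overlap and
    probability-of-superiority transforms of the mean (favored-group
    convention).
    """
    from .effects import overlap_from_d, ps_from_d

    merged = records.merge(replication[["region", "d"]].rename(columns={"d": "d_rep_tab"}),
                           on="region")
    rep = merged[merged["replicated"]]
    diff = rep[rep["classification"] == "difference"]
    out = {
        "replicated": int(len(rep)),
        "differences": int(len(diff)),
        "no_differences": int(len(rep) - len(diff)),
    }
    for label, sub in (("m_gt_f", diff[diff["d_rep_tab"] > 0]),
                       ("f_gt_m", diff[diff["d_rep_tab"] < 0])):
        if len(sub) == 0:
            out[label] = None
            continue
        d = sub["d_rep_tab"]
        mean = float(d.mean())
        out[label] = {
            "count": int(len(sub)),
            "d_min": float(d.abs().min() * np.sign(mean)),
            "d_max": float(d.abs().max() * np.sign(mean)),
            "d_mean": mean,
            "overlap": overlap_from_d(mean),
            "ps": ps_from_d(abs(mean)),
        }
    return out


def meta_analyze_replicated(
    original: pd.DataFrame, replication: pd.DataFrame, records: pd.DataFrame
) -> pd.DataFrame:
    """Pool original and replication d for every replicated region."""
    rows = []
    rep_index = records.set_index("region")["replicated"]
    orig = original.set_index("region")
    repl = replication.set_index("region")
    for region, flag in rep_index.items():
        if not flag:
            continue
        o, r = orig.loc[region], repl.loc[region]
        eff = meta_fixed_effect(
            o["d"], (int(o["n_f"]), int(o["n_m"])),
            r["d"], (int(r["n_f"]), int(r["n_m"])),
            region=region,
        )
        rows.append(
            {
                "region": region,
                "d_meta": eff.d_meta,
                "ci_lo": eff.ci[0],
                "ci_hi": eff.ci[1],
                "pi_future_lo": eff.pi_future[0],
                "pi_future_hi": eff.pi_future[1],
            }
        )
    return pd.DataFrame(rows)
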