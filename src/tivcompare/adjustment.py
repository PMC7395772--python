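"""Head-size (TIV) adjustment methods with a fit/apply separation.

Implemented methods:

* ``raw``          — identity (no adjustment).
* ``proportions``  — VOI / TIV.
* ``pcp``          — power-corrected proportions, VOI / TIV**b with b the
  per-region OLS slope of log(VOI) on log(TIV) (base-invariant).
* ``residuals``    — VOI - b * (TIV - mean TIV) with b the per-region OLS
  slope of VOI on TIV; the mean TIV of the fit sample is stored and reused.
* ``scaling_surrogate`` — partial power correction toward a reference TIV
  (see :func:`tivcompare.synthetic.make_scaling_surrogate`).

Parameters are fitted pooled across sexes (an optional sex-stratified fit is
available but off by default), and — matching how each study sample is
adjusted within itself — fitting defaults to the cohort being adjusted unless
an explicit fit cohort is supplied (leakage-aware mode for classification).
Adjusted values are left on their natural scale (ratios for proportions/PCP,
ml for residuals); all downstream effect sizes are scale-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable
from .synthetic import make_scaling_surrogate

METHODS = ("raw", "proportions", "pcp", "residuals", "scaling_surrogate")


class AdjustmentError(ValueError):
    pass


@dataclass(frozen=True)
class AdjustmentParams:
    """Fitted per-region adjustment parameters.

    ``slopes_by_sex`` is populated only by the (non-default) sex-stratified
    fit; when present, apply() uses each subject's own-sex slope.
    """

    method: str
    slopes: np.ndarray | None = None   # b_r: log-log slope (pcp) or linear slope (residuals)
    tiv_mean: float | None = None      # fit-sample mean TIV (residuals only)
    fit_n: int | None = None
    region_names: tuple = ()
    slopes_by_sex: dict | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "slopes": None if self.slopes is None else list(map(float, self.slopes)),
                "tiv_mean": self.tiv_mean,
                "fit_n": self.fit_n,
                "region_names": list(self.region_names),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AdjustmentParams":
        d = json.loads(text)
        return cls(
            method=d["method"],
            slopes=None if d["slopes"] is None else np.asarray(d["slopes"], dtype=float),
            tiv_mean=d["tiv_mean"],
            fit_n=d["fit_n"],
            region_names=tuple(d["region_names"]),
        )


@dataclass
class AdjustedTable:
    """Adjusted volumes, same shape as the source cohort, with provenance."""

    cohort: CohortTable
    values: np.ndarray
    method: str
    params: AdjustmentParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.shape != self.cohort.volumes.shape:
            raise AdjustmentError("adjusted values shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise AdjustmentError("adjusted values must be finite")

    @property
    def region_names(self):
        return self.cohort.region_names

    @property
    def sex(self):
        return self.cohort.sex

    @property
    def tiv(self):
        return self.cohort.tiv


def _check_fit_sample(cohort: CohortTable) -> None:
    if cohort.n_subjects < 3:
        raise AdjustmentError("need at least 3 subjects to fit an adjustment")
    if np.ptp(cohort.tiv) == 0:
        raise AdjustmentError("TIV has zero variance; slope undefined")


def _ols_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column OLS slope of y (n, r) on x (n,)."""
    xc = x - x.mean()
    return xc @ (y - y.mean(axis=0)) / (xc @ xc)


def proportions_adjust(cohort: CohortTable) -> AdjustedTable:
    """VOI / TIV, the simple ratio adjustment (dimensionless)."""
    return AdjustedTable(cohort, cohort.volumes / cohort.tiv[:, None], "proportions")


def pcp_fit(cohort: CohortTable, by_sex: bool = False) -> AdjustmentParams:
    """Fit per-region power-corrected-proportion exponents b_r.

    b_r is the OLS slope of log volume on log TIV, by default pooled over all
    subjects (the slope is invariant to the logarithm base). ``by_sex=True``
    fits a separate slope within each sex (non-default; the pooled fit is the
    conventional single TIV-VOI line per region).
    """
    _check_fit_sample(cohort)
    slopes = _ols_slopes(np.log(cohort.tiv), np.log(cohort.volumes))
    by = None
    if by_sex:
        by = {
            s: _ols_slopes(np.log(cohort.tiv[cohort.mask(s)]),
                           np.log(cohort.volumes[cohort.mask(s)]))
            for s in ("F", "M")
        }
    return AdjustmentParams(
        method="pcp",
        slopes=slopes,
        fit_n=cohort.n_subjects,
        region_names=tuple(cohort.region_names),
        slopes_by_sex=by,
    )


def _per_subject_slopes(cohort: CohortTable, params: AdjustmentParams) -> np.ndarray:
    if params.slopes_by_sex is None:
        return np.broadcast_to(params.slopes, cohort.volumes.shape)
    out = np.empty_like(cohort.volumes)
    for s, b in params.slopes_by_sex.items():
        out[cohort.mask(s)] = b
    return out


def pcp_apply(cohort: CohortTable, params: AdjustmentParams) -> AdjustedTable:
    """VOI / TIV**b_r with previously fitted exponents."""
    if params.method != "pcp":
        raise AdjustmentError(f"expected pcp params, got {params.method!r}")
    b = _per_subject_slopes(cohort, params)
    values = cohort.volumes / np.power(cohort.tiv[:, None], b)
    return AdjustedTable(cohort, values, "pcp", params)


def residuals_fit(cohort: CohortTable, by_sex: bool = False) -> AdjustmentParams:
    """Fit per-region linear slopes of volume on TIV and record the fit-sample TIV mean."""
    _check_fit_sample(cohort)
    slopes = _ols_slopes(cohort.tiv, cohort.volumes)
    by = None
    if by_sex:
        by = {
            s: _ols_slopes(cohort.tiv[cohort.mask(s)], cohort.volumes[cohort.mask(s)])
            for s in ("F", "M")
        }
    return AdjustmentParams(
        method="residuals",
        slopes=slopes,
        tiv_mean=float(cohort.tiv.mean()),
        fit_n=cohort.n_subjects,
        region_names=tuple(cohort.region_names),
        slopes_by_sex=by,
    )


def residuals_apply(cohort: CohortTable, params: AdjustmentParams) -> AdjustedTable:
    """VOI - b_r (TIV - mean TIV of the fit sample); preserves fit-sample region means."""
    if params.method != "residuals":
        raise AdjustmentError(f"expected residuals params, got {params.method!r}")
    centred = (cohort.tiv - params.tiv_mean)[:, None]
    values = cohort.volumes - centred * _per_subject_slopes(cohort, params)
    return AdjustedTable(cohort, values, "residuals", params)


def adjust(
    cohort: CohortTable,
    method: str,
    fit_cohort: CohortTable | None = None,
    scaling_gamma: float = 0.8,
) -> AdjustedTable:
    """Dispatch: adjust a cohort with a named method.

    Parameters are fitted on ``fit_cohort`` when given (leakage-aware mode for
    train/test workflows), otherwise on ``cohort`` itself — each sample
    adjusted within itself, the default analysis behaviour.
    """
    fit_on = fit_cohort if fit_cohort is not None else cohort
    if method == "raw":
        return AdjustedTable(cohort, cohort.volumes.copy(), "raw")
    if method == "proportions":
        return proportions_adjust(cohort)
    if method == "pcp":
        return pcp_apply(cohort, pcp_fit(fit_on))
    if method == "residuals":
        return residuals_apply(cohort, residuals_fit(fit_on))
    if method == "scaling_surrogate":
        surrogate = make_scaling_surrogate(cohort, gamma=scaling_gamma)
        return AdjustedTable(
            surrogate, surrogate.volumes.copy(), "scaling_surrogate",
            meta={"gamma": scaling_gamma},
        )
    raise AdjustmentError(f"unknown adjustment method {method!r}; choose from {METHODS}")
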