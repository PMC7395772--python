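"""Synthetic cohorts with allometric TIV-volume coupling and small sex effects.

The generative model is multiplicative (log-normal):

    TIV_i   ~ Normal(mu_sex, sigma_TIV), redrawn if more than 3 sd below mean
    log V_ir = a_r + b_r * (log TIV_i - log TIV_ref) + beta_r * 1[male] + eps_ir
    eps_ir  ~ Normal(0, sigma_r)

so a power-law correction V / TIV^b_r is exactly correctly specified, while
dividing by TIV (the proportions method) over-corrects whenever b_r < 1.
TIV_ref is a fixed 1500 ml reference so that exp(a_r) is the typical volume of
region r at reference head size; this makes a uniform intercept range map onto
a realistic range of region sizes (about 1.5-80 ml by default) regardless of
the drawn exponent.

Defaults emulate a large neuroimaging cohort: 444 subjects per sex, 116
regions, a male-female TIV gap of 212.8 ml against a common 114.4 ml sd
(standardized gap d = 1.86), exponents b_r in (0.5, 1.1) and log-scale noise
sd in (0.07, 0.18) (so TIV explains from a few percent up to ~70% of volume
variance across regions and unadjusted sex differences are uniformly male >
female with d near 1), and sex-specific log-scale offsets
beta_r ~ Normal(0, 0.015), yielding small bidirectional sex differences
(|d| mostly < 0.35) once TIV is properly adjusted for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import CohortTable

TIV_REF_ML = 1500.0


class GeneratorConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-cohort generator (volumes and TIV in ml)."""

    n_female: int = 444
    n_male: int = 444
    n_regions: int = 116
    tiv_mean_female: float = 1339.9
    tiv_mean_male: float = 1552.7
    tiv_sd: float = 114.4
    allometric_exponent_range: tuple[float, float] = (0.5, 1.1)
    intercept_range: tuple[float, float] = (np.log(1.5), np.log(80.0))
    sex_effect_sd: float = 0.015
    noise_sd_range: tuple[float, float] = (0.07, 0.18)
    seed: int = 0

    def __post_init__(self):
        if self.n_female <= 0 or self.n_male <= 0 or self.n_regions <= 0:
            raise GeneratorConfigError("counts must be positive")
        if self.tiv_sd <= 0:
            raise GeneratorConfigError("tiv_sd must be positive")
        lo, hi = self.allometric_exponent_range
        if not (0 < lo <= hi <= 2):
            raise GeneratorConfigError("exponent range must lie within (0, 2]")
        nlo, nhi = self.noise_sd_range
        if nlo < 0 or nhi < nlo:
            raise GeneratorConfigError("noise sd range must be non-negative and ordered")
        if self.sex_effect_sd < 0:
            raise GeneratorConfigError("sex_effect_sd must be non-negative")
        if self.tiv_mean_female <= 0 or self.tiv_mean_male <= 0:
            raise GeneratorConfigError("TIV means must be positive")


@dataclass(frozen=True)
class RegionParams:
    """Per-region generative parameters, shared by cohorts from one population."""

    intercept: np.ndarray        # a_r, log-ml at the reference TIV
    exponent: np.ndarray         # b_r, allometric exponent
    sex_effect: np.ndarray       # beta_r, log-scale male offset
    noise_sd: np.ndarray         # sigma_r, log-scale residual sd
    region_names: tuple = field(default=())


def sample_region_params(config: GeneratorConfig, seed: int | None = None) -> RegionParams:
    """Draw one population of region parameters from the config's ranges."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    r = config.n_regions
    lo, hi = config.allometric_exponent_range
    ilo, ihi = config.intercept_range
    nlo, nhi = config.noise_sd_range
    return RegionParams(
        intercept=rng.uniform(ilo, ihi, size=r),
        exponent=rng.uniform(lo, hi, size=r),
        sex_effect=rng.normal(0.0, config.sex_effect_sd, size=r) if config.sex_effect_sd > 0
        else np.zeros(r),
        noise_sd=rng.uniform(nlo, nhi, size=r),
        region_names=tuple(f"region_{i + 1:03d}" for i in range(r)),
    )


def _truncated_normal(rng, mean, sd, size):
    """Normal draws redrawn while more than 3 sd below the mean (positivity guard)."""
    x = rng.normal(mean, sd, size=size)
    low = mean - 3.0 * sd
    while np.any(x < low):
        bad = x < low
        x[bad] = rng.normal(mean, sd, size=bad.sum())
    return x


def generate_cohort(
    config: GeneratorConfig,
    region_params: RegionParams | None = None,
    seed: int | None = None,
) -> CohortTable:
    """Generate a cohort under the log-normal allometric model.

    `region_params` fixes the population of regions (use it to draw several
    cohorts — e.g. an original and a replication study — from one population);
    when omitted, region parameters are drawn from the config seed itself.
    `seed` overrides the subject-level seed without touching region parameters.
    """
    subject_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(subject_seed)
    params = region_params if region_params is not None else sample_region_params(config)
    if len(params.exponent) != config.n_regions:
        raise GeneratorConfigError("region_params size does not match config.n_regions")

    n = config.n_female + config.n_male
    sex = np.array(["F"] * config.n_female + ["M"] * config.n_male, dtype=object)
    tiv = np.empty(n)
    tiv[: config.n_female] = _truncated_normal(
        rng, config.tiv_mean_female, config.tiv_sd, config.n_female
    )
    tiv[config.n_female:] = _truncated_normal(
        rng, config.tiv_mean_male, config.tiv_sd, config.n_male
    )

    male = (sex == "M").astype(float)[:, None]
    log_t = np.log(tiv / TIV_REF_ML)[:, None]
    eps = rng.normal(0.0, 1.0, size=(n, config.n_regions)) * params.noise_sd[None, :]
    log_v = (
        params.intercept[None, :]
        + params.exponent[None, :] * log_t
        + params.sex_effect[None, :] * male
        + eps
    )
    return CohortTable(
        subject_id=np.array([f"sub-{i + 1:05d}" for i in range(n)]),
        sex=sex,
        tiv=tiv,
        volumes=np.exp(log_v),
        region_names=list(params.region_names),
        meta={"seed": subject_seed, "generator": asdict(config)},
    )


def make_scaling_surrogate(cohort: CohortTable, gamma: float = 0.8) -> CohortTable:
    """Statistical surrogate for image-space 'scaling' normalization.

    Multiplies every volume by (TIV_ref / TIV_i)^gamma with TIV_ref the grand
    mean TIV. gamma = 1 is equivalent to the proportions method up to a
    constant; gamma < 1 is a deliberately partial correction, mimicking a
    normalization that removes only part of the head-size dependence. This is
    a synthetic stand-in: the operation it emulates is performed on images,
    not on volume tables, and no image processing happens here.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    ref = float(np.mean(cohort.tiv))
    factor = (ref / cohort.tiv) ** gamma
    meta = dict(cohort.meta)
    meta["scaling_surrogate_gamma"] = gamma
    return CohortTable(
        subject_id=cohort.subject_id.copy(),
        sex=cohort.sex.copy(),
        tiv=cohort.tiv.copy(),
        volumes=cohort.volumes * factor[:, None],
        region_names=list(cohort.region_names),
        meta=meta,
    )
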