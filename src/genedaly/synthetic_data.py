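"""Synthetic biobank-style cohorts with known ground truth.

Everything downstream of the generators (Cox fits, shrinkage, attribution,
uncertainty) is testable against the generative parameters produced here:
sparse true log-HR matrices drawn from the spike-and-slab prior,
Hardy-Weinberg genotype dosages, per-disease exponential hazards
log-linear in the exposures, administrative censoring plus an independent
exponential death process, and GBD-style DALY rate tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from genedaly.shrinkage import ShrinkagePrior


@dataclass
class EffectMatrix:
    """True log hazard ratios b_{e,d} with exact-zero nulls.

    ``inclusion_proportion`` holds each exposure's p_e, the proportion of
    diseases with a non-zero effect.
    """

    true_log_hr: np.ndarray  # (n_exposures, n_diseases)
    null_mask: np.ndarray  # True where b == 0
    inclusion_proportion: np.ndarray  # (n_exposures,)

    def __post_init__(self) -> None:
        self.true_log_hr = np.asarray(self.true_log_hr, dtype=float)
        self.null_mask = np.asarray(self.null_mask, dtype=bool)
        if self.true_log_hr.shape != self.null_mask.shape:
            raise ValueError("shape mismatch between effects and null mask")
        if not np.array_equal(self.null_mask, self.true_log_hr == 0.0):
            raise ValueError("null_mask must mark exactly the zero entries")
        p = np.asarray(self.inclusion_proportion, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("inclusion proportions must lie in [0, 1]")
        self.inclusion_proportion = p

    @property
    def n_exposures(self) -> int:
        return self.true_log_hr.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.true_log_hr.shape[1]


@dataclass(frozen=True)
class ExposureSpec:
    """One exposure column: an allele dosage, a continuous score, or a rare burden."""

    id: str
    kind: str = "allele_dosage"  # allele_dosage | score | burden
    maf: float = 0.2  # allele frequency (allele_dosage) or carrier frequency (burden)

    def __post_init__(self) -> None:
        if self.kind not in ("allele_dosage", "score", "burden"):
            raise ValueError(f"unknown exposure kind {self.kind!r}")
        if self.kind == "allele_dosage" and not 0 < self.maf <= 0.5:
            raise ValueError("allele frequencies must lie in (0, 0.5]")
        if self.kind == "burden" and not 0 < self.maf < 1:
            raise ValueError("carrier frequency must lie in (0, 1)")


@dataclass
class CohortConfig:
    """Generative settings for one synthetic cohort.

    ``baseline_hazard`` is the per-disease event rate per person-year; use
    :func:`hazard_for_incidence` to calibrate it to a target cumulative
    incidence by the administrative end of follow-up. Entry at birth
    (entry age 0) is the default; a delayed-entry range may be configured,
    in which case events before entry are treated as unobserved.
    """

    n_individuals: int
    exposures: Sequence[ExposureSpec]
    n_diseases: int
    baseline_hazard: np.ndarray  # (n_diseases,) events per person-year
    end_of_followup_age: float = 80.0
    entry_age_range: tuple = (0.0, 0.0)
    death_hazard: float = 0.005  # competing censoring-by-death rate
    covariate_dim: int = 0
    covariate_log_hr: float = 0.0  # gamma, shared across diseases/covariates
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_hazard = np.broadcast_to(
            np.asarray(self.baseline_hazard, dtype=float), (self.n_diseases,)
        ).copy()
        if self.n_diseases < 1:
            raise ValueError("need at least one disease")
        if np.any(self.baseline_hazard <= 0) or self.death_hazard <= 0:
            raise ValueError("all hazard rates must be positive")
        if self.entry_age_range[0] > self.entry_age_range[1] or self.entry_age_range[0] < 0:
            raise ValueError("invalid entry age range")
        if self.entry_age_range[1] >= self.end_of_followup_age:
            raise ValueError("entry must precede end of follow-up")


@dataclass
class Cohort:
    """Individual-level table plus the exposure/disease index order.

    ``data`` columns: id, sex, entry_age, exit_age, death_age (NaN if
    alive), covariate columns cov_*, one dosage column per exposure id,
    and one event-age column ``event_<disease>`` per disease (NaN when no
    event was observed in follow-up).
    """

    data: pd.DataFrame
    exposure_ids: list
    disease_ids: list

    def event_col(self, disease_id) -> str:
        return f"event_{disease_id}"


def hazard_for_incidence(target_incidence, horizon_years: float) -> np.ndarray:
    """Constant hazard giving a target cumulative incidence by a horizon.

    Inverts the exponential CDF: lambda = -log(1 - F) / t.
    """
    f = np.asarray(target_incidence, dtype=float)
    if np.any((f <= 0) | (f >= 1)) or horizon_years <= 0:
        raise ValueError("incidence must lie in (0,1) and horizon be positive")
    return -np.log1p(-f) / horizon_years


def draw_true_effects(
    n_exposures: int, n_diseases: int, prior: ShrinkagePrior, seed: int = 0
) -> EffectMatrix:
    """Sample a sparse true effect matrix from the spike-and-slab prior.

    Each exposure's inclusion proportion p_e ~ Beta(alpha, beta); each
    b_{e,d} is exactly 0 with probability 1 - p_e and otherwise drawn from
    the 50:50 mixture N(+-mu, sigma^2).
    """
    if n_exposures < 1 or n_diseases < 1:
        raise ValueError("counts must be at least 1")
    rng = np.random.default_rng(seed)
    p = rng.beta(prior.alpha, prior.beta, size=n_exposures)
    nonnull = rng.random((n_exposures, n_diseases)) < p[:, None]
    signs = np.where(rng.random((n_exposures, n_diseases)) < 0.5, 1.0, -1.0)
    slab = rng.normal(signs * prior.mu, prior.sigma)
    b = np.where(nonnull, slab, 0.0)
    # a slab draw landing exactly on 0 has probability 0 but would corrupt the mask
    b[nonnull & (b == 0.0)] = np.finfo(float).tiny
    return EffectMatrix(true_log_hr=b, null_mask=~nonnull, inclusion_proportion=p)


def null_effects(n_exposures: int, n_diseases: int) -> EffectMatrix:
    """All-null effect matrix (the spike-only limit p_e = 0)."""
    b = np.zeros((n_exposures, n_diseases))
    return EffectMatrix(b, np.ones_like(b, dtype=bool), np.zeros(n_exposures))


def _draw_dosages(spec: ExposureSpec, n: int, rng) -> np.ndarray:
    if spec.kind == "allele_dosage":
        return rng.binomial(2, spec.maf, size=n).astype(float)
    if spec.kind == "score":
        return rng.standard_normal(n)
    return (rng.random(n) < spec.maf).astype(float)  # burden carrier indicator


def generate_cohort(config: CohortConfig, effects: EffectMatrix, seed: int | None = None) -> Cohort:
    """Simulate a cohort under proportional hazards with exponential baselines.

    Disease d's hazard for individual i is
    lambda_d * exp(sum_e b_{e,d} x_{i,e} + gamma * sum covariates), constant
    in age, so event ages are exponential draws. Individuals are censored
    at the earliest of death and administrative end of follow-up; only the
    first event per disease is kept, and (with delayed entry) events before
    entry are unobserved.
    """
    if effects.n_diseases != config.n_diseases or effects.n_exposures != len(config.exposures):
        raise ValueError("effect matrix dimensions do not match the cohort config")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_individuals

    sex = rng.integers(0, 2, size=n)
    entry = rng.uniform(*config.entry_age_range, size=n) if config.entry_age_range[1] > 0 else np.zeros(n)
    death = rng.exponential(1.0 / config.death_hazard, size=n)
    exit_age = np.minimum(death, config.end_of_followup_age)
    died = death <= config.end_of_followup_age

    dosages = np.column_stack([_draw_dosages(s, n, rng) for s in config.exposures])
    covs = rng.standard_normal((n, config.covariate_dim)) if config.covariate_dim else np.zeros((n, 0))

    # linear predictor per (individual, disease)
    lp = dosages @ effects.true_log_hr
    if config.covariate_dim and config.covariate_log_hr:
        lp = lp + config.covariate_log_hr * covs.sum(axis=1, keepdims=True)
    rates = config.baseline_hazard[None, :] * np.exp(lp)
    event_ages = rng.exponential(1.0 / rates)

    observed = (event_ages <= exit_age[:, None]) & (event_ages > entry[:, None])
    event_ages = np.where(observed, event_ages, np.nan)

    data = pd.DataFrame({"id": np.arange(n), "sex": sex, "entry_age": entry, "exit_age": exit_age})
    data["death_age"] = np.where(died, death, np.nan)
    for j in range(config.covariate_dim):
        data[f"cov_{j}"] = covs[:, j]
    exposure_ids = [s.id for s in config.exposures]
    for k, eid in enumerate(exposure_ids):
        data[eid] = dosages[:, k]
    disease_ids = [f"d{j}" for j in range(config.n_diseases)]
    for j, did in enumerate(disease_ids):
        data[f"event_{did}"] = event_ages[:, j]
    return Cohort(data=data, exposure_ids=exposure_ids, disease_ids=disease_ids)


def generate_summary_stats(
    effects: EffectMatrix,
    se: float | np.ndarray,
    seed: int = 0,
    exposure_ids: Sequence | None = None,
    disease_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Fast path: draw observed log HRs directly as beta_hat ~ N(b, se^2).

    Emulates the sampling distribution of the Cox estimator without
    simulating a cohort; ``se`` is a scalar or per-pair matrix of standard
    errors. Returns the flat estimate table used by the shrinkage stage.
    """
    se_arr = np.broadcast_to(np.asarray(se, dtype=float), effects.true_log_hr.shape)
    if np.any(se_arr <= 0):
        raise ValueError("standard errors must be strictly positive")
    rng = np.random.default_rng(seed)
    obs = rng.normal(effects.true_log_hr, se_arr)
    e_ids = list(exposure_ids) if exposure_ids is not None else [f"e{i}" for i in range(effects.n_exposures)]
    d_ids = list(disease_ids) if disease_ids is not None else [f"d{j}" for j in range(effects.n_diseases)]
    ei, di = np.meshgrid(np.arange(len(e_ids)), np.arange(len(d_ids)), indexing="ij")
    return pd.DataFrame(
        {
            "exposure_id": np.asarray(e_ids, dtype=object)[ei.ravel()],
            "disease_id": np.asarray(d_ids, dtype=object)[di.ravel()],
            "log_hr": obs.ravel(),
            "se": se_arr.ravel(),
        }
    )


def generate_daly_table(
    disease_ids: Sequence,
    magnitude_range: tuple = (50.0, 4000.0),
    sex_ratio_range: tuple = (0.5, 2.0),
    seed: int = 0,
    male_fraction: float = 0.49,
):
    """GBD-style yearly DALY rates per 100,000 by disease and sex.

    Disease magnitudes are drawn log-uniform over ``magnitude_range``
    (population DALY rates span orders of magnitude in GBD exports), the
    male:female ratio uniform over ``sex_ratio_range``, and the "both" row
    is the population-weighted mean of the sex rows.
    """
    from genedaly.io import DalyTable

    disease_ids = list(disease_ids)
    if not disease_ids:
        raise ValueError("disease list must not be empty")
    lo, hi = magnitude_range
    if not 0 < lo <= hi:
        raise ValueError("invalid magnitude range")
    rng = np.random.default_rng(seed)
    rows = []
    for did in disease_ids:
        both = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        ratio = rng.uniform(*sex_ratio_range)  # male / female rate
        female = both / (male_fraction * ratio + (1 - male_fraction))
        male = ratio * female
        rows += [
            {"disease_id": did, "sex": "male", "dalys_per_100k_year": male},
            {"disease_id": did, "sex": "female", "dalys_per_100k_year": female},
            {"disease_id": did, "sex": "both", "dalys_per_100k_year": both},
        ]
    return DalyTable(pd.DataFrame(rows), male_fraction=male_fraction)
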