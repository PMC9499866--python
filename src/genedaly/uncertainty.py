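"""Uncertainty for attributable DALYs.

Single-disease confidence intervals come from the delta method applied to
the map log HR -> attributable fraction -> DALYs. Totals across diseases
need the dependence between log HRs of comorbid diseases: a correlation
matrix C is estimated from the log HRs of exposure-disease pairs the
shrinkage step classified as null for both diseases (so the coefficients
reflect sampling variability rather than true effects), the covariance is
assembled as D C D with D the diagonal of standard errors, and the vector
of retained log HRs is resampled from the corresponding multivariate
normal; percentile bounds of the recomputed totals give the CI. Exposure
frequencies and GBD DALY rates are treated as fixed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from genedaly.attribution import AttributionConfig, ExposureLevelSet


@dataclass
class CorrelationMatrix:
    """Estimated log-HR correlation between diseases, with support counts."""

    C: np.ndarray
    disease_ids: list
    n_pairs: np.ndarray  # contributing exposures per entry

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("C must be symmetric")
        self.C = C


@dataclass(frozen=True)
class ResampleConfig:
    n_draws: int = 10_000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_draws < 100:
            raise ValueError("need at least 100 resampling draws")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


def estimate_logHR_correlation(
    all_estimates: pd.DataFrame,
    shrinkage_table: pd.DataFrame,
    disease_ids=None,
    min_pairs: int = 10,
) -> CorrelationMatrix:
    """Pearson correlation of log HRs across exposures null for both diseases.

    For each disease pair (i, j), take the exposures whose estimates for
    both i and j were shrunk to the null, and correlate their raw log HRs.
    Entries supported by fewer than ``min_pairs`` exposures are set to 0;
    the diagonal is 1.
    """
    merged = all_estimates.merge(
        shrinkage_table[["exposure_id", "disease_id", "retained"]],
        on=["exposure_id", "disease_id"],
        how="inner",
    )
    nulls = merged[~merged["retained"]]
    mat = nulls.pivot_table(index="exposure_id", columns="disease_id", values="log_hr")
    if disease_ids is None:
        disease_ids = sorted(all_estimates["disease_id"].unique())
    d = len(disease_ids)
    if d < 2:
        raise ValueError("need at least two diseases for a correlation matrix")
    C = np.eye(d)
    n_pairs = np.zeros((d, d), dtype=int)
    cols = {did: mat[did] if did in mat.columns else None for did in disease_ids}
    for a in range(d):
        sa = cols[disease_ids[a]]
        n_pairs[a, a] = 0 if sa is None else sa.notna().sum()
        for b in range(a + 1, d):
            sb = cols[disease_ids[b]]
            if sa is None or sb is None:
                continue
            both = sa.notna() & sb.notna()
            n = int(both.sum())
            n_pairs[a, b] = n_pairs[b, a] = n
            if n >= min_pairs:
                r = np.corrcoef(sa[both], sb[both])[0, 1]
                if np.isfinite(r):
                    C[a, b] = C[b, a] = r
    return CorrelationMatrix(C=C, disease_ids=list(disease_ids), n_pairs=n_pairs)


def nearest_psd_repair(C: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Clip negative eigenvalues to zero and rescale to unit diagonal.

    A no-op (up to numerical tolerance) for matrices that are already
    positive semi-definite.
    """
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("input must be symmetric")
    w, V = np.linalg.eigh(C)
    if w.min() >= -tol:
        return C.copy()
    w = np.clip(w, 0.0, None)
    fixed = (V * w) @ V.T
    d = np.sqrt(np.diag(fixed))
    d[d == 0] = 1.0
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2


def _total_dalys_for_draws(
    b_draws: np.ndarray,
    levels: ExposureLevelSet,
    daly_rates: np.ndarray,
    config: AttributionConfig,
    level_index: np.ndarray,
):
    """Vectorized totals over resampled log-HR vectors.

    ``b_draws`` has shape (B, d). Per-level HRs are exp(level * b) with the
    level multipliers taken from ``level_index`` (e.g. 0/1/2 allele copies,
    0/1 binary). Returns (pop_totals, ind_totals) of shape (B,).
    """
    hr = np.exp(level_index[None, None, :] * b_draws[:, :, None])  # (B, d, L)
    S = hr @ levels.P
    Sp = hr @ levels.P_prime
    afp = (S - Sp) / S
    pop = afp * daly_rates[None, :]
    pop_tot = pop.sum(axis=1)
    ind_tot = pop.sum(axis=1) / (100_000.0 * levels.exposed_fraction) * config.life_expectancy
    return pop_tot, ind_tot


def resample_total_dalys(
    log_hr: np.ndarray,
    se: np.ndarray,
    C: np.ndarray,
    levels: ExposureLevelSet,
    daly_rates: np.ndarray,
    config: ResampleConfig,
    attribution_config: AttributionConfig,
    level_index: np.ndarray | None = None,
):
    """Percentile CI for total attributable DALYs by correlated resampling.

    Draws B log-HR vectors from N(beta_hat, D C D), recomputes the total
    individual-attributable DALYs for each draw with frequencies and DALY
    rates held fixed, and returns a dict with the point estimate,
    percentile CI bounds, a normal-approximation two-sided p-value
    (z = point / SD of draws), and the draws themselves.
    """
    log_hr = np.asarray(log_hr, dtype=float)
    se = np.asarray(se, dtype=float)
    C = np.asarray(C, dtype=float)
    d = log_hr.size
    if C.shape != (d, d):
        raise ValueError("correlation matrix dimension must match the disease count")
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-8:
        raise ValueError("correlation matrix is not PSD; apply nearest_psd_repair first")
    if level_index is None:
        level_index = np.arange(len(levels.P), dtype=float)
    daly_rates = np.asarray(daly_rates, dtype=float)

    rng = np.random.default_rng(config.seed)
    cov = np.outer(se, se) * C
    draws_b = rng.multivariate_normal(log_hr, cov, size=config.n_draws, method="eigh")
    pop_draws, ind_draws = _total_dalys_for_draws(
        draws_b, levels, daly_rates, attribution_config, level_index
    )
    point_pop, point_ind = _total_dalys_for_draws(
        log_hr[None, :], levels, daly_rates, attribution_config, level_index
    )
    lo_q = (1 - config.ci_level) / 2
    out = {}
    for name, point, draws in (("pop", point_pop[0], pop_draws), ("ind", point_ind[0], ind_draws)):
        sd = float(draws.std(ddof=1))
        z = point / sd if sd > 0 else np.inf * np.sign(point) if point else 0.0
        out[name] = {
            "total": float(point),
            "ci_low": float(np.quantile(draws, lo_q)),
            "ci_high": float(np.quantile(draws, 1 - lo_q)),
            "sd": sd,
            "p_value": float(2 * norm.sf(abs(z))) if np.isfinite(z) else 0.0,
            "draws": draws,
        }
    return out


def _single_disease_dalys(b: float, levels: ExposureLevelSet, daly_rate: float, config: AttributionConfig, level_index: np.ndarray):
    hr = np.exp(level_index * b)
    S = float(levels.P @ hr)
    Sp = float(levels.P_prime @ hr)
    afp = (S - Sp) / S
    pop = afp * daly_rate
    ind = pop / (100_000.0 * levels.exposed_fraction) * config.life_expectancy
    return pop, ind


def daly_gradient(
    b: float,
    levels: ExposureLevelSet,
    daly_rate: float,
    config: AttributionConfig,
    level_index: np.ndarray | None = None,
):
    """Analytic d(individual DALYs)/d(log HR) for a single disease.

    With S(b) = sum_i P_i e^{i b} and S'(b) the counterfactual sum,
    AFp = 1 - S'/S, so dAFp/db = (S' dS - S dS') / S^2 with
    dS = sum_i i P_i e^{i b}; the DALY maps are linear in AFp.
    """
    if level_index is None:
        level_index = np.arange(len(levels.P), dtype=float)
    e = np.exp(level_index * b)
    S = float(levels.P @ e)
    Sp = float(levels.P_prime @ e)
    dS = float(levels.P @ (level_index * e))
    dSp = float(levels.P_prime @ (level_index * e))
    dafp = (Sp * dS - S * dSp) / S**2
    dpop = dafp * daly_rate
    dind = dpop / (100_000.0 * levels.exposed_fraction) * config.life_expectancy
    return dpop, dind


def delta_method_disease_ci(
    levels: ExposureLevelSet,
    log_hr: float,
    se: float,
    daly_rate: float,
    attribution_config: AttributionConfig,
    ci_level: float = 0.95,
    level_index: np.ndarray | None = None,
):
    """Symmetric normal CI for one disease's attributable DALYs.

    Propagates var(beta_hat) through the AFp -> DALY map using the analytic
    derivative. Returns dicts for the population and individual scales.
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    if level_index is None:
        level_index = np.arange(len(levels.P), dtype=float)
    pop, ind = _single_disease_dalys(log_hr, levels, daly_rate, attribution_config, level_index)
    dpop, dind = daly_gradient(log_hr, levels, daly_rate, attribution_config, level_index)
    zcrit = norm.ppf(0.5 + ci_level / 2)
    return {
        "pop": {"estimate": pop, "ci_low": pop - zcrit * abs(dpop) * se, "ci_high": pop + zcrit * abs(dpop) * se},
        "ind": {"estimate": ind, "ci_low": ind - zcrit * abs(dind) * se, "ci_high": ind + zcrit * abs(dind) * se},
    }


def sex_difference_test(total_m: float, sd_m: float, total_f: float, sd_f: float):
    """Two-sided z-test for a male-female difference in total DALYs.

    Treats the sex strata as independent: z = (m - f) / sqrt(sd_m^2 + sd_f^2).
    """
    for sd in (sd_m, sd_f):
        if sd is None or not np.isfinite(sd) or sd < 0:
            raise ValueError("both totals must carry finite resampling SDs")
    denom = np.sqrt(sd_m**2 + sd_f**2)
    if denom == 0:
        z = 0.0 if total_m == total_f else np.inf * np.sign(total_m - total_f)
    else:
        z = (total_m - total_f) / denom
    p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return float(z), p
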