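"""Attributable-burden arithmetic: PAF, population and individual DALYs.

The population-attributable fraction for a multi-level exposure compares
the observed exposure distribution P with a counterfactual P':

    AFp_d = (sum_i P_i HR_{d,i} - sum_i P'_i HR_{d,i}) / sum_i P_i HR_{d,i}

Population-attributable DALYs are AFp_d times the GBD yearly DALYs per
100,000 for the disease; individual-attributable DALYs divide by the
number of exposed individuals per 100,000 and scale by life expectancy L
to convert a yearly rate into lifetime healthy life years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

_FREQ_TOL = 1e-10


@dataclass
class ExposureLevelSet:
    """Exposure levels with observed and counterfactual population frequencies.

    ``hr`` maps disease_id -> per-level hazard ratios (HR at level 0 is 1).
    ``exposed_fraction`` is the share of the population whose level changes
    between P and P' (the denominator of the individual-DALY conversion).
    """

    P: np.ndarray
    P_prime: np.ndarray
    hr: dict = field(default_factory=dict)
    exposed_fraction: float | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.P_prime = np.asarray(self.P_prime, dtype=float)
        if self.P.shape != self.P_prime.shape:
            raise ValueError("P and P' must have the same length")
        for name, v in (("P", self.P), ("P'", self.P_prime)):
            if np.any(v < -_FREQ_TOL):
                raise ValueError(f"{name} has negative frequencies")
            if abs(v.sum() - 1.0) > _FREQ_TOL:
                raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")
        if self.exposed_fraction is None:
            # default: total probability mass that moves between scenarios
            self.exposed_fraction = float(np.abs(self.P - self.P_prime).sum() / 2)

    def hr_for(self, disease_id) -> np.ndarray:
        try:
            hr = np.asarray(self.hr[disease_id], dtype=float)
        except KeyError:
            raise KeyError(f"no hazard ratios for disease {disease_id!r}") from None
        if hr.shape != self.P.shape:
            raise ValueError("HR vector length must match number of levels")
        if np.any(hr <= 0):
            raise ValueError("hazard ratios must be positive")
        return hr


def hw_genotype_frequencies(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies (0, 1, 2 copies) at a given MAF."""
    if not 0 <= maf <= 0.5:
        raise ValueError("minor allele frequency must lie in [0, 0.5]")
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def allele_level_set(
    maf: float,
    log_hr_per_copy,
    disease_ids: Sequence | None = None,
    counterfactual: str = "one_to_zero",
) -> ExposureLevelSet:
    """Level set for an allele-dosage exposure under additive log HRs.

    Per-level HRs are exp(i * b_d) for i = 0, 1, 2 copies. The default
    counterfactual moves all one-copy carriers to zero copies (the
    one-versus-zero-copies contrast); ``"remove"`` moves everyone to zero
    copies; ``"zero_to_one"`` is the sign-flipped contrast giving one copy
    to all non-carriers.
    """
    P = hw_genotype_frequencies(maf)
    if counterfactual == "one_to_zero":
        P_prime = np.array([P[0] + P[1], 0.0, P[2]])
        exposed = P[1]
    elif counterfactual == "zero_to_one":
        P_prime = np.array([0.0, P[0] + P[1], P[2]])
        exposed = P[0]
    elif counterfactual == "remove":
        P_prime = np.array([1.0, 0.0, 0.0])
        exposed = P[1] + P[2]
    else:
        raise ValueError(f"unknown counterfactual {counterfactual!r}")
    b = np.atleast_1d(np.asarray(log_hr_per_copy, dtype=float))
    if disease_ids is None:
        disease_ids = [f"d{i}" for i in range(b.size)]
    hr = {did: np.exp(np.arange(3) * bi) for did, bi in zip(disease_ids, b)}
    return ExposureLevelSet(P=P, P_prime=P_prime, hr=hr, exposed_fraction=float(exposed))


def binary_level_set(
    exposed_fraction: float, log_hr, disease_ids: Sequence | None = None
) -> ExposureLevelSet:
    """Level set for a binary exposure (e.g. top 10% of a polygenic score vs rest)."""
    if not 0 < exposed_fraction < 1:
        raise ValueError("exposed_fraction must lie in (0, 1)")
    P = np.array([1 - exposed_fraction, exposed_fraction])
    P_prime = np.array([1.0, 0.0])
    b = np.atleast_1d(np.asarray(log_hr, dtype=float))
    if disease_ids is None:
        disease_ids = [f"d{i}" for i in range(b.size)]
    hr = {did: np.array([1.0, np.exp(bi)]) for did, bi in zip(disease_ids, b)}
    return ExposureLevelSet(P=P, P_prime=P_prime, hr=hr, exposed_fraction=exposed_fraction)


def counterfactual_from_reference(levels: ExposureLevelSet, reference_allele_freq: float) -> ExposureLevelSet:
    """Counterfactual where the population had a reference population's MAF.

    Replaces P' with Hardy-Weinberg genotype frequencies at the reference
    allele frequency while keeping the study population's P, so the
    attributable fraction measures the burden due to frequency enrichment
    relative to the reference population. Reference frequency 0 recovers
    the full-removal counterfactual.
    """
    P_prime = hw_genotype_frequencies(reference_allele_freq)
    exposed = float(np.abs(levels.P - P_prime).sum() / 2)
    return ExposureLevelSet(
        P=levels.P.copy(), P_prime=P_prime, hr=dict(levels.hr), exposed_fraction=max(exposed, 1e-300)
    )


@dataclass(frozen=True)
class AttributionConfig:
    """Settings shared by the attribution stage.

    ``life_expectancy`` (L, years) converts yearly per-100,000 DALY rates
    into lifetime individual estimates; there is no universal default, so
    it must be supplied. ``population_scale`` is the GBD's fixed 100,000.
    """

    life_expectancy: float
    sex_stratum: str = "both"
    population_scale: float = 100_000.0

    def __post_init__(self) -> None:
        if self.life_expectancy <= 0:
            raise ValueError("life expectancy must be positive")


def attributable_fraction(levels: ExposureLevelSet, disease_id) -> float:
    """Multilevel-exposure population-attributable fraction AFp_d."""
    hr = levels.hr_for(disease_id)
    observed = float(levels.P @ hr)
    counterfactual = float(levels.P_prime @ hr)
    return (observed - counterfactual) / observed


def population_attributable_dalys(afp: float, disease_id, daly_table, sex: str = "both") -> float:
    """AFp_d x DALY_d: yearly attributable DALYs per 100,000 population.

    Negative AFp (protective exposure) yields negative attributable DALYs,
    i.e. prevented burden. ``daly_table`` is a DalyTable from the io module
    (or anything with a ``rate(disease_id, sex)`` method).
    """
    return afp * daly_table.rate(disease_id, sex)


def individual_attributable_dalys(pop_dalys: float, exposed_fraction: float, life_expectancy: float) -> float:
    """Lifetime attributable healthy life years for one exposed individual."""
    if not 0 < exposed_fraction <= 1:
        raise ValueError("exposed_fraction must lie in (0, 1]")
    if life_expectancy <= 0:
        raise ValueError("life expectancy must be positive")
    return pop_dalys / (100_000.0 * exposed_fraction) * life_expectancy


def total_attributable_dalys(per_disease) -> float:
    """Sum attributable DALYs across diseases for a single exposure.

    Totals are only meaningful within one exposure; attributable DALYs for
    different exposures must never be added, so this takes a plain vector
    of per-disease values rather than anything keyed by exposure.
    """
    return float(np.sum(np.asarray(list(per_disease), dtype=float)))


def attribute_exposure(
    levels: ExposureLevelSet,
    daly_table,
    config: AttributionConfig,
    disease_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Per-disease attribution table for one exposure.

    Returns a DataFrame with columns (disease_id, afp, pop_dalys,
    ind_dalys); confidence intervals are added by the uncertainty module.
    """
    if disease_ids is None:
        disease_ids = list(levels.hr)
    rows = []
    for did in disease_ids:
        afp = attributable_fraction(levels, did)
        pop = population_attributable_dalys(afp, did, daly_table, config.sex_stratum)
        ind = individual_attributable_dalys(pop, levels.exposed_fraction, config.life_expectancy)
        rows.append({"disease_id": did, "afp": afp, "pop_dalys": pop, "ind_dalys": ind})
    return pd.DataFrame(rows)
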