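"""Hazard-ratio estimation: Cox fits, meta-analysis, composite mortality score.

Every exposure-disease pair gets a Cox proportional-hazards fit with age as
the timescale (event age as time-to-event, censoring at death or end of
follow-up), additive in exposure level, with sex and any covariate columns
adjusted for. Per-cohort estimates are combined by fixed-effects
inverse-variance-weighted meta-analysis. Non-estimable pairs (no events,
constant exposure, failed convergence) are flagged, never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError


@dataclass(frozen=True)
class Estimate:
    """One observed exposure-disease association."""

    exposure_id: str
    disease_id: str
    log_hr: float
    se: float
    n_events: int = 0
    cohort_id: str = "cohort0"
    sex_stratum: str = "both"
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status == "ok":
            if not np.isfinite(self.log_hr):
                raise ValueError("log HR must be finite")
            if self.se <= 0:
                raise ValueError("standard error must be positive")


def estimates_to_frame(estimates) -> pd.DataFrame:
    rows = [
        {
            "exposure_id": e.exposure_id,
            "disease_id": e.disease_id,
            "cohort": e.cohort_id,
            "sex": e.sex_stratum,
            "log_hr": e.log_hr,
            "se": e.se,
            "n_events": e.n_events,
            "status": e.status,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)


def encode_exposure(values, scheme: str = "additive_dosage", q: float = 0.10) -> np.ndarray:
    """Map raw per-individual values to the exposure level entering the Cox model.

    additive_dosage passes values through; top_quantile flags the highest
    q-fraction (ties broken by stable rank, so exactly floor(q*n)
    individuals are flagged); carrier flags any positive value.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty exposure vector")
    if scheme == "additive_dosage":
        return values.copy()
    if scheme == "carrier":
        return (values > 0).astype(float)
    if scheme == "top_quantile":
        if not 0 < q < 1:
            raise ValueError("quantile must lie in (0, 1)")
        k = int(np.floor(q * values.size + 1e-12))
        out = np.zeros(values.size)
        order = np.argsort(-values, kind="stable")
        out[order[:k]] = 1.0
        return out
    raise ValueError(f"unknown encoding scheme {scheme!r}")


def fit_cox(
    cohort,
    exposure_id: str,
    disease_id: str,
    covariates: tuple = ("sex",),
    exposure_values: np.ndarray | None = None,
    cohort_id: str = "cohort0",
    sex_stratum: str = "both",
    min_events: int = 1,
) -> Estimate:
    """Cox fit of one disease on one exposure, age timescale, Efron ties.

    Time-to-event is the age at first record of the disease; individuals
    without an event are censored at exit (death or administrative end of
    follow-up). Delayed-entry cohorts contribute risk time only after
    entry. ``exposure_values`` overrides the cohort's dosage column (used
    for encoded exposures such as top-decile score indicators).
    ``min_events`` is the configurable case-count power filter. Pairs that
    cannot be estimated come back with status != "ok" and NaN estimates.
    """
    df = cohort.data
    x = df[exposure_id].to_numpy(dtype=float) if exposure_values is None else np.asarray(exposure_values, dtype=float)
    event_age = df[cohort.event_col(disease_id)].to_numpy(dtype=float)
    observed = ~np.isnan(event_age)
    time = np.where(observed, event_age, df["exit_age"].to_numpy(dtype=float))

    def flagged(status: str) -> Estimate:
        return Estimate(
            exposure_id, disease_id, np.nan, np.nan, int(observed.sum()),
            cohort_id, sex_stratum, status=status,
        )

    if observed.sum() < max(min_events, 1):
        return flagged("too_few_events")
    if np.nanstd(x) == 0:
        return flagged("constant_exposure")

    model = pd.DataFrame({"T": time, "E": observed.astype(int), "x": x})
    for c in covariates:
        if c in df.columns:
            model[c] = df[c].to_numpy(dtype=float)
    entry = df["entry_age"].to_numpy(dtype=float) if "entry_age" in df.columns else None
    kwargs = {}
    if entry is not None and np.any(entry > 0):
        model["entry"] = entry
        kwargs["entry_col"] = "entry"

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                model,
                duration_col="T",
                event_col="E",
                fit_options={"max_steps": 100, "precision": 1e-9},
                **kwargs,
            )
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return flagged("no_convergence")
    return Estimate(
        exposure_id,
        disease_id,
        float(cph.params_["x"]),
        float(cph.standard_errors_["x"]),
        int(observed.sum()),
        cohort_id,
        sex_stratum,
    )


def fit_all_pairs(cohort, covariates: tuple = ("sex",), min_events: int = 1, cohort_id: str = "cohort0") -> pd.DataFrame:
    """Cox fits for every exposure x disease pair in a cohort."""
    out = []
    for eid in cohort.exposure_ids:
        for did in cohort.disease_ids:
            out.append(
                fit_cox(cohort, eid, did, covariates=covariates, min_events=min_events, cohort_id=cohort_id)
            )
    return estimates_to_frame(out)


def meta_fixed_effects(estimates) -> Estimate:
    """Fixed-effects inverse-variance-weighted combination of one pair's estimates.

    Weights w_k = 1/se_k^2; combined log HR is the weighted mean and the
    combined SE is (sum w_k)^(-1/2), never larger than the smallest input SE.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("need at least one estimate")
    keys = {(e.exposure_id, e.disease_id, e.sex_stratum) for e in estimates}
    if len(keys) > 1:
        raise ValueError(f"mixed estimate keys in meta-analysis: {sorted(keys)}")
    if len(estimates) == 1:
        return estimates[0]
    w = np.array([1.0 / e.se**2 for e in estimates])
    b = np.array([e.log_hr for e in estimates])
    combined = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    return replace(
        estimates[0],
        log_hr=combined,
        se=se,
        n_events=int(sum(e.n_events for e in estimates)),
        cohort_id="meta",
    )


def meta_analyze_frame(estimates: pd.DataFrame) -> pd.DataFrame:
    """IVW meta-analysis across cohorts, one row per (exposure, disease, sex)."""
    ok = estimates[estimates["status"] == "ok"] if "status" in estimates.columns else estimates
    group_cols = [c for c in ("exposure_id", "disease_id", "sex") if c in ok.columns]

    def combine(sub: pd.DataFrame) -> pd.Series:
        w = 1.0 / sub["se"] ** 2
        return pd.Series(
            {
                "log_hr": float((w * sub["log_hr"]).sum() / w.sum()),
                "se": float(w.sum() ** -0.5),
                "n_events": int(sub["n_events"].sum()) if "n_events" in sub.columns else -1,
                "cohort": "meta",
                "status": "ok",
            }
        )

    return ok.groupby(group_cols, sort=True).apply(combine, include_groups=False).reset_index()


def composite_linear_predictor(cohort, score_ids, covariates: tuple = ("sex",)) -> np.ndarray:
    """Composite mortality score from a Cox fit of death on several scores.

    Fits one Cox model of all-cause death on the listed score exposures
    plus sex and covariates, then evaluates each individual's linear
    predictor with sex fixed at 0.5 and all other covariates at 0, so the
    result reflects the scores alone. The returned vector is itself usable
    as a score-type exposure via :func:`encode_exposure`.
    """
    df = cohort.data
    death_age = df["death_age"].to_numpy(dtype=float)
    died = ~np.isnan(death_age)
    if not died.any():
        raise ValueError("no deaths in cohort; cannot fit mortality model")
    time = np.where(died, death_age, df["exit_age"].to_numpy(dtype=float))
    model = pd.DataFrame({"T": time, "E": died.astype(int)})
    for s in score_ids:
        model[s] = df[s].to_numpy(dtype=float)
    for c in covariates:
        if c in df.columns:
            model[c] = df[c].to_numpy(dtype=float)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(model, duration_col="T", event_col="E", fit_options={"max_steps": 100, "precision": 1e-9})
    lp = np.zeros(len(df))
    for s in score_ids:
        lp += float(cph.params_[s]) * df[s].to_numpy(dtype=float)
    if "sex" in cph.params_.index:
        lp += float(cph.params_["sex"]) * 0.5
    return lp
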