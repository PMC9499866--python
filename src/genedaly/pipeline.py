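"""Top-level driver tying fit -> shrink -> attribute -> ci together.

Consumes a cohort TSV (or a precomputed estimate TSV), a DALY table and a
config, and writes per-exposure attribution CSVs, a ranked totals table, the
disease-disease log-HR correlation matrix and a run manifest. Every stage
logs its funnel counts (pairs fitted / retained / discarded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from genedaly import io as gio
from genedaly.attribution import (
    AttributionConfig,
    allele_level_set,
    binary_level_set,
)
from genedaly.shrinkage import ShrinkagePrior, filter_by_null_probability, shrink_estimate_set
from genedaly.survival import fit_all_pairs
from genedaly.uncertainty import (
    ResampleConfig,
    estimate_logHR_correlation,
    nearest_psd_repair,
    resample_total_dalys,
)

log = logging.getLogger("genedaly")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, resolvable from a YAML mapping."""

    seed: int
    life_expectancy: float = 80.0
    output_dir: str = "results/pipeline"
    cohort_path: str | None = None
    estimates_path: str | None = None
    daly_table_path: str | None = None
    sex_stratum: str = "both"
    prior: ShrinkagePrior = field(default_factory=ShrinkagePrior)
    gibbs_iters: int = 11_000
    gibbs_burn_in: int = 1_000
    n_draws: int = 10_000
    ci_level: float = 0.95
    min_events: int = 1
    min_corr_pairs: int = 10
    exposure_frequencies: dict = field(default_factory=dict)  # exposure_id -> MAF or exposed fraction
    exposure_kinds: dict = field(default_factory=dict)  # exposure_id -> allele_dosage | binary

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = gio.load_config(path)
        prior_kwargs = cfg.pop("prior", {})
        cfg["prior"] = ShrinkagePrior(**prior_kwargs)
        return cls(**cfg)


def _level_set_for(eid, log_hrs, disease_ids, config: PipelineConfig):
    kind = config.exposure_kinds.get(eid, "allele_dosage")
    freq = config.exposure_frequencies.get(eid)
    if freq is None:
        raise ValueError(f"no exposure frequency configured for {eid!r}")
    if kind == "allele_dosage":
        return allele_level_set(freq, log_hrs, disease_ids), np.arange(3.0)
    if kind == "binary":
        return binary_level_set(freq, log_hrs, disease_ids), np.arange(2.0)
    raise ValueError(f"unknown exposure kind {kind!r} for {eid!r}")


def run_pipeline(config: PipelineConfig, daly_table=None, cohort=None) -> Path:
    """Execute all stages in order; returns the output directory.

    Idempotent under a fixed seed: rerunning writes identical files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if daly_table is None:
        if config.daly_table_path is None:
            raise ValueError("stage attribute: no DALY table given")
        daly_table = gio.read_daly_table(config.daly_table_path)

    # stage: fit
    if config.estimates_path is not None:
        estimates = gio.read_estimates(config.estimates_path)
    else:
        if cohort is None:
            if config.cohort_path is None:
                raise ValueError("stage fit: need a cohort or an estimate table")
            cohort = gio.read_cohort(config.cohort_path)
        estimates = fit_all_pairs(cohort, min_events=config.min_events)
    ok = estimates[estimates["status"] == "ok"] if "status" in estimates.columns else estimates
    log.info("stage fit: %d pairs, %d estimable", len(estimates), len(ok))
    gio.write_estimates(estimates, out / "estimates.tsv")

    # stage: shrink
    shrinkage = shrink_estimate_set(
        ok, config.prior, n_iter=config.gibbs_iters, burn_in=config.gibbs_burn_in, seed=config.seed
    )
    retained, discarded = filter_by_null_probability(shrinkage, ok)
    log.info("stage shrink: %d retained, %d discarded", len(retained), len(discarded))
    gio.write_shrinkage(shrinkage, out / "shrinkage.tsv")

    disease_ids = sorted(ok["disease_id"].unique())
    corr = estimate_logHR_correlation(
        ok, shrinkage.table, disease_ids=disease_ids, min_pairs=config.min_corr_pairs
    )
    C = nearest_psd_repair(corr.C)
    gio.write_correlation(C, disease_ids, out / "correlation.csv")

    # stage: attribute + ci, per exposure
    attr_cfg = AttributionConfig(config.life_expectancy, sex_stratum=config.sex_stratum)
    totals_rows = []
    d_index = {d: i for i, d in enumerate(disease_ids)}
    for eid, sub in retained.groupby("exposure_id", sort=True):
        if sub.empty:
            continue
        dids = list(sub["disease_id"])
        levels, level_index = _level_set_for(eid, sub["log_hr"].to_numpy(), dids, config)
        rates = np.array([daly_table.rate(d, config.sex_stratum) for d in dids])
        idx = [d_index[d] for d in dids]
        res = resample_total_dalys(
            sub["log_hr"].to_numpy(),
            sub["se"].to_numpy(),
            C[np.ix_(idx, idx)],
            levels,
            rates,
            ResampleConfig(n_draws=config.n_draws, seed=config.seed, ci_level=config.ci_level),
            attr_cfg,
            level_index=level_index,
        )
        per_dis = []
        from genedaly.attribution import attributable_fraction
        from genedaly.uncertainty import delta_method_disease_ci

        for d, b, se_b, rate in zip(dids, sub["log_hr"], sub["se"], rates):
            afp = attributable_fraction(levels, d)
            ci = delta_method_disease_ci(levels, b, se_b, rate, attr_cfg, config.ci_level, level_index)
            per_dis.append(
                {
                    "disease_id": d,
                    "afp": afp,
                    "pop_dalys": ci["pop"]["estimate"],
                    "pop_ci_low": ci["pop"]["ci_low"],
                    "pop_ci_high": ci["pop"]["ci_high"],
                    "ind_dalys": ci["ind"]["estimate"],
                    "ind_ci_low": ci["ind"]["ci_low"],
                    "ind_ci_high": ci["ind"]["ci_high"],
                }
            )
        pd.DataFrame(per_dis).to_csv(out / f"attribution_{eid}.csv", index=False)
        totals_rows.append(
            {
                "exposure_id": eid,
                "n_diseases_retained": len(dids),
                "total_pop_dalys": res["pop"]["total"],
                "pop_ci_low": res["pop"]["ci_low"],
                "pop_ci_high": res["pop"]["ci_high"],
                "total_ind_dalys": res["ind"]["total"],
                "ind_ci_low": res["ind"]["ci_low"],
                "ind_ci_high": res["ind"]["ci_high"],
                "p_value": res["ind"]["p_value"],
            }
        )
    totals = pd.DataFrame(totals_rows)
    if not totals.empty:
        totals = totals.sort_values("total_ind_dalys", ascending=False, key=np.abs).reset_index(drop=True)
    totals.to_csv(out / "totals.csv", index=False)
    log.info("stage attribute: %d exposures with retained effects", len(totals))

    import genedaly

    manifest = {
        "seed": config.seed,
        "version": genedaly.__version__,
        "prior": {
            "alpha": config.prior.alpha,
            "beta": config.prior.beta,
            "mu": config.prior.mu,
            "sigma": config.prior.sigma,
            "null_threshold": config.prior.null_threshold,
        },
        "life_expectancy": config.life_expectancy,
        "n_draws": config.n_draws,
        "pairs_fitted": int(len(estimates)),
        "pairs_estimable": int(len(ok)),
        "pairs_retained": int(len(retained)),
        "pairs_discarded": int(len(discarded)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
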