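"""Readers and writers for the pipeline's flat-file formats.

DALY tables follow the GBD GHDx CSV export dialect (columns cause, sex,
measure, val; only measure == "DALYs" rows are consumed, with an explicit
cause -> disease-id mapping). Cohorts and estimate sets are plain TSVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

_SEXES = ("male", "female", "both")


@dataclass
class DalyTable:
    """Disease x sex yearly DALYs per 100,000 population.

    ``table`` columns: disease_id, sex in {male, female, both},
    dalys_per_100k_year (non-negative). At most one row per (disease, sex).
    """

    table: pd.DataFrame
    male_fraction: float = 0.49

    def __post_init__(self) -> None:
        t = self.table
        missing = {"disease_id", "sex", "dalys_per_100k_year"} - set(t.columns)
        if missing:
            raise ValueError(f"DALY table missing columns: {sorted(missing)}")
        if not set(t["sex"]).issubset(_SEXES):
            raise ValueError(f"sex must be one of {_SEXES}")
        if (t["dalys_per_100k_year"] < 0).any():
            raise ValueError("DALY rates must be non-negative")
        if t.duplicated(["disease_id", "sex"]).any():
            dups = t[t.duplicated(["disease_id", "sex"], keep=False)]
            raise ValueError(f"duplicate (disease, sex) rows:\n{dups}")
        self._rates = t.set_index(["disease_id", "sex"])["dalys_per_100k_year"]

    def rate(self, disease_id, sex: str = "both") -> float:
        try:
            return float(self._rates.loc[(disease_id, sex)])
        except KeyError:
            raise KeyError(f"no DALY rate for disease {disease_id!r}, sex {sex!r}") from None

    def disease_ids(self) -> list:
        return list(dict.fromkeys(self.table["disease_id"]))


def read_daly_table(path, cause_map: dict | None = None, male_fraction: float = 0.49) -> DalyTable:
    """Read a GBD GHDx-dialect CSV (cause, sex, measure, val).

    ``cause_map`` maps GBD cause names to internal disease ids, mirroring
    the manual GBD-to-endpoint mapping a real analysis needs; unmapped
    causes are an error listing the offenders. Sex labels are lowercased
    ("Male"/"Female"/"Both" accepted).
    """
    df = pd.read_csv(path)
    missing = {"cause", "sex", "measure", "val"} - set(df.columns)
    if missing:
        raise ValueError(f"GBD CSV missing columns: {sorted(missing)}")
    df = df[df["measure"].str.lower().isin(["dalys", "dalys (disability-adjusted life years)"])]
    df = df.assign(sex=df["sex"].str.lower())
    if cause_map is not None:
        unmapped = sorted(set(df["cause"]) - set(cause_map))
        if unmapped:
            raise ValueError(f"unmapped GBD causes: {unmapped}")
        df = df.assign(disease_id=df["cause"].map(cause_map))
    else:
        df = df.assign(disease_id=df["cause"])
    out = df[["disease_id", "sex", "val"]].rename(columns={"val": "dalys_per_100k_year"})
    return DalyTable(out.reset_index(drop=True), male_fraction=male_fraction)


def write_daly_table(daly: DalyTable, path) -> None:
    """Write back in the GBD dialect so the file round-trips through read_daly_table."""
    out = daly.table.rename(columns={"disease_id": "cause", "dalys_per_100k_year": "val"})
    out = out.assign(measure="DALYs")[["cause", "sex", "measure", "val"]]
    out.to_csv(path, index=False)


def write_cohort(cohort, path) -> None:
    """Cohort as a flat TSV, one row per individual, empty field = no event."""
    cohort.data.to_csv(path, sep="\t", index=False)


def read_cohort(path):
    from genedaly.synthetic_data import Cohort

    data = pd.read_csv(path, sep="\t")
    disease_ids = [c[len("event_"):] for c in data.columns if c.startswith("event_")]
    reserved = {"id", "sex", "entry_age", "exit_age", "death_age"}
    exposure_ids = [
        c
        for c in data.columns
        if c not in reserved and not c.startswith("event_") and not c.startswith("cov_")
    ]
    return Cohort(data=data, exposure_ids=exposure_ids, disease_ids=disease_ids)


ESTIMATE_COLUMNS = ["exposure_id", "disease_id", "cohort", "sex", "log_hr", "se", "n_events", "status"]


def write_estimates(estimates: pd.DataFrame, path) -> None:
    df = estimates.copy()
    for col, default in (("cohort", "cohort0"), ("sex", "both"), ("n_events", -1), ("status", "ok")):
        if col not in df.columns:
            df[col] = default
    df[ESTIMATE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"exposure_id", "disease_id", "log_hr", "se"} - set(df.columns)
    if missing:
        raise ValueError(f"estimate TSV missing columns: {sorted(missing)}")
    return df


def write_shrinkage(result, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def read_shrinkage(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_correlation(C: np.ndarray, disease_ids, path) -> None:
    pd.DataFrame(C, index=list(disease_ids), columns=list(disease_ids)).to_csv(path)


def read_correlation(path):
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), list(df.columns)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    if "seed" not in cfg:
        raise ValueError("config must specify a seed")
    return cfg


def enumerate_analysis_pairs(exposure_manifest: pd.DataFrame, disease_ids) -> pd.DataFrame:
    """Cross every exposure in a manifest with every disease in the panel.

    This is the pipeline's bookkeeping of survival analyses to run: e.g. a
    manifest of 1,044 common variants, 9 rare-variant burdens, 74 HLA
    alleles and 30 polygenic scores against 80 diseases enumerates
    1,157 x 80 = 92,560 pairs.
    """
    if "exposure_id" not in exposure_manifest.columns:
        raise ValueError("manifest needs an exposure_id column")
    if exposure_manifest["exposure_id"].duplicated().any():
        raise ValueError("duplicate exposure ids in manifest")
    disease_ids = list(disease_ids)
    eid = exposure_manifest["exposure_id"].to_numpy()
    ei = np.repeat(np.arange(len(eid)), len(disease_ids))
    di = np.tile(np.arange(len(disease_ids)), len(eid))
    return pd.DataFrame(
        {"exposure_id": eid[ei], "disease_id": np.asarray(disease_ids, dtype=object)[di]}
    )
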