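"""Tiered quality control for dairy test-day records.

The cleaning pipeline applies seven stages in a fixed order:

1. drop records with a missing ear tag or an undecipherable test date;
2. drop records whose parity/season is missing and cannot be inferred
   (season from the test-date month, parity from a calving-sequence table);
3. drop records with more than 30 % of the core traits missing;
4. deduplicate per ear tag + test date, keeping the most complete record
   (fewest missing core fields, then the latest, then stable input order);
5. mean-impute continuous traits with under 5 % column missingness using
   parity-by-season cell means (single-breed data, so the breed stratum of
   a breed-parity-season imputation collapses);
6. flag statistical outliers (|Z| > 3 within parity-by-season cells, or
   outside 1.5 IQR) and delete physiologically impossible values
   (daily milk yield below 2 kg or above 60 kg); possible-but-extreme
   records are kept, carrying an audit flag;
7. restrict days in milk to lactation weeks 3-44 (15-308 days).

Each stage's in/removed/out counts are recorded in a :class:`CleaningReport`
whose arithmetic is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

#: the core traits counted by the 30 %-missing rule
CORE_TRAITS = (
    "dmy_kg",
    "my_morn_kg",
    "my_noon_kg",
    "my_night_kg",
    "fat_pct",
    "protein_pct",
    "bw_kg",
)

SEASONS = ("spring", "summer", "fall", "winter")

_SEASON_OF_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
    12: "winter", 1: "winter", 2: "winter",
}

#: canonical column order of a standardized test-day table
STANDARD_COLUMNS = [
    "ear_tag", "test_date", "parity", "season", "dim",
    "dmy_kg", "my_morn_kg", "my_noon_kg", "my_night_kg",
    "fat_pct", "protein_pct", "bw_kg", "flags",
]


@dataclass
class QCConfig:
    """Thresholds of the cleaning protocol (defaults as described above)."""

    max_core_missing_frac: float = 0.30
    max_impute_missing_frac: float = 0.05
    z_threshold: float = 3.0
    iqr_multiplier: float = 1.5
    dmy_range_kg: tuple[float, float] = (2.0, 60.0)
    dim_range_days: tuple[int, int] = (15, 308)  # lactation weeks 3-44

    def __post_init__(self) -> None:
        if not 0 < self.max_core_missing_frac < 1:
            raise ValueError("max_core_missing_frac must be in (0, 1)")
        if self.z_threshold <= 0 or self.iqr_multiplier <= 0:
            raise ValueError("outlier thresholds must be positive")


@dataclass
class CleaningStage:
    name: str
    records_in: int
    records_removed: int
    reason: str
    records_out: int
    cumulative_removal_pct: float


@dataclass
class CleaningReport:
    """Per-stage audit of the cleaning pipeline."""

    initial_records: int = 0
    initial_cows: int = 0
    final_cows: int = 0
    stages: list[CleaningStage] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def add(self, name: str, n_in: int, removed: int, reason: str) -> None:
        n_out = n_in - removed
        cum = 0.0 if self.initial_records == 0 else (
            (self.initial_records - n_out) / self.initial_records * 100.0
        )
        self.stages.append(CleaningStage(name, n_in, removed, reason, n_out, round(cum, 2)))

    @property
    def final_records(self) -> int:
        return self.stages[-1].records_out if self.stages else self.initial_records

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.stages])

    def to_dict(self) -> dict:
        return {
            "initial_records": self.initial_records,
            "final_records": self.final_records,
            "initial_cows": self.initial_cows,
            "final_cows": self.final_cows,
            "stages": [vars(s) for s in self.stages],
            "notes": list(self.notes),
        }


def season_from_month(month: int) -> str:
    return _SEASON_OF_MONTH[int(month)]


def standardize(rows: pd.DataFrame, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Map raw columns to the standard schema and normalise types.

    Dates are parsed (undecipherable ones flagged ``bad_date`` for stage-1
    removal), seasons are derived from the test-date month when absent, and
    numeric traits are coerced with invalid entries becoming missing.
    """
    df = rows.copy()
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    if "ear_tag" not in df.columns:
        raise ValueError("mandatory column 'ear_tag' not mappable")
    for col in STANDARD_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["flags"] = df["flags"].fillna("").astype(str)

    parsed = pd.to_datetime(df["test_date"], errors="coerce", format="mixed")
    bad = parsed.isna() & df["test_date"].notna()
    df["test_date"] = parsed
    df.loc[bad, "flags"] = _append_flag(df.loc[bad, "flags"], "bad_date")

    df["ear_tag"] = df["ear_tag"].astype("string").str.strip()
    df.loc[df["ear_tag"].isin(["", "nan", "None"]), "ear_tag"] = pd.NA

    for col in ("dmy_kg", "my_morn_kg", "my_noon_kg", "my_night_kg",
                "fat_pct", "protein_pct", "bw_kg"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["parity"] = pd.to_numeric(df["parity"], errors="coerce").astype("Int64")
    df["dim"] = pd.to_numeric(df["dim"], errors="coerce").astype("Int64")

    season = df["season"].astype("string").str.strip().str.lower()
    season = season.where(season.isin(SEASONS))
    month_season = df["test_date"].dt.month.map(_SEASON_OF_MONTH)
    df["season"] = season.fillna(month_season.astype("string"))
    return df[STANDARD_COLUMNS]


def _append_flag(flags: pd.Series, tag: str) -> pd.Series:
    has = flags.str.split(";").apply(lambda parts: tag in parts)
    appended = flags.where(flags == "", flags + ";") + tag
    return flags.where(has, appended)


def infer_from_pedigree(
    record: pd.Series,
    ped: Pedigree | None = None,
    calving_table: Mapping[str, Sequence] | None = None,
) -> pd.Series:
    """Backfill season (from the test-date month) and parity (from a
    calving-sequence table: number of calvings on or before the test date,
    i.e. prior calvings + 1) on a single record; unknown stays unchanged."""
    rec = record.copy()
    if pd.isna(rec.get("season")) and pd.notna(rec.get("test_date")):
        rec["season"] = season_from_month(pd.Timestamp(rec["test_date"]).month)
    if pd.isna(rec.get("parity")) and calving_table is not None:
        calvings = calving_table.get(rec.get("ear_tag"), None)
        if calvings is not None and pd.notna(rec.get("test_date")):
            test = pd.Timestamp(rec["test_date"])
            prior = sum(pd.Timestamp(c) <= test for c in calvings)
            if prior > 0:
                rec["parity"] = prior
    return rec


def clean(
    records: pd.DataFrame,
    config: QCConfig | None = None,
    ped: Pedigree | None = None,
    calving_table: Mapping[str, Sequence] | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the tiered cleaning protocol; returns survivors and the audit."""
    config = config or QCConfig()
    df = records.copy().reset_index(drop=True)
    report = CleaningReport(
        initial_records=len(df),
        initial_cows=int(df["ear_tag"].nunique()) if len(df) else 0,
    )
    if df.empty:
        report.notes.append("empty input")
        return df, report

    df["_order"] = np.arange(len(df))

    # 1. critical identifiers
    n_in = len(df)
    bad_date = df["flags"].str.contains("bad_date") | df["test_date"].isna()
    drop = df["ear_tag"].isna() | bad_date
    df = df[~drop]
    report.add("Remove Missing Records: Key IDs", n_in, int(drop.sum()),
               "Missing ear tag or undecipherable test date")

    # 2. parity / season not inferable
    n_in = len(df)
    missing_season = df["season"].isna()
    if missing_season.any():
        inferred = df.loc[missing_season].apply(
            lambda r: infer_from_pedigree(r, ped, calving_table), axis=1)
        df.loc[missing_season, ["season", "parity"]] = inferred[["season", "parity"]]
    missing_parity = df["parity"].isna()
    if missing_parity.any() and calving_table is not None:
        inferred = df.loc[missing_parity].apply(
            lambda r: infer_from_pedigree(r, ped, calving_table), axis=1)
        df.loc[missing_parity, "parity"] = inferred["parity"]
    drop = df["parity"].isna() | df["season"].isna()
    df = df[~drop]
    report.add("Remove Missing Records: Core Vars", n_in, int(drop.sum()),
               "Missing parity/season not inferable")

    # 3. >30% of core traits missing
    n_in = len(df)
    core = df[list(CORE_TRAITS)]
    frac_missing = core.isna().mean(axis=1)
    drop = frac_missing > config.max_core_missing_frac
    df = df[~drop]
    report.add("Remove High-Missing Records (>30%)", n_in, int(drop.sum()),
               "Excessive missing core fields")

    # 4. duplicates per ear tag + date
    n_in = len(df)
    n_miss = df[list(CORE_TRAITS)].isna().sum(axis=1)
    ranked = df.assign(_miss=n_miss).sort_values(
        by=["_miss", "test_date", "_order"],
        ascending=[True, False, True],
        kind="stable",
    )
    keep_idx = ranked.drop_duplicates(subset=["ear_tag", "test_date"], keep="first").index
    removed = n_in - len(keep_idx)
    df = df.loc[df.index.isin(keep_idx)]
    report.add("Remove Duplicate Records", n_in, removed,
               "Duplicate ear tag + test date (most complete kept)")

    # 5. mean imputation within parity x season cells (<5% column missingness)
    n_in = len(df)
    imputed_cols = []
    for col in CORE_TRAITS:
        frac = df[col].isna().mean()
        if 0.0 < frac < config.max_impute_missing_frac:
            cell_mean = df.groupby(["parity", "season"], observed=True)[col].transform("mean")
            fill = cell_mean.fillna(df[col].mean())
            df.loc[df[col].isna(), col] = fill[df[col].isna()]
            imputed_cols.append(col)
    report.add("Mean Imputation (Numerical Vars)", n_in, 0,
               f"Imputed parity-season cell means: {', '.join(imputed_cols) or 'none'}")

    # 6. outliers: flag statistical, delete impossible
    n_in = len(df)
    for col in ("dmy_kg", "fat_pct", "protein_pct"):
        grp = df.groupby(["parity", "season"], observed=True)[col]
        mu, sd = grp.transform("mean"), grp.transform("std")
        z = (df[col] - mu) / sd.replace(0.0, np.nan)
        q1 = grp.transform(lambda s: s.quantile(0.25))
        q3 = grp.transform(lambda s: s.quantile(0.75))
        iqr = q3 - q1
        extreme = (z.abs() > config.z_threshold) | (
            (df[col] < q1 - config.iqr_multiplier * iqr)
            | (df[col] > q3 + config.iqr_multiplier * iqr)
        )
        extreme = extreme.fillna(False)
        df.loc[extreme, "flags"] = _append_flag(
            df.loc[extreme, "flags"], f"extreme_{col}")
    lo, hi = config.dmy_range_kg
    impossible = df["dmy_kg"].notna() & ((df["dmy_kg"] < lo) | (df["dmy_kg"] > hi))
    df = df[~impossible]
    report.add("Identify and Remove Invalid Outliers", n_in, int(impossible.sum()),
               f"Daily milk yield outside [{lo}, {hi}] kg (extreme values flagged, kept)")

    # 7. days in milk window (lactation weeks 3-44)
    n_in = len(df)
    dlo, dhi = config.dim_range_days
    out_of_window = df["dim"].notna() & ((df["dim"] < dlo) | (df["dim"] > dhi))
    df = df[~out_of_window]
    report.add("Restrict Days in Milk (weeks 3-44)", n_in, int(out_of_window.sum()),
               f"Days in milk outside [{dlo}, {dhi}]")

    df = df.drop(columns=["_order"]).reset_index(drop=True)
    report.final_cows = int(df["ear_tag"].nunique())
    report.notes.append(
        "Counts are record-level; cow-level initial/final counts are reported "
        "separately because recording-scheme audits are often tabulated per cow."
    )
    return df, report
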