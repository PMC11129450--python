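"""Readers for the five cohort CSV schemas with row-level diagnostics.

Schemas (all plain CSV, header row required):

* genotypes.csv      — patient_id, gene, allele1, allele2, quality_ok
* medications.csv    — patient_id, period (1–11), atc
* participation.csv  — patient_id, period, assessed
* asec.csv           — patient_id, period (3/5/7/9), atc, item_01..item_12
* reasons.csv        — patient_id, period, atc, reason
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .asec import ASEC_PERIODS, ITEM_COLUMNS
from .substrates import validate_atc
from .trajectory import N_PERIODS, REASONS

__all__ = [
    "SchemaError",
    "read_genotypes",
    "read_medications",
    "read_participation",
    "read_asec",
    "read_reasons",
]

_TRUTHY = {"true": True, "1": True, "yes": True,
           "false": False, "0": False, "no": False}


class SchemaError(ValueError):
    """An input CSV violates its schema; message carries row numbers."""


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _parse_bool(series: pd.Series, path, column: str) -> pd.Series:
    lowered = series.astype(str).str.strip().str.lower()
    bad = ~lowered.isin(_TRUTHY)
    if bad.any():
        rows = [i + 2 for i in series.index[bad][:5]]  # 1-based + header
        raise SchemaError(f"{path}: non-boolean {column} at rows {rows}")
    return lowered.map(_TRUTHY)


def _parse_period(series: pd.Series, path, valid=None) -> pd.Series:
    numeric = pd.to_numeric(series, errors="coerce")
    ok = numeric.notna() & (numeric == numeric.round())
    if valid is None:
        ok &= (numeric >= 1) & (numeric <= N_PERIODS)
    else:
        ok &= numeric.isin(list(valid))
    if (~ok).any():
        rows = [i + 2 for i in series.index[~ok][:5]]
        raise SchemaError(f"{path}: invalid period at rows {rows}")
    return numeric.astype(int)


def _parse_atc(series: pd.Series, path) -> pd.Series:
    def check(value):
        try:
            return validate_atc(value)
        except ValueError:
            return None

    parsed = series.map(check)
    bad = parsed.isna()
    if bad.any():
        rows = [i + 2 for i in series.index[bad][:5]]
        raise SchemaError(f"{path}: malformed ATC code at rows {rows}")
    return parsed


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require(df, ["patient_id", "gene", "allele1", "allele2", "quality_ok"], path)
    df["gene"] = df["gene"].str.upper()
    bad = ~df["gene"].isin(["CYP2D6", "CYP2C19"])
    if bad.any():
        rows = [i + 2 for i in df.index[bad][:5]]
        raise SchemaError(f"{path}: unsupported gene at rows {rows}")
    df["quality_ok"] = _parse_bool(df["quality_ok"], path, "quality_ok")
    return df


def read_medications(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require(df, ["patient_id", "period", "atc"], path)
    df["period"] = _parse_period(df["period"], path)
    df["atc"] = _parse_atc(df["atc"], path)
    return df


def read_participation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require(df, ["patient_id", "period", "assessed"], path)
    df["period"] = _parse_period(df["period"], path)
    df["assessed"] = _parse_bool(df["assessed"], path, "assessed")
    dup = df.duplicated(subset=["patient_id", "period"])
    if dup.any():
        rows = [i + 2 for i in df.index[dup][:5]]
        raise SchemaError(f"{path}: duplicate patient-period at rows {rows}")
    return df


def read_asec(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["patient_id", "period", "atc", *ITEM_COLUMNS], path)
    df["patient_id"] = df["patient_id"].astype(str)
    df["period"] = _parse_period(df["period"], path, valid=ASEC_PERIODS)
    df["atc"] = _parse_atc(df["atc"].astype(str), path)
    items = df[list(ITEM_COLUMNS)]
    bad = ~items.isin([0, 1]).all(axis=1)
    if bad.any():
        rows = [i + 2 for i in df.index[bad][:5]]
        raise SchemaError(f"{path}: non-binary ASEC items at rows {rows}")
    return df


def read_reasons(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _require(df, ["patient_id", "period", "atc", "reason"], path)
    df["period"] = _parse_period(df["period"], path)
    df["atc"] = _parse_atc(df["atc"], path)
    bad = ~df["reason"].isin(REASONS)
    if bad.any():
        rows = [i + 2 for i in df.index[bad][:5]]
        raise SchemaError(f"{path}: unknown reason code at rows {rows}")
    return df
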