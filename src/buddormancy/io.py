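"""CSV schemas, validated readers and deterministic writers.

All pipeline files are plain CSV with ISO-8601 dates. Writers prepend
``#``-prefixed header comments carrying a schema version and, when
available, the run's config hash; readers skip them. Validation errors
name the offending rows (1-based data rows, excluding header lines).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "write_csv",
    "read_csv",
    "read_temps",
    "read_phenology",
    "read_mass",
    "read_isotopes",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """An input file violates its schema."""


def write_csv(df: pd.DataFrame, path: "str | Path", meta: Optional[dict] = None) -> Path:
    """Write a frame with schema-version/config-hash header comments."""
    path = Path(path)
    lines = [f"# schema_version: {SCHEMA_VERSION}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    body = df.to_csv(index=False, float_format="%.10g", lineterminator="\n")
    path.write_text("\n".join(lines) + "\n" + body)
    return path


def read_csv(path: "str | Path") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, comment="#")


def _require_columns(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, name: str) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna() & df[col].notna()]
    if len(bad):
        rows = [int(i) + 1 for i in bad[:5]]
        raise SchemaError(
            f"{name}: column {col!r} has non-numeric value(s) at data row(s) {rows}"
        )
    return vals


def _dates(df: pd.DataFrame, col: str, name: str, allow_blank: bool = False) -> pd.Series:
    raw = df[col]
    if allow_blank:
        raw = raw.replace("", np.nan)
    vals = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = df.index[vals.isna() & raw.notna()]
    if len(bad):
        rows = [int(i) + 1 for i in bad[:5]]
        raise SchemaError(f"{name}: column {col!r} has unparseable date(s) at row(s) {rows}")
    return vals


def read_temps(path: "str | Path") -> pd.DataFrame:
    """Hourly logger file: site, datetime, temp_c."""
    df = read_csv(path)
    _require_columns(df, ["site", "datetime", "temp_c"], "temps")
    df["datetime"] = _dates(df, "datetime", "temps")
    df["temp_c"] = _numeric(df, "temp_c", "temps")
    out_of_band = df.index[(df["temp_c"] < -50) | (df["temp_c"] > 50)]
    if len(out_of_band):
        rows = [int(i) + 1 for i in out_of_band[:5]]
        raise SchemaError(f"temps: temp_c outside [-50, 50] °C at row(s) {rows}")
    return df


def read_phenology(path: "str | Path") -> pd.DataFrame:
    """Per-twig forcing assay file (wide dialect: one stage-date column per stage)."""
    df = read_csv(path)
    req = [
        "twig_id", "tree_id", "species", "site", "campaign_date",
        "forcing_start", "stage2_date", "n_buds_total", "n_buds_ge_stage2",
    ]
    _require_columns(df, req, "phenology")
    df["campaign_date"] = _dates(df, "campaign_date", "phenology")
    df["forcing_start"] = _dates(df, "forcing_start", "phenology")
    df["stage2_date"] = _dates(df.fillna({"stage2_date": ""}), "stage2_date",
                               "phenology", allow_blank=True)
    df["n_buds_total"] = _numeric(df, "n_buds_total", "phenology").astype(int)
    df["n_buds_ge_stage2"] = _numeric(df, "n_buds_ge_stage2", "phenology").astype(int)
    bad = df.index[
        (df["n_buds_total"] < 1)
        | (df["n_buds_ge_stage2"] < 0)
        | (df["n_buds_ge_stage2"] > df["n_buds_total"])
    ]
    if len(bad):
        rows = [int(i) + 1 for i in bad[:5]]
        raise SchemaError(f"phenology: inconsistent bud counts at row(s) {rows}")
    bad = df.index[df["forcing_start"] < df["campaign_date"]]
    if len(bad):
        rows = [int(i) + 1 for i in bad[:5]]
        raise SchemaError(f"phenology: forcing_start precedes campaign_date at row(s) {rows}")
    return df


def read_mass(path: "str | Path") -> pd.DataFrame:
    """Bud mass file: sample_id, fresh_mass_mg, dry_mass_mg."""
    df = read_csv(path)
    _require_columns(df, ["sample_id", "fresh_mass_mg", "dry_mass_mg"], "mass")
    df["fresh_mass_mg"] = _numeric(df, "fresh_mass_mg", "mass")
    df["dry_mass_mg"] = _numeric(df, "dry_mass_mg", "mass")
    bad = df.index[
        (df["dry_mass_mg"] <= 0) | (df["dry_mass_mg"] > df["fresh_mass_mg"])
    ]
    if len(bad):
        rows = [int(i) + 1 for i in bad[:5]]
        raise SchemaError(f"mass: dry mass non-positive or exceeding fresh at row(s) {rows}")
    return df


def read_isotopes(path: "str | Path") -> pd.DataFrame:
    """Isotope file: per-sample δ²H/δ¹⁸O with metadata and labelling flag."""
    df = read_csv(path)
    req = [
        "sample_id", "species", "site", "tree_id", "campaign_date",
        "tissue", "d2H_permil", "d18O_permil", "is_labelled",
    ]
    _require_columns(df, req, "isotopes")
    df["campaign_date"] = _dates(df, "campaign_date", "isotopes")
    df["d2H_permil"] = _numeric(df, "d2H_permil", "isotopes")
    df["d18O_permil"] = _numeric(df, "d18O_permil", "isotopes")
    bad = df.index[~df["tissue"].isin(["bud", "twig"])]
    if len(bad):
        rows = [int(i) + 1 for i in bad[:5]]
        raise SchemaError(f"isotopes: tissue must be 'bud' or 'twig' at row(s) {rows}")
    if df["is_labelled"].dtype == object:
        mapped = df["is_labelled"].astype(str).str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        bad = df.index[mapped.isna()]
        if len(bad):
            rows = [int(i) + 1 for i in bad[:5]]
            raise SchemaError(f"isotopes: is_labelled not boolean at row(s) {rows}")
        df["is_labelled"] = mapped
    df["is_labelled"] = df["is_labelled"].astype(bool)
    bad = df.index[(df["d2H_permil"] <= -1000) | (df["d18O_permil"] <= -1000)]
    if len(bad):
        rows = [int(i) + 1 for i in bad[:5]]
        raise SchemaError(f"isotopes: delta value(s) at/below -1000‰ at row(s) {rows}")
    # rename to the column names the isotope stage uses
    return df.rename(columns={"d2H_permil": "d2H", "d18O_permil": "d18O"})
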