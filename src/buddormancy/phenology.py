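"""Dormancy-status observables from climate loggers and forcing assays.

Covers four measurements:

* daily aggregation of hourly air-temperature loggers (mean/min/max/sd)
  and first-frost detection;
* budburst success of a forced twig — the fraction of its buds reaching
  at least the budburst stage (stage 2 on the 0–4 scale: dormant,
  swelling, budburst, folded leaves, unfolded leaves);
* thermal time to budburst under constant forcing, the assay's readout
  of dormancy depth — days from forcing start to the first stage-2
  observation times the forcing offset above a base temperature;
* bud water content from fresh and dry mass.

Twigs whose buds never reach stage 2 are censored: they contribute a
success fraction but no thermal time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_daily",
    "period_summary",
    "first_frost_date",
    "budburst_success",
    "thermal_time_to_budburst",
    "bud_water_content",
    "outcomes_table",
    "BudburstOutcome",
]

FULL_DAY_HOURS = 20  # days with fewer hourly readings are flagged incomplete


@dataclass
class BudburstOutcome:
    """Derived per-twig outcome of a forcing assay."""

    twig_id: str
    success_fraction: float
    days_to_stage2: Optional[float]
    thermal_time_dd: Optional[float]  # degree-days above base
    censored: bool
    suspicious: bool = False  # stage 2 on the day forcing started

    def __post_init__(self) -> None:
        if self.censored != (self.days_to_stage2 is None):
            raise ValueError("censored flag inconsistent with days_to_stage2")
        if (self.thermal_time_dd is None) != (self.days_to_stage2 is None):
            raise ValueError("thermal_time_dd must be absent iff censored")


def aggregate_daily(temps: pd.DataFrame) -> pd.DataFrame:
    """Aggregate an hourly logger series to daily climate statistics.

    Parameters
    ----------
    temps
        Frame with columns ``site, datetime, temp_c``; timestamps must be
        strictly increasing within each site.

    Returns
    -------
    DataFrame with one row per site × day: ``site, date, mean_c, min_c,
    max_c, sd_c, n_hours, complete`` (``sd_c`` is the within-day
    population-style sample standard deviation, ddof=1; 0 for a single
    reading).
    """
    if temps.empty:
        raise ValueError("empty temperature series")
    t = temps.copy()
    t["datetime"] = pd.to_datetime(t["datetime"])
    for site, grp in t.groupby("site"):
        dt = grp["datetime"]
        if not dt.is_monotonic_increasing or dt.duplicated().any():
            raise ValueError(f"timestamps for site {site} must be strictly increasing")
    t["date"] = t["datetime"].dt.floor("D")
    out = (
        t.groupby(["site", "date"])["temp_c"]
        .agg(mean_c="mean", min_c="min", max_c="max", sd_c="std", n_hours="count")
        .reset_index()
    )
    out["sd_c"] = out["sd_c"].fillna(0.0)
    out["complete"] = out["n_hours"] >= FULL_DAY_HOURS
    if (~out["complete"]).any():
        n_bad = int((~out["complete"]).sum())
        warnings.warn(f"{n_bad} day(s) have fewer than {FULL_DAY_HOURS} hourly readings")
    return out


def period_summary(
    daily: pd.DataFrame, start: str, end: str, site: Optional[str] = None
) -> dict:
    """Mean of daily means ± mean of daily sds over a date window.

    The conventional climate summary for a sampling period: e.g. a site
    reported as "6.4 ± 2.6 °C" is the average daily mean temperature and
    the average within-day standard deviation over the campaign window.
    """
    d = daily
    if site is not None:
        d = d.loc[d["site"] == site]
    win = d.loc[(d["date"] >= pd.Timestamp(start)) & (d["date"] <= pd.Timestamp(end))]
    if win.empty:
        raise ValueError("no daily records in the requested window")
    return {
        "mean_c": float(win["mean_c"].mean()),
        "mean_daily_sd_c": float(win["sd_c"].mean()),
        "n_days": int(len(win)),
    }


def first_frost_date(
    daily: pd.DataFrame, mode: str = "min_below_0", site: Optional[str] = None
) -> Optional[pd.Timestamp]:
    """Earliest day whose minimum (or mean) temperature drops below 0 °C.

    Returns None if no day qualifies.
    """
    if mode not in ("min_below_0", "mean_below_0"):
        raise ValueError(f"unknown frost mode {mode!r}")
    d = daily
    if site is not None:
        d = d.loc[d["site"] == site]
    if d.empty:
        raise ValueError("empty daily series")
    col = "min_c" if mode == "min_below_0" else "mean_c"
    hit = d.loc[d[col] < 0.0, "date"]
    return None if hit.empty else pd.Timestamp(hit.min())


def budburst_success(n_buds_ge_stage2: int, n_buds_total: int) -> float:
    """Fraction of a twig's buds that reached at least the budburst stage."""
    if n_buds_total < 1:
        raise ValueError("n_buds_total must be >= 1")
    if not 0 <= n_buds_ge_stage2 <= n_buds_total:
        raise ValueError("bud counts out of range")
    return n_buds_ge_stage2 / n_buds_total


def thermal_time_to_budburst(
    record: pd.Series,
    forcing_temp_c: float = 20.0,
    base_temp_c: float = 0.0,
) -> BudburstOutcome:
    """Thermal time (degree-days above base) to the first stage-2 observation.

    ``record`` needs ``twig_id, forcing_start, stage2_date, n_buds_total,
    n_buds_ge_stage2``; a missing ``stage2_date`` marks a censored twig.
    Under constant forcing the thermal time is simply days × (forcing −
    base); base defaults to 0 °C so 14 days at 20 °C is 280 °C·d.
    """
    if forcing_temp_c <= base_temp_c:
        raise ValueError("forcing temperature must exceed the base temperature")
    success = budburst_success(
        int(record["n_buds_ge_stage2"]), int(record["n_buds_total"])
    )
    s2 = record.get("stage2_date")
    if s2 is None or (isinstance(s2, float) and np.isnan(s2)) or s2 is pd.NaT or s2 == "":
        return BudburstOutcome(
            twig_id=str(record["twig_id"]),
            success_fraction=success,
            days_to_stage2=None,
            thermal_time_dd=None,
            censored=True,
        )
    s2 = pd.Timestamp(s2)
    start = pd.Timestamp(record["forcing_start"])
    days = (s2 - start) / pd.Timedelta(days=1)
    if days < 0:
        raise ValueError(
            f"twig {record['twig_id']}: stage-2 date {s2.date()} precedes "
            f"forcing start {start.date()}"
        )
    return BudburstOutcome(
        twig_id=str(record["twig_id"]),
        success_fraction=success,
        days_to_stage2=float(days),
        thermal_time_dd=float(days) * (forcing_temp_c - base_temp_c),
        censored=False,
        suspicious=days == 0,
    )


def bud_water_content(
    fresh_mass_mg, dry_mass_mg, basis: str = "fresh"
) -> "np.ndarray | float":
    """Water content (%) of a bud from mass before and after water extraction.

    Fresh-mass basis (default): 100·(fresh − dry)/fresh, bounded in
    [0, 100). Dry-mass basis: 100·(fresh − dry)/dry.
    """
    fresh = np.asarray(fresh_mass_mg, dtype=float)
    dry = np.asarray(dry_mass_mg, dtype=float)
    if np.any(dry <= 0):
        raise ValueError("dry mass must be strictly positive")
    if np.any(dry > fresh):
        bad = np.argwhere(np.atleast_1d(dry > fresh)).ravel().tolist()
        raise ValueError(f"dry mass exceeds fresh mass at row(s) {bad[:5]}")
    if basis == "fresh":
        out = 100.0 * (fresh - dry) / fresh
    elif basis == "dry":
        out = 100.0 * (fresh - dry) / dry
    else:
        raise ValueError(f"unknown water-content basis {basis!r}")
    return out if out.ndim else float(out)


def outcomes_table(
    phenology: pd.DataFrame,
    forcing_temp_c: float = 20.0,
    base_temp_c: float = 0.0,
) -> pd.DataFrame:
    """Per-twig budburst outcomes for a whole phenology table.

    ``phenology`` carries one row per forced twig with the columns used
    by :func:`thermal_time_to_budburst` plus the identifying metadata
    (``tree_id, species, site, campaign_date``), which are copied through.
    """
    rows = []
    for _, rec in phenology.iterrows():
        oc = thermal_time_to_budburst(rec, forcing_temp_c, base_temp_c)
        rows.append(
            {
                "twig_id": oc.twig_id,
                "tree_id": rec["tree_id"],
                "species": rec["species"],
                "site": rec["site"],
                "campaign_date": pd.Timestamp(rec["campaign_date"]),
                "success_fraction": oc.success_fraction,
                "n_buds_total": int(rec["n_buds_total"]),
                "n_buds_ge_stage2": int(rec["n_buds_ge_stage2"]),
                "days_to_stage2": oc.days_to_stage2,
                "thermal_time_dd": oc.thermal_time_dd,
                "censored": oc.censored,
            }
        )
    return pd.DataFrame(rows)
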