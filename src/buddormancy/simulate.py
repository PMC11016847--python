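"""Synthetic twig-cutting dormancy experiments with known ground truth.

Emulates a two-site, five-species winter campaign series: hourly
temperature loggers at a low- and a high-elevation site (~2.3 °C apart),
15 sampling campaigns from October to early April (12 main plus 3
higher-resolution mid-winter ones), five deciduous species with distinct
chilling requirements and dormancy depths, plus three natural-abundance
isotope campaigns in the following winter for the background lines.

The latent biology is deliberately simple but carries the qualitative
structure the analysis stage must recover:

* chilling hours (air temperature within a 0–10 °C band) accumulate
  from autumn; ln(dormancy depth) declines linearly with chill toward
  the species' residual forcing requirement;
* budburst success rises from a base to a maximum as chilling
  progresses; twigs whose buds all fail are censored;
* short-term label uptake peaks during leaf senescence, collapses to a
  near-zero floor afterwards (the endodormancy-onset signature) and,
  for some species, rises again just before budburst;
* bud water content follows a U: autumn plateau, winter plateau, and a
  rise starting several weeks before the field budburst date;
* natural-abundance bud water lies on a species line δ²H = β₀ + β₁·δ¹⁸O
  with slope below the global meteoric water line, drifting toward
  heavier δ¹⁸O through late winter; labelled samples are constructed on
  the atom-fraction scale (background + uptake × label excess) and
  inverted to delta, so the uptake pipeline is exactly invertible when
  all noise terms are zero.

Instrument noise defaults are 1‰ (δ²H) and 0.2‰ (δ¹⁸O). Every stream of
randomness derives from the single config seed; identical configs give
byte-identical output bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS
from .isotope import atom_percent_to_delta, delta_to_atom_percent

__all__ = [
    "SiteParams",
    "SpeciesParams",
    "NoiseParams",
    "SimConfig",
    "default_config",
    "simulate_temperatures",
    "simulate_dormancy_trajectory",
    "simulate_experiment",
    "write_bundle",
    "config_hash",
]

SEASON_COLDEST_DOY = 15  # mid-January
DIURNAL_PEAK_HOUR = 14
CHILL_BAND_C = (0.0, 10.0)
FORCING_TEMP_C = 20.0
MONITOR_INTERVAL_DAYS = 3.5  # twice-weekly budburst checks


@dataclass
class SiteParams:
    """Climate generator parameters for one site."""

    name: str
    annual_mean_c: float = 11.8
    seasonal_amplitude_c: float = 8.2
    diurnal_amplitude_c: float = 3.4
    ar1_coefficient: float = 0.95
    noise_sd_c: float = 2.4
    site_offset_c: float = 0.0  # added to the annual mean

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.seasonal_amplitude_c < 0 or self.diurnal_amplitude_c < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class SpeciesParams:
    """Dormancy, uptake and water-content parameters for one species."""

    name: str
    chill_requirement_h: float
    forcing_requirement_dd: float
    depth_decay_rate: float  # per chilling hour, on ln(thermal time)
    base_success: float
    max_success: float
    senescence_window: Tuple[str, str] = ("2019-10-18", "2019-11-15")
    background_beta0: float = -15.0
    background_beta1: float = 6.0
    uptake_peak_pct: float = 35.0
    uptake_floor_pct: float = 1.0
    uptake_presenescence_pct: float = 1.0
    prebudburst_uptake_rise_pct: float = 0.0
    twig_uptake_bonus_pct: float = 6.0
    wc_autumn_pct: float = 50.0
    wc_winter_pct: float = 46.0
    wc_spring_pct: float = 56.0
    wc_rise_lead_days: float = 45.0
    field_budburst_date: str = "2020-04-15"

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_success <= self.max_success <= 1.0:
            raise ValueError("need 0 <= base_success <= max_success <= 1")
        if self.uptake_floor_pct >= self.uptake_peak_pct:
            raise ValueError("uptake floor must lie below the peak")
        if not 0.0 < self.background_beta1 <= 8.0:
            raise ValueError("background slope must lie in (0, 8]")


@dataclass
class NoiseParams:
    """All stochastic dispersion parameters of the generator."""

    d2H_sd: float = 1.0  # ‰, instrument
    d18O_sd: float = 0.2  # ‰, instrument
    line_scatter_sd: float = 1.5  # ‰, biological scatter of δ²H around the line
    d18O_spread_sd: float = 2.0  # ‰, between-sample spread of natural δ¹⁸O
    wc_sd_pct: float = 2.0
    uptake_cv: float = 0.30  # multiplicative (lognormal) biological spread
    uptake_sd_pct: float = 0.5  # small additive component
    thermal_time_lnsd: float = 0.12  # lognormal twig-level depth noise
    tree_logit_sd: float = 0.4  # tree effect on success logit
    tree_wc_sd_pct: float = 1.5
    tree_uptake_lnsd: float = 0.20  # multiplicative tree effect on uptake
    tree_depth_lnsd: float = 0.10

    def zeroed(self) -> "NoiseParams":
        """All-zero copy, for exact-recovery oracle runs."""
        return NoiseParams(**{k: 0.0 for k in asdict(self)})


def _default_sites() -> List[SiteParams]:
    return [
        SiteParams(name="Muttenz", site_offset_c=0.0),
        SiteParams(name="Uetliberg", site_offset_c=-2.3, diurnal_amplitude_c=2.2,
                   noise_sd_c=1.8),
    ]


def _default_species() -> List[SpeciesParams]:
    # chilling requirements are sized so that dormancy release stretches
    # into late winter (February–March), as in the field assay: cumulative
    # 0–10 °C hours over Nov–Mar total roughly 3000 h at these sites
    return [
        SpeciesParams("maple", 2000, 320, 0.0007, 0.10, 0.70,
                      background_beta0=-15, background_beta1=6.5,
                      uptake_peak_pct=35, wc_autumn_pct=52, wc_winter_pct=48,
                      wc_spring_pct=58),
        SpeciesParams("hornbeam", 1300, 180, 0.0012, 0.30, 0.85,
                      background_beta0=-20, background_beta1=5.8,
                      uptake_peak_pct=40, uptake_floor_pct=3.0,
                      wc_autumn_pct=50, wc_winter_pct=46, wc_spring_pct=56),
        SpeciesParams("beech", 2400, 340, 0.0005, 0.60, 0.90,
                      background_beta0=-12, background_beta1=6.2,
                      uptake_peak_pct=30, prebudburst_uptake_rise_pct=10.0,
                      wc_autumn_pct=44, wc_winter_pct=41, wc_spring_pct=50),
        SpeciesParams("oak", 2200, 220, 0.0005, 0.15, 0.45,
                      background_beta0=-8, background_beta1=7.0,
                      uptake_peak_pct=25, wc_autumn_pct=42, wc_winter_pct=40,
                      wc_spring_pct=47),
        SpeciesParams("lime", 1600, 200, 0.0009, 0.02, 0.80,
                      background_beta0=-25, background_beta1=5.5,
                      uptake_peak_pct=45, prebudburst_uptake_rise_pct=12.0,
                      wc_autumn_pct=57, wc_winter_pct=53, wc_spring_pct=62),
    ]


#: 12 main campaigns (Oct 2019 – Mar 2020, ~biweekly) + 3 extra mid-winter ones.
DEFAULT_CAMPAIGN_DATES = [
    "2019-10-10", "2019-10-23", "2019-11-06", "2019-11-27", "2019-12-11",
    "2019-12-27", "2020-01-08", "2020-01-16", "2020-01-24", "2020-02-01",
    "2020-02-08", "2020-02-16", "2020-02-26", "2020-03-12", "2020-03-30",
]
#: Natural-abundance background campaigns in the following winter.
DEFAULT_BACKGROUND_DATES = ["2021-01-21", "2021-02-18", "2021-03-04"]
#: δ¹⁸O background means at those dates: ~10‰ late-winter evaporative shift.
DEFAULT_BACKGROUND_D18O_MEANS = [-3.0, 2.0, 7.0]
#: Campaign index of the twig-tissue comparison (24 Jan).
TWIG_TISSUE_CAMPAIGN = 9


@dataclass
class SimConfig:
    """Full generator configuration."""

    seed: int = 0
    n_trees_per_species_site: int = 5
    campaign_dates: List[str] = field(default_factory=lambda: list(DEFAULT_CAMPAIGN_DATES))
    background_dates: List[str] = field(default_factory=lambda: list(DEFAULT_BACKGROUND_DATES))
    background_d18o_means: List[float] = field(
        default_factory=lambda: list(DEFAULT_BACKGROUND_D18O_MEANS)
    )
    n_background_per_site_date: int = 8
    sites: List[SiteParams] = field(default_factory=_default_sites)
    species: List[SpeciesParams] = field(default_factory=_default_species)
    noise: NoiseParams = field(default_factory=NoiseParams)
    label_d2h_permil: float = 2000.0
    season_start: str = "2019-10-01"
    season_end: str = "2020-04-30"
    chill_band_c: Tuple[float, float] = CHILL_BAND_C

    def __post_init__(self) -> None:
        dates = pd.to_datetime(self.campaign_dates)
        if not dates.is_monotonic_increasing or dates.duplicated().any():
            raise ValueError("campaign_dates must be strictly increasing")


def default_config(seed: int = 0) -> SimConfig:
    return SimConfig(seed=seed)


def config_hash(config: SimConfig) -> str:
    """Stable short hash of the full configuration (seed included)."""
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ----------------------------------------------------------------------
# climate


def simulate_temperatures(
    site: SiteParams, start: str, end: str, seed: int
) -> pd.DataFrame:
    """Hourly logger series: seasonal + diurnal sinusoids + AR(1) noise."""
    times = pd.date_range(start, end, freq="h")
    if len(times) < 30 * 24:
        raise ValueError("date range must span at least 30 days")
    doy = times.dayofyear.to_numpy(float)
    hour = times.hour.to_numpy(float)
    seasonal = -site.seasonal_amplitude_c * np.cos(
        2 * np.pi * (doy - SEASON_COLDEST_DOY) / 365.25
    )
    diurnal = -site.diurnal_amplitude_c * np.cos(
        2 * np.pi * (hour - DIURNAL_PEAK_HOUR) / 24.0
    )
    rng = np.random.default_rng(seed)
    n = len(times)
    eps = np.zeros(n)
    if site.noise_sd_c > 0:
        innov_sd = site.noise_sd_c * np.sqrt(1.0 - site.ar1_coefficient**2)
        white = rng.normal(0.0, 1.0, size=n)
        eps[0] = white[0] * site.noise_sd_c
        for t in range(1, n):
            eps[t] = site.ar1_coefficient * eps[t - 1] + innov_sd * white[t]
    temp = site.annual_mean_c + site.site_offset_c + seasonal + diurnal + eps
    return pd.DataFrame({"site": site.name, "datetime": times, "temp_c": temp})


def chilling_hours(temps: pd.DataFrame, band: Tuple[float, float] = CHILL_BAND_C) -> pd.Series:
    """Cumulative chilling hours (temp within band) indexed by timestamp."""
    inband = ((temps["temp_c"] >= band[0]) & (temps["temp_c"] <= band[1])).astype(int)
    return pd.Series(inband.cumsum().to_numpy(), index=pd.to_datetime(temps["datetime"]))


def simulate_dormancy_trajectory(
    species: SpeciesParams,
    temps: pd.DataFrame,
    campaign_dates: List[str],
    chill_band: Tuple[float, float] = CHILL_BAND_C,
) -> pd.DataFrame:
    """Latent per-campaign dormancy state for one species at one site.

    Chilling hours are counted on the hourly series; ln(dormancy depth)
    declines linearly with chill from its autumn value down to
    ln(forcing requirement), reached when the chilling requirement is
    met ("released").
    """
    cum = chilling_hours(temps, chill_band)
    rows = []
    for ci, d in enumerate(pd.to_datetime(campaign_dates), start=1):
        upto = cum.loc[:d]
        chill = float(upto.iloc[-1]) if len(upto) else 0.0
        ln_depth = np.log(species.forcing_requirement_dd) + species.depth_decay_rate * max(
            0.0, species.chill_requirement_h - chill
        )
        rows.append(
            {
                "campaign_index": ci,
                "campaign_date": d,
                "chill_accum_h": chill,
                "dormancy_depth_dd": float(np.exp(ln_depth)),
                "released": chill >= species.chill_requirement_h,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# latent trajectories


def _uptake_trajectory(species: SpeciesParams, date: pd.Timestamp) -> float:
    s0, s1 = (pd.Timestamp(x) for x in species.senescence_window)
    budburst = pd.Timestamp(species.field_budburst_date)
    if date < s0:
        return species.uptake_presenescence_pct
    if date <= s1:
        return species.uptake_peak_pct
    base = species.uptake_floor_pct
    if date >= budburst - pd.Timedelta(days=21):
        base += species.prebudburst_uptake_rise_pct
    return base


WC_RELEASE_COUPLING = 0.5  # share of the winter→spring rise driven by dormancy release


def _wc_trajectory(
    species: SpeciesParams, date: pd.Timestamp, release_frac: float = 0.0
) -> float:
    """U-shaped water content: autumn plateau, post-senescence minimum,
    then recovery through winter and a fast rise before field budburst.

    The winter recovery is coupled to dormancy release
    (``release_frac`` = accumulated chill / chilling requirement): bud
    rehydration tracks deacclimation, which is what makes water content
    a proxy for dormancy depth. The remaining rise happens in the final
    ``wc_rise_lead_days`` before the field budburst date.
    """
    s1 = pd.Timestamp(species.senescence_window[1])
    winter_at = s1 + pd.Timedelta(days=15)
    budburst = pd.Timestamp(species.field_budburst_date)
    rise_start = budburst - pd.Timedelta(days=species.wc_rise_lead_days)
    span = species.wc_spring_pct - species.wc_winter_pct
    if date <= s1:
        return species.wc_autumn_pct
    if date < winter_at:
        frac = (date - s1) / (winter_at - s1)
        return species.wc_autumn_pct + frac * (species.wc_winter_pct - species.wc_autumn_pct)
    val = species.wc_winter_pct + WC_RELEASE_COUPLING * span * min(1.0, release_frac)
    if date >= rise_start:
        frac = min(1.0, (date - rise_start) / (budburst - rise_start))
        val += (1.0 - WC_RELEASE_COUPLING) * span * frac
    return min(val, species.wc_spring_pct)


def _background_d18o_mean(config: SimConfig, date: pd.Timestamp) -> float:
    """Seasonal natural-abundance δ¹⁸O mean, drifting heavier toward spring."""
    # linear drift from -4‰ (early Oct) to +6‰ (late Apr), emulating the
    # ~10‰ late-winter evaporative enrichment of bud water
    start = pd.Timestamp(config.season_start)
    end = pd.Timestamp(config.season_end)
    span = (end - start).days
    frac = np.clip((date - start).days / span, 0.0, 1.0)
    return -4.0 + 10.0 * frac


def true_onset_campaign(species: SpeciesParams, campaign_dates: List[str]) -> Optional[int]:
    """Programmed endodormancy-onset campaign: first floor campaign after the peak."""
    vals = [_uptake_trajectory(species, pd.Timestamp(d)) for d in campaign_dates]
    peak = int(np.argmax(vals))
    for i in range(peak + 1, len(vals)):
        if vals[i] <= species.uptake_floor_pct + species.prebudburst_uptake_rise_pct * 0 + 1e-9:
            return i + 1
    return None


# ----------------------------------------------------------------------
# full experiment


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def simulate_experiment(config: SimConfig) -> Dict[str, pd.DataFrame]:
    """Generate a complete synthetic campaign bundle.

    Returns ``{"temps", "phenology", "mass", "isotopes", "truth"}``
    DataFrames matching the pipeline's CSV schemas. Fully reproducible:
    the bundle is a pure function of the config (seed included).
    """
    label = config.label_d2h_permil
    noise = config.noise
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(len(config.sites) + 1)
    temps_frames = []
    site_temps: Dict[str, pd.DataFrame] = {}
    for site, s in zip(config.sites, seeds[:-1]):
        t = simulate_temperatures(site, config.season_start, config.season_end, int(s))
        site_temps[site.name] = t
        temps_frames.append(t)
    rng = np.random.default_rng(seeds[-1])

    ap_label = delta_to_atom_percent(label)
    campaign_ts = [pd.Timestamp(d) for d in config.campaign_dates]

    pheno_rows, mass_rows, iso_rows, truth_rows = [], [], [], []
    for site in config.sites:
        for species in config.species:
            traj = simulate_dormancy_trajectory(
                species, site_temps[site.name], config.campaign_dates, config.chill_band_c
            )
            onset_true = true_onset_campaign(species, config.campaign_dates)
            for tree in range(1, config.n_trees_per_species_site + 1):
                tree_id = f"{site.name[:3].upper()}-{species.name}-T{tree}"
                eff_logit = rng.normal(0.0, noise.tree_logit_sd) if noise.tree_logit_sd else 0.0
                eff_wc = rng.normal(0.0, noise.tree_wc_sd_pct) if noise.tree_wc_sd_pct else 0.0
                eff_up = rng.normal(0.0, noise.tree_uptake_lnsd) if noise.tree_uptake_lnsd else 0.0
                eff_depth = rng.normal(0.0, noise.tree_depth_lnsd) if noise.tree_depth_lnsd else 0.0
                for ci, cdate in enumerate(campaign_ts, start=1):
                    state = traj.iloc[ci - 1]
                    # ---- forcing twig: success + thermal time ----
                    twig_id = f"{tree_id}-C{ci:02d}F"
                    forcing_start = cdate + pd.Timedelta(days=1)
                    n_buds = int(rng.integers(8, 15))
                    p = species.base_success + (
                        species.max_success - species.base_success
                    ) * min(1.0, state["chill_accum_h"] / species.chill_requirement_h)
                    p_tree = float(_sigmoid(_logit(p) + eff_logit))
                    n_ge2 = int(rng.binomial(n_buds, p_tree))
                    depth = float(
                        state["dormancy_depth_dd"]
                        * np.exp(eff_depth + (rng.normal(0.0, noise.thermal_time_lnsd)
                                              if noise.thermal_time_lnsd else 0.0))
                    )
                    if n_ge2 > 0:
                        days = depth / FORCING_TEMP_C
                        days_obs = float(
                            np.ceil(days / MONITOR_INTERVAL_DAYS) * MONITOR_INTERVAL_DAYS
                        )
                        stage2 = forcing_start + pd.Timedelta(days=days_obs)
                        stage4 = stage2 + pd.Timedelta(days=7)
                    else:
                        stage2 = stage4 = None
                    pheno_rows.append(
                        {
                            "twig_id": twig_id,
                            "tree_id": tree_id,
                            "species": species.name,
                            "site": site.name,
                            "campaign_date": cdate.date().isoformat(),
                            "forcing_start": forcing_start.date().isoformat(),
                            "stage1_date": (
                                (stage2 - pd.Timedelta(days=MONITOR_INTERVAL_DAYS)).date().isoformat()
                                if stage2 is not None else ""
                            ),
                            "stage2_date": stage2.date().isoformat() if stage2 is not None else "",
                            "stage4_date": stage4.date().isoformat() if stage4 is not None else "",
                            "n_buds_total": n_buds,
                            "n_buds_ge_stage2": n_ge2,
                        }
                    )
                    # ---- labelled bud sample: uptake + water content ----
                    sample_id = f"{tree_id}-C{ci:02d}B"
                    tissues = [("bud", sample_id)]
                    if ci == TWIG_TISSUE_CAMPAIGN:
                        tissues.append(("twig", f"{tree_id}-C{ci:02d}W"))
                    for tissue, sid in tissues:
                        u_traj = _uptake_trajectory(species, cdate)
                        if tissue == "twig":
                            u_traj += species.twig_uptake_bonus_pct
                        # biological spread is proportional to the signal
                        # (lognormal tree and sample effects) plus a small
                        # additive component; near-zero winter uptake stays
                        # near zero instead of being inflated by clipping
                        u = u_traj * np.exp(
                            eff_up
                            + (rng.normal(0.0, noise.uptake_cv) if noise.uptake_cv else 0.0)
                        ) + (
                            rng.normal(0.0, noise.uptake_sd_pct) if noise.uptake_sd_pct else 0.0
                        )
                        u = float(np.clip(u, 0.0, 99.0))
                        d18o_true = _background_d18o_mean(config, cdate) + (
                            rng.normal(0.0, noise.d18O_spread_sd)
                            if noise.d18O_spread_sd else 0.0
                        )
                        bg_d2h_true = (
                            species.background_beta0
                            + species.background_beta1 * d18o_true
                            + (rng.normal(0.0, noise.line_scatter_sd)
                               if noise.line_scatter_sd else 0.0)
                        )
                        ap_bg = delta_to_atom_percent(bg_d2h_true)
                        ap_sample = ap_bg + u / 100.0 * (ap_label - ap_bg)
                        d2h_true = atom_percent_to_delta(ap_sample)
                        d2h_meas = d2h_true + (
                            rng.normal(0.0, noise.d2H_sd) if noise.d2H_sd else 0.0
                        )
                        d18o_meas = d18o_true + (
                            rng.normal(0.0, noise.d18O_sd) if noise.d18O_sd else 0.0
                        )
                        iso_rows.append(
                            {
                                "sample_id": sid,
                                "species": species.name,
                                "site": site.name,
                                "tree_id": tree_id,
                                "campaign_date": cdate.date().isoformat(),
                                "tissue": tissue,
                                "d2H_permil": d2h_meas,
                                "d18O_permil": d18o_meas,
                                "is_labelled": True,
                            }
                        )
                        if tissue == "bud":
                            release_frac = float(
                                state["chill_accum_h"] / species.chill_requirement_h
                            )
                            wc = _wc_trajectory(species, cdate, release_frac) + eff_wc + (
                                rng.normal(0.0, noise.wc_sd_pct) if noise.wc_sd_pct else 0.0
                            )
                            wc = float(np.clip(wc, 1.0, 99.0))
                            dry = float(np.exp(rng.normal(np.log(20.0), 0.25)))
                            fresh = dry / (1.0 - wc / 100.0)
                            mass_rows.append(
                                {
                                    "sample_id": sid,
                                    "fresh_mass_mg": fresh,
                                    "dry_mass_mg": dry,
                                }
                            )
                        truth_rows.append(
                            {
                                "sample_id": sid,
                                "twig_id": twig_id,
                                "species": species.name,
                                "site": site.name,
                                "tree_id": tree_id,
                                "campaign_index": ci,
                                "campaign_date": cdate.date().isoformat(),
                                "tissue": tissue,
                                "uptake_truth_pct": u,
                                "wc_truth_pct": (
                                    wc if tissue == "bud" else np.nan
                                ),
                                "depth_truth_dd": depth,
                                "success_p_truth": p_tree,
                                "chill_accum_h": float(state["chill_accum_h"]),
                                "released": bool(state["released"]),
                                "onset_campaign_true": (
                                    onset_true if onset_true is not None else np.nan
                                ),
                            }
                        )

    # ---- natural-abundance background campaigns (following winter) ----
    for site in config.sites:
        for species in config.species:
            for bdate, bmean in zip(config.background_dates, config.background_d18o_means):
                for k in range(1, config.n_background_per_site_date + 1):
                    sid = f"{site.name[:3].upper()}-{species.name}-BG{bdate[:7]}-{k}"
                    d18o_true = bmean + (
                        rng.normal(0.0, noise.d18O_spread_sd) if noise.d18O_spread_sd else 0.0
                    )
                    d2h_true = (
                        species.background_beta0
                        + species.background_beta1 * d18o_true
                        + (rng.normal(0.0, noise.line_scatter_sd)
                           if noise.line_scatter_sd else 0.0)
                    )
                    iso_rows.append(
                        {
                            "sample_id": sid,
                            "species": species.name,
                            "site": site.name,
                            "tree_id": f"{site.name[:3].upper()}-{species.name}-BG{k}",
                            "campaign_date": bdate,
                            "tissue": "bud",
                            "d2H_permil": d2h_true
                            + (rng.normal(0.0, noise.d2H_sd) if noise.d2H_sd else 0.0),
                            "d18O_permil": d18o_true
                            + (rng.normal(0.0, noise.d18O_sd) if noise.d18O_sd else 0.0),
                            "is_labelled": False,
                        }
                    )

    return {
        "temps": pd.concat(temps_frames, ignore_index=True),
        "phenology": pd.DataFrame(pheno_rows),
        "mass": pd.DataFrame(mass_rows),
        "isotopes": pd.DataFrame(iso_rows),
        "truth": pd.DataFrame(truth_rows),
    }


def write_bundle(bundle: Dict[str, pd.DataFrame], outdir: "str | Path",
                 config: Optional[SimConfig] = None) -> Dict[str, Path]:
    """Write a bundle to ``outdir`` as CSVs plus a JSON manifest."""
    from .io import write_csv  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    header = None
    if config is not None:
        header = {"config_hash": config_hash(config), "seed": config.seed}
    for name, df in bundle.items():
        p = outdir / f"{name}.csv"
        write_csv(df, p, meta=header)
        paths[name] = p
    if config is not None:
        manifest = {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "config": asdict(config),
            "files": sorted(f"{n}.csv" for n in bundle),
        }
        mp = outdir / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        paths["manifest"] = mp
    return paths
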