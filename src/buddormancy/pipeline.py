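"""End-to-end orchestration: isotope → phenology → models → report.

The pipeline is deterministic: all randomness lives in the synthetic
generator, and identical inputs yield byte-identical outputs (the run
manifest records a config hash, not wall-clock time).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .constants import DEFAULT_CONSTANTS, IsotopeConstants
from .isotope import LabelSpec, fit_background_lines, line_vs_gmwl, uptake_table
from .models import (
    BudburstSuccessModel,
    CampaignResponseModel,
    DormancyDepthModel,
    assign_campaign_index,
    build_analysis_table,
    detect_endodormancy_onset,
    dormancy_correlations,
)
from .phenology import (
    aggregate_daily,
    bud_water_content,
    first_frost_date,
    outcomes_table,
    period_summary,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serialisable to one YAML file."""

    temps_csv: str = "temps.csv"
    phenology_csv: str = "phenology.csv"
    mass_csv: str = "mass.csv"
    isotopes_csv: str = "isotopes.csv"
    output_dir: str = "out"
    r_standard_2h: float = DEFAULT_CONSTANTS.r_standard_2h
    r_standard_18o: float = DEFAULT_CONSTANTS.r_standard_18o
    label_d2h_permil: float = 2000.0
    guard_permil: float = 100.0
    line_scope: str = "species"  # or "species_site"
    forcing_temp_c: float = 20.0
    base_temp_c: float = 0.0
    water_content_basis: str = "fresh"
    exclude_campaigns: List[int] = field(default_factory=lambda: [1, 2, 3])
    after_first_frost: bool = True
    after_date: Optional[str] = None  # overrides frost detection when set
    onset_threshold_fraction: float = 0.1
    onset_peak_window_end: str = "2019-12-15"  # autumn window for the peak search
    correlation_level: str = "tree"
    responses: List[str] = field(
        default_factory=lambda: ["success", "depth", "water", "uptake"]
    )

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    _PATH_FIELDS = ("temps_csv", "phenology_csv", "mass_csv", "isotopes_csv", "output_dir")

    def param_dict(self) -> dict:
        """Analysis parameters only — file locations excluded, so the hash
        identifies the configuration, not where it ran."""
        d = asdict(self)
        for k in self._PATH_FIELDS:
            d.pop(k, None)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.param_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _results_frame(res) -> pd.DataFrame:
    """Combine a fitted model's coefficients and ANOVA into one flat table."""
    coef = res.coef_table.copy()
    coef.insert(0, "table", "coefficients")
    coef["chisq"] = np.nan
    coef["df"] = np.nan
    coef["anova_type"] = ""
    an = res.anova().copy()
    an.insert(0, "table", "anova")
    an["estimate"] = np.nan
    an["se"] = np.nan
    an["z"] = np.nan
    cols = ["table", "term", "estimate", "se", "z", "p", "chisq", "df", "anova_type"]
    return pd.concat([coef[cols], an[cols]], ignore_index=True)


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute all stages and write the output bundle.

    Returns a dict of in-memory results (tables, fitted models, report
    text); writes ``uptake.csv``, ``outcomes.csv``, ``water_content.csv``,
    ``background_lines.csv``, ``model_<response>.csv``,
    ``correlations.csv``, ``onset.csv``, ``report.txt`` and
    ``manifest.json`` to ``config.output_dir``. On any stage failure the
    partially written outputs are removed and the exception re-raised.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    meta = {"config_hash": config.hash()}

    def _emit(df: pd.DataFrame, name: str) -> None:
        written.append(bio.write_csv(df, outdir / name, meta=meta))

    try:
        # ---------------- inputs ----------------
        temps = bio.read_temps(config.temps_csv)
        pheno = bio.read_phenology(config.phenology_csv)
        mass = bio.read_mass(config.mass_csv)
        isotopes = bio.read_isotopes(config.isotopes_csv)

        constants = IsotopeConstants(
            r_standard_2h=config.r_standard_2h, r_standard_18o=config.r_standard_18o
        )
        label = LabelSpec(
            d2H_label=config.label_d2h_permil, guard_permil=config.guard_permil
        )

        # ---------------- isotope stage ----------------
        lines = fit_background_lines(isotopes, line_scope=config.line_scope)
        line_rows = []
        for key, ln in lines.items():
            diag = line_vs_gmwl(ln, constants)
            line_rows.append(
                {
                    "species": ln.species,
                    "site": ln.site or "pooled",
                    "beta0": ln.beta0,
                    "beta1": ln.beta1,
                    "n": ln.n,
                    "residual_sd": ln.residual_sd,
                    "se_beta0": ln.se_beta0,
                    "se_beta1": ln.se_beta1,
                    "slope_deficit": diag["slope_deficit"],
                    "evaporative_flag": diag["evaporative_flag"],
                }
            )
        lines_df = pd.DataFrame(line_rows).sort_values(["species", "site"]).reset_index(drop=True)
        uptake = uptake_table(
            isotopes, lines, label=label, constants=constants, line_scope=config.line_scope
        )
        uptake_out = uptake[
            [
                "sample_id", "species", "site", "tree_id", "campaign_date", "tissue",
                "d2H", "d18O", "d2H_background_permil", "atom_pct_sample",
                "atom_pct_background", "atom_pct_label", "uptake_pct", "qc_flag",
            ]
        ].rename(columns={"d2H": "d2H_permil", "d18O": "d18O_permil"})
        uptake_out = uptake_out.copy()
        uptake_out["campaign_date"] = pd.to_datetime(uptake_out["campaign_date"]).dt.date
        _emit(lines_df, "background_lines.csv")
        _emit(uptake_out, "uptake.csv")

        # ---------------- phenology stage ----------------
        daily = aggregate_daily(temps)
        frost = {
            site: {
                mode: first_frost_date(daily, mode, site=site)
                for mode in ("min_below_0", "mean_below_0")
            }
            for site in sorted(daily["site"].unique())
        }
        outcomes = outcomes_table(pheno, config.forcing_temp_c, config.base_temp_c)
        oc_out = outcomes.copy()
        oc_out["campaign_date"] = oc_out["campaign_date"].dt.date
        _emit(oc_out, "outcomes.csv")

        meta_cols = ["sample_id", "species", "site", "tree_id", "campaign_date", "tissue"]
        wc = mass.merge(isotopes[meta_cols], on="sample_id", how="left")
        wc = wc.loc[wc["tissue"].fillna("bud") == "bud"].copy()
        wc["water_content_pct"] = bud_water_content(
            wc["fresh_mass_mg"], wc["dry_mass_mg"], basis=config.water_content_basis
        )
        wc_out = wc[meta_cols[:5] + ["fresh_mass_mg", "dry_mass_mg", "water_content_pct"]].copy()
        wc_out["campaign_date"] = pd.to_datetime(wc_out["campaign_date"]).dt.date
        _emit(wc_out, "water_content.csv")

        # ---------------- analysis stage ----------------
        if config.after_date is not None:
            after = pd.Timestamp(config.after_date)
        elif config.after_first_frost:
            frosts = [f["min_below_0"] for f in frost.values() if f["min_below_0"] is not None]
            after = min(frosts) if frosts else pd.Timestamp(outcomes["campaign_date"].min())
        else:
            after = pd.Timestamp(outcomes["campaign_date"].min())

        samples = uptake.loc[uptake["tissue"] == "bud"].merge(
            wc[["sample_id", "water_content_pct"]], on="sample_id", how="left"
        )
        samples["campaign_date"] = pd.to_datetime(samples["campaign_date"])
        samples["campaign_index"] = assign_campaign_index(samples["campaign_date"])

        fitted = {}
        if "success" in config.responses:
            fitted["success"] = BudburstSuccessModel(outcomes).fit()
        if "depth" in config.responses:
            fitted["depth"] = DormancyDepthModel(outcomes, after).fit()
        if "water" in config.responses:
            fitted["water"] = CampaignResponseModel(samples, "water_content_pct").fit()
        if "uptake" in config.responses:
            fitted["uptake"] = CampaignResponseModel(samples, "uptake_pct").fit()
        for name, res in fitted.items():
            _emit(_results_frame(res), f"model_{name}.csv")

        analysis = build_analysis_table(
            outcomes,
            uptake.assign(campaign_date=pd.to_datetime(uptake["campaign_date"])),
            wc.assign(campaign_date=pd.to_datetime(wc["campaign_date"])),
            level=config.correlation_level,
        )
        corr = dormancy_correlations(analysis, config.exclude_campaigns)
        _emit(corr, "correlations.csv")

        # onset detection on per-species campaign-mean uptake (sites pooled)
        date_by_index = (
            samples.drop_duplicates("campaign_index")
            .set_index("campaign_index")["campaign_date"]
            .sort_index()
        )
        autumn_end = pd.Timestamp(config.onset_peak_window_end)
        window_idx = date_by_index.index[date_by_index <= autumn_end]
        peak_window = (int(window_idx.min()), int(window_idx.max())) if len(window_idx) else None
        onset_rows = []
        for sp, grp in samples.groupby("species"):
            means = grp.groupby("campaign_index")["uptake_pct"].mean()
            est = detect_endodormancy_onset(
                means,
                threshold_fraction=config.onset_threshold_fraction,
                species=sp,
                scope="pooled",
                peak_window=peak_window,
            )
            onset_rows.append(
                {
                    "species": est.species,
                    "scope": est.scope,
                    "onset_campaign_index": est.onset_campaign_index,
                    "peak_campaign_index": est.peak_campaign_index,
                    "peak_uptake_pct": est.peak_uptake_pct,
                    "post_drop_mean_pct": est.post_drop_mean_pct,
                    "threshold_fraction": est.threshold_fraction,
                    "detected": est.detected,
                }
            )
        onset_df = pd.DataFrame(onset_rows).sort_values("species").reset_index(drop=True)
        _emit(onset_df, "onset.csv")

        # ---------------- report ----------------
        campaign_span = (outcomes["campaign_date"].min(), outcomes["campaign_date"].max())
        report = _render_report(
            config, daily, frost, lines_df, fitted, corr, onset_df, after, campaign_span
        )
        rp = outdir / "report.txt"
        rp.write_text(report)
        written.append(rp)

        manifest = {
            "config_hash": config.hash(),
            "config": config.param_dict(),
            "after_date": str(pd.Timestamp(after).date()),
            "outputs": sorted(p.name for p in written) + ["manifest.json"],
        }
        mp = outdir / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        written.append(mp)
    except Exception:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise

    return {
        "daily": daily,
        "frost": frost,
        "background_lines": lines_df,
        "uptake": uptake,
        "outcomes": outcomes,
        "water_content": wc,
        "samples": samples,
        "models": fitted,
        "analysis": analysis,
        "correlations": corr,
        "onset": onset_df,
        "after_date": after,
        "report": report,
    }


def _render_report(
    config, daily, frost, lines_df, fitted, corr, onset_df, after, campaign_span
) -> str:
    """Human-readable run summary mirroring the campaign-table layout."""
    out = ["Bud dormancy pipeline report", "=" * 60, ""]
    out.append("Site climate (first to last sampling campaign)")
    start, end = campaign_span
    for site in sorted(daily["site"].unique()):
        s = period_summary(daily, start, end, site=site)
        fr = frost[site]
        out.append(
            f"  {site}: {s['mean_c']:.1f} ± {s['mean_daily_sd_c']:.1f} °C over "
            f"{s['n_days']} days; first frost (daily min < 0 °C): "
            f"{fr['min_below_0'].date() if fr['min_below_0'] is not None else 'none'}; "
            f"first day with mean < 0 °C: "
            f"{fr['mean_below_0'].date() if fr['mean_below_0'] is not None else 'none'}"
        )
    out.append(f"  dormancy-depth model restricted to campaigns on/after {pd.Timestamp(after).date()}")
    out.append("")
    out.append("Natural-abundance background lines (d2H = b0 + b1 * d18O)")
    for _, r in lines_df.iterrows():
        out.append(
            f"  {r['species']:<9} ({r['site']}): b0 = {r['beta0']:7.2f} ‰, "
            f"b1 = {r['beta1']:5.2f} (se {r['se_beta1']:.2f}), n = {int(r['n'])}, "
            f"slope deficit vs GMWL = {r['slope_deficit']:.2f}"
            + ("  [evaporative]" if r["evaporative_flag"] else "")
        )
    out.append("")
    titles = {
        "success": "Budburst success (binomial, type II ANOVA)",
        "depth": "Thermal time to budburst, ln-scale (type III ANOVA)",
        "water": "Bud water content (campaigns categorical, type III ANOVA)",
        "uptake": "Short-term water uptake (campaigns categorical, type III ANOVA)",
    }
    for name, res in fitted.items():
        out.append(titles.get(name, name))
        an = res.anova()
        out.append(an.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        out.append(
            f"  n = {res.nobs}; backend = "
            + ("fixed effects + cluster-robust (tree)" if res.used_fallback
               else "mixed model (random tree intercept)")
        )
        out.append("")
    out.append(
        "Per-species Pearson correlations "
        f"(campaigns {sorted(config.exclude_campaigns)} excluded, "
        f"paired at {config.correlation_level} x campaign level)"
    )
    out.append(corr.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    out.append("")
    out.append("Endodormancy onset from campaign-mean short-term uptake")
    out.append(onset_df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    out.append("")
    return "\n".join(out)
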