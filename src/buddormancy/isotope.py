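"""Water stable-isotope arithmetic for the ²H-labelling assay.

The short-term water-uptake assay incubates detached twig pieces in
deuterium-enriched water (δ²H ≈ 2000‰) for 24 h and asks what fraction of
the bud's water was replaced by label. Because the natural-abundance δ²H
of bud water drifts through winter (evaporative enrichment), the
unlabelled background is not a constant: it is predicted per sample from
the measured δ¹⁸O through a species-specific linear δ¹⁸O→δ²H relationship
fitted on natural-abundance campaigns,

    δ²H_background = β₀ + β₁ · δ¹⁸O_sample.

Delta values are converted to atom percent (the fraction of heavy
isotope among all atoms of the element),

    atom% = 100 · R · (δ/1000 + 1) / (1 + R · (δ/1000 + 1)),

with R the VSMOW reference ratio, and the uptake of labelled water is
the excess atom% over background normalised by the label's excess:

    uptake% = (atom%_sample − atom%_background)
              / (atom%_label − atom%_background) · 100.

All functions accept scalars or numpy arrays and are vectorised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, IsotopeConstants

__all__ = [
    "IsotopeMeasurement",
    "BackgroundLine",
    "LabelSpec",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "fit_background_line",
    "fit_background_lines",
    "predict_background_d2h",
    "label_uptake_percent",
    "uptake_table",
    "line_vs_gmwl",
]

DELTA_LOWER_BOUND = -1000.0  # ‰; −1000 means zero heavy isotope


class InsufficientDataError(ValueError):
    """Too few samples to fit a background line."""


class DegeneratePredictorError(ValueError):
    """No variance in δ¹⁸O; slope is unidentifiable."""


class IllConditionedLabelError(ValueError):
    """Label δ²H too close to the predicted background."""


@dataclass
class IsotopeMeasurement:
    """One bud or twig tissue water extract.

    Delta values are in ‰ vs VSMOW. ``is_labelled`` is True for samples
    from the 24-h label incubation and False for natural-abundance
    (background) campaigns.
    """

    sample_id: str
    species: str
    site: str
    tree_id: str
    campaign_date: "pd.Timestamp"
    tissue: str  # "bud" or "twig"
    d2H: float
    d18O: float
    is_labelled: bool

    def __post_init__(self) -> None:
        if self.tissue not in ("bud", "twig"):
            raise ValueError(f"sample {self.sample_id}: tissue must be 'bud' or 'twig'")
        for name, v in (("d2H", self.d2H), ("d18O", self.d18O)):
            if v <= DELTA_LOWER_BOUND:
                raise ValueError(
                    f"sample {self.sample_id}: {name} = {v}‰ is at or below the "
                    f"physical lower bound of {DELTA_LOWER_BOUND}‰"
                )
        if not self.is_labelled and (self.d2H > 0.0 or self.d18O > 10.0):
            warnings.warn(
                f"sample {self.sample_id}: natural-abundance sample outside the "
                f"expected range (d2H={self.d2H}‰, d18O={self.d18O}‰)",
                stacklevel=2,
            )


@dataclass
class BackgroundLine:
    """Species-specific natural-abundance δ¹⁸O→δ²H regression line."""

    species: str
    beta0: float  # intercept, ‰
    beta1: float  # slope, dimensionless
    n: int
    residual_sd: float
    se_beta0: float
    se_beta1: float
    site: Optional[str] = None  # None when fitted pooled across sites

    def __post_init__(self) -> None:
        if self.n < 3:
            raise InsufficientDataError(
                f"background line for {self.species} needs n >= 3 (got {self.n})"
            )
        if self.residual_sd < 0 or self.se_beta0 < 0 or self.se_beta1 < 0:
            raise ValueError("residual sd and standard errors must be non-negative")


@dataclass
class LabelSpec:
    """The isotopic label applied in the incubation tubes."""

    d2H_label: float = 2000.0  # ‰ vs VSMOW
    guard_permil: float = 100.0  # label must exceed background by at least this

    def __post_init__(self) -> None:
        if self.d2H_label <= DELTA_LOWER_BOUND:
            raise ValueError("label delta below physical bound")


def delta_to_atom_percent(delta, r_standard: float = DEFAULT_CONSTANTS.r_standard_2h):
    """Convert a delta value (‰ vs standard) to atom percent.

    Strictly increasing in ``delta``; returns values in the open
    interval (0, 100).
    """
    delta = np.asarray(delta, dtype=float)
    if r_standard <= 0:
        raise ValueError("r_standard must be strictly positive")
    if np.any(delta <= DELTA_LOWER_BOUND):
        bad = np.atleast_1d(delta)[np.atleast_1d(delta) <= DELTA_LOWER_BOUND]
        raise ValueError(
            f"delta value(s) {bad.tolist()} at or below {DELTA_LOWER_BOUND}‰ "
            "are outside the physical domain"
        )
    r_sample = r_standard * (delta / 1000.0 + 1.0)
    out = 100.0 * r_sample / (1.0 + r_sample)
    return out if out.ndim else float(out)


def atom_percent_to_delta(ap, r_standard: float = DEFAULT_CONSTANTS.r_standard_2h):
    """Algebraic inverse of :func:`delta_to_atom_percent`."""
    ap = np.asarray(ap, dtype=float)
    if r_standard <= 0:
        raise ValueError("r_standard must be strictly positive")
    if np.any((ap <= 0.0) | (ap >= 100.0)):
        raise ValueError("atom percent must lie strictly between 0 and 100")
    frac = ap / 100.0
    r_sample = frac / (1.0 - frac)
    out = 1000.0 * (r_sample / r_standard - 1.0)
    return out if out.ndim else float(out)


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Simple-OLS slope/intercept with standard errors and residual sd."""
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    if sxx == 0.0:
        raise DegeneratePredictorError("zero variance in d18O; cannot fit a slope")
    beta1 = np.sum((x - xbar) * (y - ybar)) / sxx
    beta0 = ybar - beta1 * xbar
    resid = y - (beta0 + beta1 * x)
    dof = n - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    se_beta1 = residual_sd / np.sqrt(sxx)
    se_beta0 = residual_sd * np.sqrt(1.0 / n + xbar**2 / sxx)
    return float(beta0), float(beta1), residual_sd, float(se_beta0), float(se_beta1)


def fit_background_line(
    samples: pd.DataFrame,
    species: str,
    site: Optional[str] = None,
) -> BackgroundLine:
    """Fit the natural-abundance δ¹⁸O→δ²H line for one species.

    Parameters
    ----------
    samples
        Frame with columns ``species, site, d2H, d18O, is_labelled``; only
        rows with ``is_labelled == False`` and matching species (and site,
        if ``site`` is given) enter the fit.
    species
        Species whose line to fit.
    site
        If given, restrict to that site; by default the fit pools both
        sites and all natural-abundance campaigns.
    """
    sel = (~samples["is_labelled"].astype(bool)) & (samples["species"] == species)
    if site is not None:
        sel &= samples["site"] == site
    sub = samples.loc[sel]
    if len(sub) < 3:
        raise InsufficientDataError(
            f"need >= 3 natural-abundance samples for {species}"
            + (f" at {site}" if site else "")
            + f"; got {len(sub)}"
        )
    x = sub["d18O"].to_numpy(dtype=float)
    y = sub["d2H"].to_numpy(dtype=float)
    beta0, beta1, residual_sd, se_beta0, se_beta1 = _ols_line(x, y)
    return BackgroundLine(
        species=species,
        beta0=beta0,
        beta1=beta1,
        n=len(sub),
        residual_sd=residual_sd,
        se_beta0=se_beta0,
        se_beta1=se_beta1,
        site=site,
    )


def fit_background_lines(
    samples: pd.DataFrame, line_scope: str = "species"
) -> dict:
    """Fit background lines for every species (optionally per site).

    ``line_scope`` is ``"species"`` (pooled across sites, the default) or
    ``"species_site"``. Returns a dict keyed by species (or
    ``(species, site)`` tuples).
    """
    if line_scope not in ("species", "species_site"):
        raise ValueError(f"unknown line_scope {line_scope!r}")
    nat = samples.loc[~samples["is_labelled"].astype(bool)]
    lines: dict = {}
    if line_scope == "species":
        for sp in sorted(nat["species"].unique()):
            lines[sp] = fit_background_line(samples, sp)
    else:
        for sp in sorted(nat["species"].unique()):
            for st in sorted(nat.loc[nat["species"] == sp, "site"].unique()):
                lines[(sp, st)] = fit_background_line(samples, sp, site=st)
    return lines


def predict_background_d2h(line: BackgroundLine, d18O_sample):
    """Predicted natural-abundance δ²H for a sample's measured δ¹⁸O."""
    d18O_sample = np.asarray(d18O_sample, dtype=float)
    out = line.beta0 + line.beta1 * d18O_sample
    return out if out.ndim else float(out)


def label_uptake_percent(
    d2H_sample,
    d18O_sample,
    line: BackgroundLine,
    label: LabelSpec = LabelSpec(),
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
):
    """Short-term uptake of labelled water (%) for labelled samples.

    Computes the three atom% terms (sample, predicted background, label)
    and returns the excess of the sample over background normalised by
    the label excess. The result is *not* clipped: small negative values
    arise from instrument noise and carry information about the noise
    floor; values outside [−5, 105] should be flagged downstream.

    Raises
    ------
    IllConditionedLabelError
        If the label δ²H does not exceed the predicted background by at
        least ``label.guard_permil`` (denominator too close to zero).
    """
    d2H_sample = np.asarray(d2H_sample, dtype=float)
    bg_d2h = predict_background_d2h(line, d18O_sample)
    if np.any(label.d2H_label < np.asarray(bg_d2h) + label.guard_permil):
        raise IllConditionedLabelError(
            f"label d2H = {label.d2H_label}‰ does not exceed the predicted "
            f"background by the guard of {label.guard_permil}‰ "
            f"(species {line.species})"
        )
    ap_sample = delta_to_atom_percent(d2H_sample, constants.r_standard_2h)
    ap_bg = delta_to_atom_percent(bg_d2h, constants.r_standard_2h)
    ap_label = delta_to_atom_percent(label.d2H_label, constants.r_standard_2h)
    out = (ap_sample - ap_bg) / (ap_label - ap_bg) * 100.0
    return out if np.ndim(out) else float(out)


def uptake_table(
    isotopes: pd.DataFrame,
    lines: dict,
    label: LabelSpec = LabelSpec(),
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
    line_scope: str = "species",
) -> pd.DataFrame:
    """Apply the uptake calculation to every labelled sample of a campaign table.

    Returns the labelled rows of ``isotopes`` augmented with the predicted
    background, the three atom% terms, ``uptake_pct`` and a ``qc_flag``
    column ("ok" or "outside_range" for uptake outside [−5, 105]).

    Twig-tissue samples reuse the bud background line of the same species:
    their natural-abundance δ¹⁸O–δ²H slope is indistinguishable from the
    bud slope, and only buds were sampled in the background campaigns.
    """
    lab = isotopes.loc[isotopes["is_labelled"].astype(bool)].copy()
    if lab.empty:
        raise ValueError("no labelled samples in the input table")

    def _line_for(row) -> BackgroundLine:
        key = row["species"] if line_scope == "species" else (row["species"], row["site"])
        try:
            return lines[key]
        except KeyError:
            raise KeyError(
                f"no background line available for {key!r} "
                f"(sample {row['sample_id']})"
            ) from None

    bg = np.empty(len(lab))
    for i, (_, row) in enumerate(lab.iterrows()):
        bg[i] = predict_background_d2h(_line_for(row), row["d18O"])
    if np.any(label.d2H_label < bg + label.guard_permil):
        bad = lab.loc[label.d2H_label < bg + label.guard_permil, "sample_id"].tolist()
        raise IllConditionedLabelError(
            f"label too close to predicted background for samples {bad[:5]}"
        )
    ap_sample = delta_to_atom_percent(lab["d2H"].to_numpy(), constants.r_standard_2h)
    ap_bg = delta_to_atom_percent(bg, constants.r_standard_2h)
    ap_label = delta_to_atom_percent(label.d2H_label, constants.r_standard_2h)
    uptake = (ap_sample - ap_bg) / (ap_label - ap_bg) * 100.0

    lab["d2H_background_permil"] = bg
    lab["atom_pct_sample"] = ap_sample
    lab["atom_pct_background"] = ap_bg
    lab["atom_pct_label"] = ap_label
    lab["uptake_pct"] = uptake
    lab["qc_flag"] = np.where(
        (uptake < -5.0) | (uptake > 105.0), "outside_range", "ok"
    )
    return lab


def line_vs_gmwl(
    line: BackgroundLine, constants: IsotopeConstants = DEFAULT_CONSTANTS
) -> dict:
    """Compare a background line's slope with the global meteoric water line.

    A slope significantly below 8 (``beta1 + 2·se`` still under the GMWL
    slope) indicates evaporative (Rayleigh) enrichment of the bud water
    pool: ¹⁸O accumulates faster than ²H when water evaporates through
    the cuticle.
    """
    deficit = constants.gmwl_slope - line.beta1
    flag = bool(line.beta1 + 2.0 * line.se_beta1 < constants.gmwl_slope)
    return {
        "species": line.species,
        "slope_deficit": float(deficit),
        "evaporative_flag": flag,
    }
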