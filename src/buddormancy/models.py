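"""Statistical models linking the dormancy proxies to campaign structure.

Four response models are fitted to the campaign data, mirroring the
analysis design of the twig-cutting assay:

* **budburst success** — per-twig binomial counts (buds at ≥ stage 2 out
  of total buds) on a logit link, with sampling date continuous,
  species, site, all two-way interactions, and donor tree as the
  grouping unit; evaluated with a type II ANOVA;
* **dormancy depth** — ln(thermal time to budburst) with a second-order
  date polynomial (both orders interacting with species and site),
  restricted to campaigns after the first frost; type III ANOVA;
* **bud water content** and **short-term water uptake** — Gaussian
  models with sampling campaign as a categorical factor; type III ANOVA.

Gaussian responses are fitted as linear mixed models with a random
intercept per donor tree (statsmodels MixedLM); the binomial model and
any non-convergent Gaussian fit use a fixed-effects fit with
cluster-robust covariance by tree — same fixed-effect contrasts, robust
to the within-tree correlation the random intercept would absorb. ANOVA
tables are Wald chi-square tests on sum-coded coefficient blocks
(type III) or on marginality-respecting refits (type II). Post-hoc
comparisons are Tukey-adjusted contrasts of estimated marginal means.

The module also provides the campaign-filtered per-species Pearson
correlations between the four proxies and the endodormancy-onset
detector on campaign-mean uptake trajectories.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import Design, Factor, term_contains

__all__ = [
    "DormancyResults",
    "BudburstSuccessModel",
    "DormancyDepthModel",
    "CampaignResponseModel",
    "fit_success_model",
    "fit_dormancy_depth_model",
    "fit_campaign_model",
    "tukey_contrasts",
    "build_analysis_table",
    "dormancy_correlations",
    "OnsetEstimate",
    "detect_endodormancy_onset",
]

RESPONSE_VARS = ["success_fraction", "thermal_time_dd", "water_content_pct", "uptake_pct"]


def orthogonal_polynomial(x: np.ndarray, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial basis (without the constant column).

    Columns are mutually orthogonal, orthogonal to the intercept and
    scaled to unit norm, like R's ``poly()``; keeps quadratic date terms
    well conditioned.
    """
    x = np.asarray(x, dtype=float)
    X = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, _ = np.linalg.qr(X)
    return Q[:, 1:]


# ----------------------------------------------------------------------
# results object


class DormancyResults:
    """Fitted dormancy model: coefficients, ANOVA, contrasts, diagnostics.

    Not constructed directly — returned by the models' ``fit()``.
    """

    def __init__(
        self,
        model: "_FixedTermsModel",
        params: np.ndarray,
        cov: np.ndarray,
        colnames: List[str],
        slices: Dict[str, np.ndarray],
        converged: bool,
        used_fallback: bool,
        random_effect_var: float,
        df_resid: float,
    ):
        self.model = model
        self.response = model.response_name
        self.params = np.asarray(params, float)
        self.cov = np.asarray(cov, float)
        self.colnames = colnames
        self.slices = slices
        self.converged = converged
        self.used_fallback = used_fallback
        self.random_effect_var = random_effect_var
        self.df_resid = float(df_resid)
        self.nobs = len(model.data)

    # -- coefficient table ------------------------------------------------
    @property
    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        z = np.divide(self.params, se, out=np.full_like(self.params, np.nan), where=se > 0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"term": self.colnames, "estimate": self.params, "se": se, "z": z, "p": p}
        )

    # -- ANOVA ------------------------------------------------------------
    def _wald_block(self, params: np.ndarray, cov: np.ndarray, idx: np.ndarray):
        b = params[idx]
        V = cov[np.ix_(idx, idx)]
        Vinv = np.linalg.pinv(V)
        chi2 = float(b @ Vinv @ b)
        df = int(np.linalg.matrix_rank(V))
        return chi2, df, float(stats.chi2.sf(chi2, df))

    def anova(self, typ: Optional[str] = None) -> pd.DataFrame:
        """Wald chi-square ANOVA table (type II or III).

        Type III tests each term's sum-coded block in the full model.
        Type II refits, for each term, the model without any higher-order
        term containing it and tests the term there (marginality rule).
        """
        typ = typ or self.model.default_anova_type
        if typ not in ("II", "III"):
            raise ValueError("anova type must be 'II' or 'III'")
        rows = []
        if typ == "III":
            chi2, df, p = self._wald_block(self.params, self.cov, self.slices["Intercept"])
            rows.append(("(Intercept)", chi2, df, p))
            for t in self.model.terms:
                chi2, df, p = self._wald_block(self.params, self.cov, self.slices[t])
                rows.append((t, chi2, df, p))
        else:
            rows.append(("(Intercept)", np.nan, np.nan, np.nan))
            for t in self.model.terms:
                keep = [s for s in self.model.terms if not term_contains(s, t)]
                fit = self.model._fit_terms(keep)
                chi2, df, p = self._wald_block(fit["params"], fit["cov"], fit["slices"][t])
                rows.append((t, chi2, df, p))
        out = pd.DataFrame(rows, columns=["term", "chisq", "df", "p"])
        out["anova_type"] = typ
        return out

    # -- Tukey HSD on estimated marginal means ----------------------------
    def tukey(self, factor: str) -> pd.DataFrame:
        """All pairwise contrasts of a factor's estimated marginal means.

        P-values are family-wise adjusted with the studentized-range
        (Tukey HSD) distribution; for a two-level factor the adjusted
        p equals the unadjusted one.
        """
        if factor not in self.model.design.factors or not self.model.design.factors[
            factor
        ].is_categorical:
            raise ValueError(f"{factor!r} is not a categorical factor of this model")
        L, levels = self.model.design.emm_rows(self.model.data, factor, self.model.terms)
        est = L @ self.params
        V = L @ self.cov @ L.T
        k = len(levels)
        df = min(max(self.df_resid, 2.0), 1e4)
        rows = []
        for i, j in itertools.combinations(range(k), 2):
            diff = est[i] - est[j]
            se = float(np.sqrt(V[i, i] + V[j, j] - 2 * V[i, j]))
            tval = diff / se if se > 0 else np.nan
            p_adj = float(stats.studentized_range.sf(abs(tval) * np.sqrt(2.0), k, df))
            rows.append((f"{levels[i]} - {levels[j]}", diff, se, tval, p_adj))
        return pd.DataFrame(rows, columns=["contrast", "estimate", "se", "t", "p_adj"])

    def emmeans(self, factor: str) -> pd.DataFrame:
        """Estimated marginal means of a factor on the linear-predictor scale."""
        L, levels = self.model.design.emm_rows(self.model.data, factor, self.model.terms)
        est = L @ self.params
        se = np.sqrt(np.diag(L @ self.cov @ L.T))
        return pd.DataFrame({"level": levels, "emmean": est, "se": se})

    # -- summary -----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"Dormancy model: {self.response}",
            f"  n = {self.nobs}, backend = "
            + ("fixed-effects + cluster-robust (tree)" if self.used_fallback else "mixed (random tree intercept)"),
            f"  converged = {self.converged}, random tree variance = "
            + (f"{self.random_effect_var:.4g}" if np.isfinite(self.random_effect_var) else "n/a"),
            "",
            f"Type {self.model.default_anova_type} Wald ANOVA",
            self.anova().to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            "Coefficients (sum coding)",
            self.coef_table.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


# ----------------------------------------------------------------------
# model classes


class _FixedTermsModel:
    """Shared machinery: design building, fitting, refitting for type II."""

    response_name = "response"
    default_anova_type = "III"

    def __init__(self, data: pd.DataFrame, design: Design, terms: List[str], group_col: str):
        self.data = data.reset_index(drop=True)
        self.design = design
        self.terms = terms
        self.group_col = group_col
        self.groups = pd.factorize(self.data[group_col])[0]

    def _fit_terms(self, terms: Sequence[str]) -> dict:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self) -> DormancyResults:
        info = self._fit_terms(self.terms)
        return DormancyResults(
            model=self,
            params=info["params"],
            cov=info["cov"],
            colnames=info["colnames"],
            slices=info["slices"],
            converged=info["converged"],
            used_fallback=info["used_fallback"],
            random_effect_var=info["re_var"],
            df_resid=info["df_resid"],
        )


class BudburstSuccessModel(_FixedTermsModel):
    """Binomial (logit) model of budburst success.

    One row per forced twig with ``n_buds_ge_stage2`` successes out of
    ``n_buds_total``; sampling date enters as a continuous covariate in
    units of 30 days since the first campaign. Fitted as a binomial GLM
    on the per-twig proportions with binomial weights and
    cluster-robust covariance by donor tree.
    """

    response_name = "budburst_success"
    default_anova_type = "II"

    def __init__(self, outcomes: pd.DataFrame, group_col: str = "tree_id"):
        data = outcomes.copy().reset_index(drop=True)
        for col in ("n_buds_total", "n_buds_ge_stage2", "campaign_date", "species", "site"):
            if col not in data.columns:
                raise ValueError(f"success model input lacks column {col!r}")
        if (data["n_buds_total"] < 1).any():
            raise ValueError("every twig needs n_buds_total >= 1")
        data["campaign_date"] = pd.to_datetime(data["campaign_date"])
        t0 = data["campaign_date"].min()
        data["date_scaled"] = (data["campaign_date"] - t0).dt.days / 30.0
        design = Design(
            factors=[
                Factor("date", columns=["date_scaled"]),
                Factor("species", levels=sorted(data["species"].unique())),
                Factor("site", levels=sorted(data["site"].unique())),
            ],
            terms=[],
        )
        terms = ["date", "species", "site", "date:species", "date:site", "species:site"]
        design.terms = terms
        for f in (design.factors["species"], design.factors["site"]):
            if len(f.levels) < 2:
                raise ValueError(f"factor {f.name} needs >= 2 levels")
        super().__init__(data, design, terms, group_col)

    def _fit_terms(self, terms: Sequence[str]) -> dict:
        X, slices, colnames = self.design.build(self.data, terms)
        endog = (self.data["n_buds_ge_stage2"] / self.data["n_buds_total"]).to_numpy()
        weights = self.data["n_buds_total"].to_numpy(dtype=float)
        glm = sm.GLM(endog, X, family=sm.families.Binomial(), var_weights=weights)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = glm.fit(cov_type="cluster", cov_kwds={"groups": self.groups})
            except Exception as exc:  # rank deficiency / separation
                raise ValueError(
                    f"binomial fit failed for terms {list(terms)}: {exc}"
                ) from exc
        if not np.all(np.isfinite(res.params)):
            raise ValueError("binomial fit produced non-finite coefficients (separation?)")
        return {
            "params": np.asarray(res.params),
            "cov": np.asarray(res.cov_params()),
            "colnames": colnames,
            "slices": slices,
            "converged": bool(res.converged) if hasattr(res, "converged") else True,
            "used_fallback": True,  # fixed effects + cluster-robust by design
            "re_var": np.nan,
            "df_resid": len(np.unique(self.groups)) - 1,
        }


class _GaussianMixedModel(_FixedTermsModel):
    """Gaussian response, random tree intercept, OLS+cluster-robust fallback."""

    def __init__(self, data, design, terms, group_col, response_col):
        self.response_col = response_col
        super().__init__(data, design, terms, group_col)

    def _fit_terms(self, terms: Sequence[str]) -> dict:
        X, slices, colnames = self.design.build(self.data, terms)
        y = self.data[self.response_col].to_numpy(dtype=float)
        k = X.shape[1]
        converged, used_fallback, re_var = False, False, np.nan
        params = cov = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MixedLM(y, X, groups=self.groups).fit(reml=True, maxiter=200)
                if res.converged and np.all(np.isfinite(np.asarray(res.fe_params))):
                    params = np.asarray(res.fe_params)
                    cov = np.asarray(res.cov_params())[:k, :k]
                    re_var = float(np.asarray(res.cov_re)[0, 0])
                    converged = True
            except Exception:
                pass
        if params is None or not np.all(np.isfinite(np.sqrt(np.abs(np.diag(cov))))):
            ols = sm.OLS(y, X).fit()
            res = ols.get_robustcov_results(cov_type="cluster", groups=self.groups)
            params = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
            used_fallback, converged = True, True
        return {
            "params": params,
            "cov": cov,
            "colnames": colnames,
            "slices": slices,
            "converged": converged,
            "used_fallback": used_fallback,
            "re_var": re_var,
            "df_resid": len(y) - k,
        }


class DormancyDepthModel(_GaussianMixedModel):
    """ln(thermal time to budburst) with a quadratic date trend.

    Restricted to uncensored twigs from campaigns on/after ``after_date``
    (the first frost by default): before frost the thermal-time patterns
    are non-linear and inconsistent across species. Both polynomial
    orders interact with species and site; type III ANOVA.
    """

    response_name = "dormancy_depth"
    default_anova_type = "III"

    def __init__(
        self,
        outcomes: pd.DataFrame,
        after_date: "str | pd.Timestamp",
        group_col: str = "tree_id",
    ):
        data = outcomes.copy()
        data["campaign_date"] = pd.to_datetime(data["campaign_date"])
        data = data.loc[
            (~data["censored"].astype(bool))
            & (data["campaign_date"] >= pd.Timestamp(after_date))
        ].reset_index(drop=True)
        if data["campaign_date"].nunique() <= 1:
            raise ValueError(
                "dormancy-depth model needs more than one campaign after the filter date"
            )
        if (data["thermal_time_dd"] <= 0).any():
            # day-0 budburst gives thermal time 0; shift by half a
            # monitoring interval so the log is defined
            data.loc[data["thermal_time_dd"] <= 0, "thermal_time_dd"] = 0.5 * 20.0
        data["log_thermal_time"] = np.log(data["thermal_time_dd"].to_numpy(dtype=float))
        t = (data["campaign_date"] - data["campaign_date"].min()).dt.days.to_numpy(float)
        P = orthogonal_polynomial(t, 2)
        data["date_p1"], data["date_p2"] = P[:, 0], P[:, 1]
        design = Design(
            factors=[
                Factor("date", columns=["date_p1", "date_p2"]),
                Factor("species", levels=sorted(data["species"].unique())),
                Factor("site", levels=sorted(data["site"].unique())),
            ],
            terms=[],
        )
        terms = ["date", "species", "site", "date:species", "date:site", "species:site"]
        design.terms = terms
        super().__init__(data, design, terms, group_col, "log_thermal_time")


class CampaignResponseModel(_GaussianMixedModel):
    """Gaussian model with sampling campaign as a categorical factor.

    For bud water content and short-term uptake the seasonal course is
    strongly non-linear, so each campaign gets its own level and the
    per-campaign contrasts come from Tukey comparisons. Type III ANOVA.
    """

    response_name = "campaign_response"
    default_anova_type = "III"

    def __init__(
        self,
        samples: pd.DataFrame,
        response: str,
        group_col: str = "tree_id",
    ):
        if response not in ("water_content_pct", "uptake_pct"):
            raise ValueError("response must be 'water_content_pct' or 'uptake_pct'")
        data = samples.dropna(subset=[response]).copy().reset_index(drop=True)
        if data["campaign_index"].nunique() < 2:
            raise ValueError("campaign model needs >= 2 campaigns with data")
        data["campaign"] = data["campaign_index"].astype(int).astype(str)
        camp_levels = [str(i) for i in sorted(data["campaign_index"].astype(int).unique())]
        cell = data.groupby(["campaign", "species"]).size()
        full = len(camp_levels) * data["species"].nunique()
        if len(cell) < full:
            warnings.warn(
                f"{full - len(cell)} empty campaign x species cell(s); "
                "their interaction contrasts are not estimable"
            )
        design = Design(
            factors=[
                Factor("campaign", levels=camp_levels),
                Factor("species", levels=sorted(data["species"].unique())),
                Factor("site", levels=sorted(data["site"].unique())),
            ],
            terms=[],
        )
        terms = [
            "campaign",
            "species",
            "site",
            "campaign:species",
            "campaign:site",
            "species:site",
        ]
        design.terms = terms
        self.response_name = response
        super().__init__(data, design, terms, group_col, response)


# ----------------------------------------------------------------------
# functional wrappers


def fit_success_model(table: pd.DataFrame) -> DormancyResults:
    """Fit the binomial budburst-success model (type II ANOVA)."""
    return BudburstSuccessModel(table).fit()


def fit_dormancy_depth_model(table: pd.DataFrame, after_date) -> DormancyResults:
    """Fit the ln-thermal-time model restricted to campaigns after ``after_date``."""
    return DormancyDepthModel(table, after_date).fit()


def fit_campaign_model(table: pd.DataFrame, response: str) -> DormancyResults:
    """Fit the categorical-campaign model for water content or uptake."""
    col = {"water_content": "water_content_pct", "uptake": "uptake_pct"}.get(
        response, response
    )
    return CampaignResponseModel(table, col).fit()


def tukey_contrasts(result: DormancyResults, factor: str) -> pd.DataFrame:
    """Tukey-HSD adjusted pairwise contrasts of a fitted model's factor."""
    return result.tukey(factor)


# ----------------------------------------------------------------------
# analysis table and correlations


def assign_campaign_index(dates: pd.Series) -> pd.Series:
    """1-based chronological campaign index for a date column."""
    d = pd.to_datetime(dates)
    order = {ts: i + 1 for i, ts in enumerate(sorted(d.unique()))}
    return d.map(order).astype(int)


def build_analysis_table(
    outcomes: pd.DataFrame,
    uptake: pd.DataFrame,
    water: pd.DataFrame,
    level: str = "tree",
) -> pd.DataFrame:
    """Join the four dormancy proxies at the tree × campaign level.

    ``outcomes`` is per forced twig, ``uptake`` and ``water`` are per
    labelled bud sample (twig-tissue rows are ignored here). Twig-level
    responses are averaged per donor tree and campaign before joining —
    the level at which the proxies are paired for correlations. With
    ``level="twig"`` the per-twig/per-sample rows are kept and joined on
    tree × campaign instead.
    """
    keys = ["species", "site", "tree_id", "campaign_date"]
    oc = outcomes.copy()
    oc["campaign_date"] = pd.to_datetime(oc["campaign_date"])
    up = uptake.loc[uptake.get("tissue", "bud") == "bud"].copy()
    up["campaign_date"] = pd.to_datetime(up["campaign_date"])
    wc = water.copy()
    wc["campaign_date"] = pd.to_datetime(wc["campaign_date"])

    if level == "tree":
        oc_a = (
            oc.groupby(keys, as_index=False)
            .agg(
                success_fraction=("success_fraction", "mean"),
                thermal_time_dd=("thermal_time_dd", "mean"),
            )
        )
        up_a = up.groupby(keys, as_index=False).agg(uptake_pct=("uptake_pct", "mean"))
        wc_a = wc.groupby(keys, as_index=False).agg(
            water_content_pct=("water_content_pct", "mean")
        )
    elif level == "twig":
        oc_a = oc[keys + ["success_fraction", "thermal_time_dd"]]
        up_a = up[keys + ["uptake_pct"]]
        wc_a = wc[keys + ["water_content_pct"]]
    else:
        raise ValueError("level must be 'tree' or 'twig'")

    tab = oc_a.merge(up_a, on=keys, how="outer").merge(wc_a, on=keys, how="outer")
    tab["campaign_index"] = assign_campaign_index(tab["campaign_date"])
    return tab.sort_values(["species", "site", "tree_id", "campaign_index"]).reset_index(
        drop=True
    )


def dormancy_correlations(
    table: pd.DataFrame,
    exclude_campaigns: Iterable[int] = (),
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Per-species Pearson correlations between the four dormancy proxies.

    ``table`` is the tree × campaign analysis table. Campaign indices in
    ``exclude_campaigns`` (e.g. the leaf-senescence campaigns 1–3) are
    dropped first. Pairs with fewer than ``min_pairs`` complete
    observations are marked not computable rather than silently dropped.
    """
    excl = set(int(c) for c in exclude_campaigns)
    sub = table.loc[~table["campaign_index"].isin(excl)]
    rows = []
    for sp in sorted(table["species"].unique()):
        grp = sub.loc[sub["species"] == sp]
        for vx, vy in itertools.combinations(RESPONSE_VARS, 2):
            pair = grp[[vx, vy]].dropna()
            if len(pair) < min_pairs:
                rows.append((sp, vx, vy, np.nan, np.nan, len(pair), False))
                continue
            r, p = stats.pearsonr(pair[vx], pair[vy])
            rows.append((sp, vx, vy, float(r), float(p), len(pair), True))
    return pd.DataFrame(
        rows, columns=["species", "var_x", "var_y", "r", "p", "n", "computable"]
    )


# ----------------------------------------------------------------------
# endodormancy onset


@dataclass
class OnsetEstimate:
    """Detected endodormancy onset on a campaign-mean uptake trajectory."""

    species: str
    scope: str  # e.g. "pooled" or a site name
    onset_campaign_index: Optional[int]
    peak_campaign_index: int
    peak_uptake_pct: float
    post_drop_mean_pct: float
    threshold_fraction: float
    detected: bool


def detect_endodormancy_onset(
    means: "pd.Series | Dict[int, float]",
    threshold_fraction: float = 0.1,
    species: str = "",
    scope: str = "pooled",
    peak_window: Optional[Tuple[int, int]] = None,
) -> OnsetEstimate:
    """Locate the collapse of short-term water uptake after its autumn peak.

    ``means`` maps campaign index to the campaign-mean uptake (%). The
    peak is the maximum mean (optionally restricted to a window of
    campaign indices covering autumn); the onset is the first campaign
    after the peak whose mean falls below ``threshold_fraction × peak``
    *and stays below it at the following campaign* (persistence rule,
    guarding against single noisy dips). Invariant under uniform
    rescaling of the trajectory.
    """
    s = pd.Series(dict(means)) if not isinstance(means, pd.Series) else means.copy()
    s = s.sort_index()
    if len(s) < 4:
        raise ValueError("need >= 4 campaign means to detect an onset")
    if not (s > 0).any():
        raise ValueError("all campaign means are <= 0; no uptake signal")
    win = s if peak_window is None else s.loc[peak_window[0] : peak_window[1]]
    peak_idx = int(win.idxmax())
    peak = float(win.max())
    thresh = threshold_fraction * peak
    after = s.loc[s.index > peak_idx]
    onset: Optional[int] = None
    idxs = list(after.index)
    for i, ci in enumerate(idxs[:-1]):
        if after.loc[ci] < thresh and after.loc[idxs[i + 1]] < thresh:
            onset = int(ci)
            break
    post = s.loc[s.index >= onset] if onset is not None else after
    return OnsetEstimate(
        species=species,
        scope=scope,
        onset_campaign_index=onset,
        peak_campaign_index=peak_idx,
        peak_uptake_pct=peak,
        post_drop_mean_pct=float(post.mean()) if len(post) else np.nan,
        threshold_fraction=threshold_fraction,
        detected=onset is not None,
    )
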