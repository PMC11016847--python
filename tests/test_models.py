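"""Statistical stage: response models, ANOVA conventions, contrasts,
correlations and endodormancy-onset detection."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from buddormancy.design import Design, Factor, term_contains
from buddormancy.models import (
    BudburstSuccessModel,
    CampaignResponseModel,
    DormancyDepthModel,
    _GaussianMixedModel,
    build_analysis_table,
    detect_endodormancy_onset,
    dormancy_correlations,
    fit_campaign_model,
    orthogonal_polynomial,
    tukey_contrasts,
)

warnings.filterwarnings("ignore")

SPECIES = ["maple", "hornbeam", "beech", "oak", "lime"]
SITES = ["low", "high"]
DATES = pd.date_range("2019-10-10", periods=12, freq="14D")


def _sigmoid(x):
    return 1 / (1 + np.exp(-x))


def success_table(rng, slope=0.0, species_slopes=None, tree_sd=0.3, n_trees=5):
    """Per-twig binomial success data with a programmed logistic date trend."""
    rows = []
    for sp, site in itertools.product(SPECIES, SITES):
        for tr in range(n_trees):
            tree = f"{site}-{sp}-{tr}"
            eff = rng.normal(0, tree_sd)
            for ci, d in enumerate(DATES):
                b = slope + (species_slopes or {}).get(sp, 0.0)
                p = _sigmoid(-0.5 + b * ci / 11 + eff)
                n = 10
                rows.append(
                    {
                        "twig_id": f"{tree}-{ci}", "tree_id": tree, "species": sp,
                        "site": site, "campaign_date": d,
                        "n_buds_total": n, "n_buds_ge_stage2": rng.binomial(n, p),
                        "success_fraction": np.nan, "censored": False,
                    }
                )
    return pd.DataFrame(rows)


def depth_table(rng, date_slope=0.0, site_offset=0.0, quad=0.0, noise=0.15, n_trees=5):
    """Uncensored ln-thermal-time data with programmed date/site structure."""
    rows = []
    for sp, site in itertools.product(SPECIES, SITES):
        for tr in range(n_trees):
            tree = f"{site}-{sp}-{tr}"
            eff = rng.normal(0, 0.1)
            for ci, d in enumerate(DATES):
                x = ci / 11
                ln_tt = 6.5 + date_slope * x + quad * x**2 + eff
                if site == "high":
                    ln_tt += site_offset
                rows.append(
                    {
                        "twig_id": f"{tree}-{ci}", "tree_id": tree, "species": sp,
                        "site": site, "campaign_date": d, "censored": False,
                        "thermal_time_dd": float(np.exp(ln_tt + rng.normal(0, noise))),
                    }
                )
    return pd.DataFrame(rows)


def campaign_table(rng, step_species=None, step_at=6, step=0.0, n_trees=5, n_campaigns=8):
    rows = []
    for sp, site in itertools.product(SPECIES, SITES):
        for tr in range(n_trees):
            tree = f"{site}-{sp}-{tr}"
            eff = rng.normal(0, 1.0)
            for ci in range(1, n_campaigns + 1):
                val = 45.0 + eff + rng.normal(0, 2.0)
                if sp == step_species and ci >= step_at:
                    val += step
                rows.append(
                    {
                        "tree_id": tree, "species": sp, "site": site,
                        "campaign_index": ci, "water_content_pct": val,
                        "uptake_pct": np.nan,
                    }
                )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------


class TestDesign:
    def test_sum_coding_block_shapes(self):
        data = pd.DataFrame(
            {"a": ["x", "y", "z"] * 4, "b": ["u", "v"] * 6, "c": np.arange(12.0)}
        )
        des = Design(
            [Factor("a", levels=["x", "y", "z"]), Factor("b", levels=["u", "v"]),
             Factor("c", columns=["c"])],
            ["a", "b", "c", "a:b"],
        )
        X, slices, names = des.build(data)
        assert X.shape == (12, 1 + 2 + 1 + 1 + 2)
        # sum coding: each categorical column sums to zero over a balanced cycle
        assert np.allclose(X[:, slices["a"]].sum(axis=0), 0)
        assert np.allclose(X[:, slices["b"]].sum(axis=0), 0)

    def test_term_containment(self):
        assert term_contains("a:b", "a")
        assert not term_contains("a", "a")
        assert not term_contains("a:b", "c")

    def test_orthogonal_polynomial(self):
        x = np.arange(20.0)
        P = orthogonal_polynomial(x, 2)
        G = np.column_stack([np.ones(20), P])
        assert np.allclose(G.T @ G, np.eye(3) * np.diag(G.T @ G), atol=1e-10)


class TestAnovaConventions:
    def test_type2_equals_type3_balanced_no_interactions(self, rng):
        # balanced two-factor grid, main effects only: the two conventions coincide
        data = pd.DataFrame(
            [
                {"g": g, "a": a, "b": b, "y": {"x": 0, "y": 1, "z": 2}[a]
                 + {"u": 0.0, "v": 0.5}[b] + rng.normal(0, 0.5)}
                for g in range(10) for a in "xyz" for b in "uv"
            ]
        )
        data["tree_id"] = data["g"].astype(str)
        des = Design(
            [Factor("a", levels=["x", "y", "z"]), Factor("b", levels=["u", "v"])],
            ["a", "b"],
        )
        m = _GaussianMixedModel(data, des, ["a", "b"], "tree_id", "y")
        m.response_name = "y"
        res = m.fit()
        a2 = res.anova("II").set_index("term")
        a3 = res.anova("III").set_index("term")
        for t in ("a", "b"):
            assert a2.loc[t, "chisq"] == pytest.approx(a3.loc[t, "chisq"], rel=1e-6)

    def test_pvalues_in_unit_interval(self, rng):
        res = BudburstSuccessModel(success_table(rng, slope=1.0)).fit()
        for typ in ("II", "III"):
            an = res.anova(typ)
            ps = an["p"].dropna()
            assert ((ps >= 0) & (ps <= 1)).all()


class TestSuccessModel:
    def test_detects_programmed_date_effect(self, rng):
        hits = 0
        for _ in range(10):
            res = BudburstSuccessModel(success_table(rng, slope=2.0)).fit()
            an = res.anova("II").set_index("term")
            date_row = an.loc["date"]
            coef = res.coef_table.set_index("term").loc["date_scaled", "estimate"]
            if date_row["p"] < 0.05 and coef > 0:
                hits += 1
        assert hits >= 9

    def test_null_data_mostly_quiet(self, rng):
        # identical proportions everywhere: no term should light up
        tab = success_table(rng, slope=0.0, tree_sd=0.0)
        tab["n_buds_ge_stage2"] = 5
        res = BudburstSuccessModel(tab).fit()
        an = res.anova("II").set_index("term")
        coef = res.coef_table.set_index("term").loc["date_scaled", "estimate"]
        assert abs(coef) < 1e-6
        assert (an["p"].dropna() > 0.9).all()

    def test_detects_species_specific_slopes(self, rng):
        hits = 0
        for _ in range(10):
            tab = success_table(rng, slope=1.0, species_slopes={"maple": 2.5, "oak": -1.5})
            res = BudburstSuccessModel(tab).fit()
            p = res.anova("II").set_index("term").loc["date:species", "p"]
            hits += p < 0.05
        assert hits >= 6

    def test_uses_cluster_robust_fallback(self, rng):
        res = BudburstSuccessModel(success_table(rng)).fit()
        assert res.used_fallback


class TestDepthModel:
    def test_linear_trend_quadratic_quiet(self, rng):
        tab = depth_table(rng, date_slope=-1.0)
        res = DormancyDepthModel(tab, after_date="2019-10-01").fit()
        an = res.anova("III").set_index("term")
        assert an.loc["date", "p"] < 0.05
        # second polynomial coefficient itself should be indistinguishable from 0
        coefs = res.coef_table.set_index("term")
        assert coefs.loc["date_p2", "p"] > 0.01

    def test_constant_response_quiet(self, rng):
        tab = depth_table(rng, noise=0.2)
        res = DormancyDepthModel(tab, after_date="2019-10-01").fit()
        an = res.anova("III").set_index("term")
        quiet = an.drop(index="(Intercept)")
        assert (quiet["p"] > 0.01).sum() >= 5  # at most chance-level hits

    def test_detects_site_offset(self, rng):
        tab = depth_table(rng, date_slope=-1.0, site_offset=-0.4)
        res = DormancyDepthModel(tab, after_date="2019-10-01").fit()
        assert res.anova("III").set_index("term").loc["site", "p"] < 0.05

    def test_after_date_filter(self, rng):
        tab = depth_table(rng)
        res = DormancyDepthModel(tab, after_date="2019-12-01").fit()
        assert res.nobs < len(tab)
        with pytest.raises(ValueError, match="more than one campaign"):
            DormancyDepthModel(tab, after_date="2020-06-01")


class TestCampaignModel:
    def test_null_campaign_quiet_and_sites_identical(self, rng):
        res = CampaignResponseModel(campaign_table(rng), "water_content_pct").fit()
        an = res.anova("III").set_index("term")
        assert an.loc["campaign", "p"] > 0.001  # no programmed campaign signal
        assert an.loc["site", "p"] > 0.05

    def test_detects_species_specific_step(self, rng):
        tab = campaign_table(rng, step_species="lime", step=8.0)
        res = CampaignResponseModel(tab, "water_content_pct").fit()
        an = res.anova("III").set_index("term")
        assert an.loc["campaign:species", "p"] < 0.05

    def test_functional_wrapper(self, rng):
        res = fit_campaign_model(campaign_table(rng), "water_content")
        assert res.response == "water_content_pct"

    def test_mixed_backend_reports_tree_variance(self, rng):
        res = CampaignResponseModel(campaign_table(rng), "water_content_pct").fit()
        if not res.used_fallback:
            assert res.random_effect_var > 0.1  # programmed tree sd = 1


class TestTukey:
    def test_two_level_factor_unadjusted(self, rng):
        res = CampaignResponseModel(campaign_table(rng), "water_content_pct").fit()
        tk = tukey_contrasts(res, "site")
        assert len(tk) == 1
        t = float(tk.loc[0, "t"])
        df = min(res.df_resid, 1e4)
        p_unadj = 2 * stats.t.sf(abs(t), df)
        assert tk.loc[0, "p_adj"] == pytest.approx(p_unadj, rel=0.02)

    def test_identical_levels_not_significant(self, rng):
        res = CampaignResponseModel(campaign_table(rng), "water_content_pct").fit()
        tk = tukey_contrasts(res, "species")
        assert len(tk) == 10
        assert (tk["p_adj"] > 0.05).all()

    def test_shifted_level_detected(self, rng):
        tab = campaign_table(rng)
        tab.loc[tab["species"] == "lime", "water_content_pct"] += 10.0  # 5 residual sd
        res = CampaignResponseModel(tab, "water_content_pct").fit()
        tk = tukey_contrasts(res, "species")
        lime = tk[tk["contrast"].str.contains("lime")]
        rest = tk[~tk["contrast"].str.contains("lime")]
        assert (lime["p_adj"] < 0.05).all()
        assert (rest["p_adj"] > 0.05).all()

    def test_absent_factor_errors(self, rng):
        res = CampaignResponseModel(campaign_table(rng), "water_content_pct").fit()
        with pytest.raises(ValueError, match="not a categorical factor"):
            tukey_contrasts(res, "elevation")


class TestCorrelations:
    def _table(self, rng, coupled=True, noise=0.0):
        rows = []
        for sp in SPECIES:
            for site in SITES:
                for tr in range(5):
                    for ci in range(1, 13):
                        tt = 800 - 50 * ci + rng.normal(0, 30)
                        wc = (60 - 0.02 * tt if coupled else rng.normal(50, 5))
                        wc += rng.normal(0, noise)
                        rows.append(
                            {
                                "species": sp, "site": site, "tree_id": f"{site}{sp}{tr}",
                                "campaign_index": ci, "campaign_date": DATES[0],
                                "success_fraction": rng.uniform(0, 1),
                                "thermal_time_dd": tt, "water_content_pct": wc,
                                "uptake_pct": rng.normal(5, 2),
                            }
                        )
        return pd.DataFrame(rows)

    def test_perfect_anticorrelation(self, rng):
        tab = self._table(rng, coupled=True, noise=0.0)
        corr = dormancy_correlations(tab)
        key = corr[(corr.var_x == "thermal_time_dd") & (corr.var_y == "water_content_pct")]
        assert np.allclose(key["r"], -1.0, atol=1e-10)

    def test_matches_pearson_oracle(self, rng):
        tab = self._table(rng, coupled=True, noise=3.0)
        corr = dormancy_correlations(tab)
        grp = tab[tab.species == "beech"]
        x, y = grp["thermal_time_dd"].to_numpy(), grp["water_content_pct"].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
        got = corr[
            (corr.species == "beech")
            & (corr.var_x == "thermal_time_dd")
            & (corr.var_y == "water_content_pct")
        ]["r"].iloc[0]
        assert got == pytest.approx(r_hand, abs=1e-10)

    def test_independent_responses_small_r(self, rng):
        tab = self._table(rng, coupled=False)
        corr = dormancy_correlations(tab)
        key = corr[(corr.var_x == "thermal_time_dd") & (corr.var_y == "water_content_pct")]
        assert (key["r"].abs() < 0.3).all()

    def test_exclusion_and_insufficient_pairs(self, rng):
        tab = self._table(rng)
        corr = dormancy_correlations(tab, exclude_campaigns={1, 2, 3})
        assert (corr["n"] == 90).all()  # 120 tree-campaign pairs minus 3 campaigns
        tiny = tab[tab.campaign_index <= 1]
        corr2 = dormancy_correlations(tiny, exclude_campaigns={1})
        assert (~corr2["computable"]).all()
        assert len(corr2) > 0  # marked, not dropped

    def test_senescence_peak_exclusion_attenuates(self, rng):
        # uptake has a senescence peak in campaigns 2-3 while depth is high:
        # the apparent uptake-depth coupling weakens once those are excluded
        tab = self._table(rng, coupled=True, noise=1.0)
        peak = tab["campaign_index"].isin([2, 3])
        tab.loc[peak, "uptake_pct"] += 30.0
        full = dormancy_correlations(tab)
        filt = dormancy_correlations(tab, exclude_campaigns={1, 2, 3})
        sel = lambda c: c[
            (c.var_x == "thermal_time_dd") & (c.var_y == "uptake_pct")
        ].set_index("species")["r"]
        assert (sel(filt).abs() < sel(full).abs()).all()


class TestOnsetDetection:
    def test_constructed_step(self):
        est = detect_endodormancy_onset(
            pd.Series({1: 0.0, 2: 8.0, 3: 9.0, 4: 0.3, 5: 0.2, 6: 0.2}),
            threshold_fraction=0.1,
        )
        assert est.onset_campaign_index == 4
        assert est.peak_campaign_index == 3
        assert est.detected

    def test_monotone_increasing_absent(self):
        est = detect_endodormancy_onset(pd.Series({1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0}))
        assert est.onset_campaign_index is None and not est.detected

    def test_single_dip_rejected_by_persistence(self):
        est = detect_endodormancy_onset(
            pd.Series({1: 1.0, 2: 9.0, 3: 0.2, 4: 5.0, 5: 0.3, 6: 0.1})
        )
        assert est.onset_campaign_index == 5

    def test_rescaling_invariance(self):
        s = pd.Series({1: 0.5, 2: 8.0, 3: 7.0, 4: 0.4, 5: 0.3, 6: 0.2})
        a = detect_endodormancy_onset(s)
        b = detect_endodormancy_onset(s * 137.0)
        assert a.onset_campaign_index == b.onset_campaign_index

    def test_errors(self):
        with pytest.raises(ValueError, match=">= 4"):
            detect_endodormancy_onset(pd.Series({1: 1.0, 2: 0.1, 3: 0.1}))
        with pytest.raises(ValueError, match="uptake signal"):
            detect_endodormancy_onset(pd.Series({1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}))

    def test_noisy_recovery_rate(self):
        # programmed collapse at campaign 4, per-sample noise sd = 10% of peak,
        # 10 trees per campaign mean
        rng = np.random.default_rng(77)
        traj = np.array([2.0, 35.0, 30.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        hits = 0
        for _ in range(50):
            draws = traj[None, :] + rng.normal(0, 3.5, size=(10, 10))
            means = pd.Series(np.clip(draws, 0, None).mean(axis=0),
                              index=range(1, 11))
            est = detect_endodormancy_onset(means, threshold_fraction=0.1)
            hits += est.onset_campaign_index == 4
        assert hits >= 45


class TestAnalysisTable:
    def test_build_from_bundle(self, default_bundle):
        from buddormancy.isotope import fit_background_lines, uptake_table
        from buddormancy.phenology import bud_water_content, outcomes_table

        iso = default_bundle["isotopes"].rename(
            columns={"d2H_permil": "d2H", "d18O_permil": "d18O"}
        )
        oc = outcomes_table(default_bundle["phenology"])
        up = uptake_table(iso, fit_background_lines(iso))
        wc = default_bundle["mass"].merge(
            iso[["sample_id", "species", "site", "tree_id", "campaign_date"]],
            on="sample_id",
        )
        wc["water_content_pct"] = bud_water_content(wc["fresh_mass_mg"], wc["dry_mass_mg"])
        tab = build_analysis_table(oc, up, wc)
        assert tab["campaign_index"].between(1, 15).all()
        # 2 sites x 5 species x 5 trees x 15 campaigns
        assert len(tab) == 750
        assert not tab.duplicated(["tree_id", "campaign_index"]).any()
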