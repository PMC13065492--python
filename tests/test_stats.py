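import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pathfractal import (
    InsufficientDataError,
    ParameterError,
    aic_model_selection,
    akaike_weights,
    fit_random_intercept_model,
    levene_test,
    manova_pillai,
    oneway_anova,
    pca_fdi,
    pearson_matrix,
    rda_traits,
    tukey_hsd,
)
from pathfractal.stats import CANDIDATE_FORMULAS


def sim_table(n=120, seed=0, treat_effect=0.0, site_sd=0.0, n_sites=4):
    """Small Gaussian specimen table with a known treatment effect."""
    rng = np.random.default_rng(seed)
    rows = []
    u = rng.normal(0, site_sd, n_sites)
    for i in range(n):
        trt = ["control", "+5C", "+10C"][i % 3]
        site = i % n_sites
        base = 1.6 + (treat_effect if trt == "+10C" else 0.0)
        rows.append(
            {
                "specimen_id": f"s{i}",
                "family": ["Baetidae", "Leptophlebiidae"][i % 2],
                "microhabitat": ["sand", "boulders", "pebbles"][(i // 3) % 3],
                "treatment": trt,
                "site": f"site{site}",
                "FDIr": base + u[site] + rng.normal(0, 0.1),
                "FDIb": base + u[site] + rng.normal(0, 0.1),
                "FDId": base + u[site] + rng.normal(0, 0.1),
            }
        )
    return pd.DataFrame(rows)


class TestAkaikeWeights:
    @pytest.mark.parametrize(
        "aics,best_weight",
        [
            ([350.004, 357.820, 368.170, 404.393], 0.980),
            ([79.351, 90.256, 96.709, 145.088], 0.995),
            ([9.945, 19.999, 28.081, 97.102], 0.993),
        ],
    )
    def test_published_model_selection_blocks(self, aics, best_weight):
        delta, w = akaike_weights(aics)
        assert delta[0] == 0.0
        # within one unit of the printed precision (the published table's own
        # deltas are rounded inconsistently at the third decimal)
        assert w[0] == pytest.approx(best_weight, abs=1e-3)
        assert w.sum() == pytest.approx(1.0)

    def test_shift_invariance(self):
        a = np.array([10.0, 12.0, 19.0])
        _, w1 = akaike_weights(a)
        _, w2 = akaike_weights(a + 123.4)
        assert np.allclose(w1, w2)

    def test_tied_models_split_evenly(self):
        _, w = akaike_weights([5.0, 5.0])
        assert np.allclose(w, [0.5, 0.5])


class TestLevene:
    def test_identical_groups_no_signal(self):
        v = np.r_[np.arange(10.0), np.arange(10.0)]
        g = np.r_[["a"] * 10, ["b"] * 10]
        w, p = levene_test(v, g)
        assert w == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_tenfold_scale_detected(self):
        rng = np.random.default_rng(1)
        v = np.r_[rng.normal(0, 1, 50), rng.normal(0, 10, 50)]
        g = np.r_[["a"] * 50, ["b"] * 50]
        _, p = levene_test(v, g)
        assert p < 0.01

    def test_tiny_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            levene_test([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestAnova:
    def test_textbook_three_groups(self):
        v = [1, 2, 3, 2, 3, 4, 3, 4, 5]
        g = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = oneway_anova(v, g)
        assert res.F == pytest.approx(3.0)
        assert res.p == pytest.approx(float(sps.f.sf(3.0, 2, 6)))
        assert (res.df_between, res.df_within) == (2, 6)

    def test_zero_within_variance_flagged(self):
        res = oneway_anova([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert res.degenerate

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=30)
        g = np.array(["a", "b", "c"] * 10)
        perm = rng.permutation(30)
        assert oneway_anova(v, g).F == pytest.approx(oneway_anova(v[perm], g[perm]).F)


class TestMixedModel:
    def test_matches_ols_when_no_site_variance(self):
        import statsmodels.formula.api as smf

        df = sim_table(n=120, seed=3, treat_effect=-0.2, site_sd=0.0)
        lmm = fit_random_intercept_model(df, "FDIb", "treatment")
        ols = smf.ols("FDIb ~ treatment", df).fit()
        for term in ols.params.index:
            assert lmm.params[term] == pytest.approx(ols.params[term], abs=2e-3)

    def test_loglik_never_decreases_with_extra_predictor(self):
        df = sim_table(n=120, seed=4, treat_effect=-0.2, site_sd=0.1)
        small = fit_random_intercept_model(df, "FDIb", "treatment")
        big = fit_random_intercept_model(df, "FDIb", "treatment + family")
        assert big.llf >= small.llf - 1e-6

    def test_parameter_count(self):
        df = sim_table(n=60, seed=5)
        null = fit_random_intercept_model(df, "FDIb", "1")
        assert null.k == 3  # intercept + residual var + site var

    def test_recovers_simulated_treatment_effect(self):
        # true +10C effect -0.2; patsy baseline is the "+10C" level, so the
        # control contrast estimates +0.2
        hits = 0
        for seed in range(100):
            df = sim_table(n=270, seed=seed, treat_effect=-0.2, site_sd=0.1)
            f = fit_random_intercept_model(df, "FDIb", "treatment")
            est = f.params["treatment[T.control]"]
            se = f.bse["treatment[T.control]"]
            hits += abs(est - 0.2) <= 2 * se
        assert hits >= 93

    def test_rank_deficient_design_rejected(self):
        df = sim_table(n=30, seed=6)
        df["clone"] = df["treatment"]
        with pytest.raises(ParameterError, match="rank-deficient"):
            fit_random_intercept_model(df, "FDIb", "treatment + clone")

    def test_agrees_with_lme4(self, tmp_path):
        """Independent oracle: same model fit by R's lme4 (ML)."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = sim_table(n=90, seed=7, treat_effect=-0.15, site_sd=0.1)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- lmer(FDIb ~ treatment + (1|site), data=d, REML=FALSE)
                cat(AIC(m), logLik(m), fixef(m)["(Intercept)"], sep="\\n")
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        r_aic, r_llf, r_int = map(float, out.stdout.split())
        f = fit_random_intercept_model(df, "FDIb", "treatment")
        assert f.llf == pytest.approx(r_llf, abs=1e-3)
        assert f.aic == pytest.approx(r_aic, abs=1e-2)
        assert f.params["Intercept"] == pytest.approx(r_int, abs=1e-4)


class TestModelSelection:
    def test_table_structure(self):
        df = sim_table(n=120, seed=8, treat_effect=-0.3, site_sd=0.05)
        tab = aic_model_selection(df, "FDIb", candidates=("1", "treatment",
                                                          "treatment + family"))
        assert tab["delta_aic"].iloc[0] == 0.0
        assert tab["AIC"].is_monotonic_increasing
        assert tab["akaike_weight"].sum() == pytest.approx(1.0)

    def test_strong_effect_beats_null(self):
        df = sim_table(n=150, seed=9, treat_effect=-0.3, site_sd=0.05)
        tab = aic_model_selection(df, "FDIb", candidates=CANDIDATE_FORMULAS)
        assert "treatment" in tab.iloc[0]["fixed_effects"]

    def test_rows_with_missing_response_dropped_once(self):
        df = sim_table(n=90, seed=10)
        df.loc[::7, "FDIb"] = np.nan
        tab = aic_model_selection(df, "FDIb", candidates=("1", "treatment"))
        assert len(tab) == 2


class TestPCA:
    def test_identical_columns_single_axis(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=50)
        df = pd.DataFrame({"specimen_id": range(50), "FDIr": v, "FDIb": v, "FDId": v})
        res = pca_fdi(df)
        assert res.variance_explained[0] == pytest.approx(100.0)

    def test_independent_columns_equal_axes(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {
                "specimen_id": range(3000),
                "FDIr": rng.normal(size=3000),
                "FDIb": rng.normal(size=3000),
                "FDId": rng.normal(size=3000),
            }
        )
        res = pca_fdi(df)
        assert np.all(np.abs(res.variance_explained - 100 / 3) < 5)

    def test_variance_sums_to_100(self):
        df = sim_table(n=60, seed=13)
        res = pca_fdi(df)
        assert res.variance_explained.sum() == pytest.approx(100.0)
        assert np.all(np.diff(res.variance_explained) <= 1e-9)

    def test_dominant_label_and_tie_flag(self):
        df = pd.DataFrame(
            {
                "specimen_id": ["a", "b", "c"],
                "FDIr": [2.0, 1.0, 1.5],
                "FDIb": [1.0, 2.0, 1.5],
                "FDId": [0.5, 0.5, 1.5],
            }
        )
        res = pca_fdi(df)
        assert list(res.groups["dominant_fdi"]) == ["FDIr", "FDIb", "FDIr"]
        assert list(res.groups["tie"]) == [False, False, True]

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame(
            {"specimen_id": range(5), "FDIr": [1.0] * 5,
             "FDIb": np.arange(5.0), "FDId": np.arange(5.0)}
        )
        with pytest.raises(ParameterError):
            pca_fdi(df)

    def test_too_few_rows(self):
        df = pd.DataFrame({"specimen_id": [1, 2], "FDIr": [1, 2],
                           "FDIb": [1, 2], "FDId": [1, 2]})
        with pytest.raises(InsufficientDataError):
            pca_fdi(df)


class TestManova:
    def test_identical_group_means_trace_near_zero(self):
        df = sim_table(n=300, seed=14)
        res = manova_pillai(df, factors=("family",))
        assert res.loc[0, "pillai"] < 0.05

    def test_univariate_limit_equals_anova(self):
        df = sim_table(n=80, seed=15, treat_effect=-0.4)
        res = manova_pillai(df, responses=("FDIb",), factors=("family",))
        an = oneway_anova(df["FDIb"], df["family"])
        assert res.loc[0, "F"] == pytest.approx(an.F, rel=1e-9)
        assert res.loc[0, "p"] == pytest.approx(an.p, rel=1e-9)

    def test_matches_statsmodels_single_factor(self):
        from statsmodels.multivariate.manova import MANOVA

        df = sim_table(n=90, seed=16, treat_effect=-0.2)
        mine = manova_pillai(df, factors=("treatment",))
        sm = MANOVA.from_formula("FDIr + FDIb + FDId ~ treatment", data=df)
        tab = sm.mv_test().results["treatment"]["stat"]
        assert mine.loc[0, "pillai"] == pytest.approx(
            float(tab.loc["Pillai's trace", "Value"]), abs=1e-8
        )
        assert mine.loc[0, "F"] == pytest.approx(
            float(tab.loc["Pillai's trace", "F Value"]), rel=1e-6
        )

    def test_pvalues_in_unit_interval(self):
        df = sim_table(n=120, seed=17, treat_effect=-0.2, site_sd=0.1)
        res = manova_pillai(df)
        assert res["p"].between(0, 1).all()

    def test_single_level_factor_rejected(self):
        df = sim_table(n=30, seed=18)
        df["family"] = "Baetidae"
        with pytest.raises(ParameterError):
            manova_pillai(df, factors=("family",))


class TestTukey:
    def test_identical_groups(self):
        v = np.r_[np.arange(10.0), np.arange(10.0)]
        g = np.r_[["a"] * 10, ["b"] * 10]
        t = tukey_hsd(v, g)
        assert t.loc[0, "diff"] == pytest.approx(0.0)
        assert t.loc[0, "p_adj"] == pytest.approx(1.0)

    def test_intervals_bracket_difference(self):
        rng = np.random.default_rng(19)
        v = rng.normal(size=60)
        g = np.array(["a", "b", "c"] * 20)
        t = tukey_hsd(v, g)
        assert ((t["lwr"] <= t["diff"]) & (t["diff"] <= t["upr"])).all()

    def test_shifted_group_flagged_only_in_its_contrasts(self):
        rng = np.random.default_rng(20)
        v = np.r_[rng.normal(0, 1, 40), rng.normal(0, 1, 40), rng.normal(2, 1, 40)]
        g = np.r_[["a"] * 40, ["b"] * 40, ["c"] * 40]
        t = tukey_hsd(v, g).set_index("comparison")
        assert t.loc["c-a", "p_adj"] < 0.01
        assert t.loc["c-b", "p_adj"] < 0.01
        assert t.loc["b-a", "p_adj"] > 0.05

    def test_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(21)
        v = rng.normal(size=45) + np.repeat([0.0, 0.5, 1.0], 15)
        g = np.repeat(["a", "b", "c"], 15)
        mine = tukey_hsd(v, g).set_index("comparison")
        sm = pairwise_tukeyhsd(v, g)
        for (g1, g2), diff, p in zip(
            [(a, b) for i, a in enumerate("abc") for b in "abc"[i + 1:]],
            sm.meandiffs,
            sm.pvalues,
        ):
            row = mine.loc[f"{g2}-{g1}"]
            assert row["diff"] == pytest.approx(diff, abs=1e-10)
            assert row["p_adj"] == pytest.approx(p, abs=1e-4)


class TestRDA:
    def test_variance_decomposition_identity(self):
        df = sim_table(n=90, seed=22, treat_effect=-0.2)
        res = rda_traits(df, ("FDIr", "FDIb", "FDId"), constraint="family")
        assert res.extras["constrained_pct"] + res.extras[
            "unconstrained_pct"
        ] == pytest.approx(100.0)
        assert res.variance_explained.sum() == pytest.approx(100.0)

    def test_unrelated_constraint_explains_little(self):
        df = sim_table(n=400, seed=23)
        res = rda_traits(df, ("FDIr", "FDIb", "FDId"), constraint="family")
        assert res.extras["constrained_pct"] < 3.0

    def test_perfect_separation_captured_by_first_axis(self):
        rng = np.random.default_rng(24)
        fam = np.repeat(["Baetidae", "Leptophlebiidae"], 40)
        sig = (fam == "Baetidae").astype(float)
        df = pd.DataFrame(
            {
                "family": fam,
                "FDIr": sig + rng.normal(0, 1e-3, 80),
                "FDIb": sig + rng.normal(0, 1e-3, 80),
                "FDId": sig + rng.normal(0, 1e-3, 80),
            }
        )
        res = rda_traits(df, ("FDIr", "FDIb", "FDId"), constraint="family")
        assert res.extras["constrained_pct"] > 99.0
        assert res.variance_explained[0] > 99.0

    def test_single_level_constraint_rejected(self):
        df = sim_table(n=30, seed=25)
        df["family"] = "Baetidae"
        with pytest.raises(ParameterError):
            rda_traits(df, ("FDIr", "FDIb"), constraint="family")


class TestPearson:
    def test_exact_linear_relations(self):
        x = np.arange(20.0)
        df = pd.DataFrame({"x": x, "y2": 2 * x, "yneg": -x})
        cm = pearson_matrix(df, ["x", "y2", "yneg"])
        assert cm.r.loc["x", "y2"] == pytest.approx(1.0)
        assert cm.r.loc["x", "yneg"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(cm.r), 1.0)

    def test_pairwise_complete_counts(self):
        df = pd.DataFrame(
            {"a": [1.0, 2, 3, np.nan, 5], "b": [2.0, 4, np.nan, 8, 10],
             "c": [1.0, 1, 2, 3, 5]}
        )
        cm = pearson_matrix(df, ["a", "b", "c"])
        assert cm.n.loc["a", "b"] == 3
        assert cm.n.loc["a", "c"] == 4

    def test_insufficient_pairs_flagged(self):
        df = pd.DataFrame({"a": [1.0, np.nan, np.nan, 4], "b": [np.nan, 2.0, 3, np.nan]})
        cm = pearson_matrix(df, ["a", "b"])
        assert np.isnan(cm.r.loc["a", "b"])

    def test_independent_normals_small_r(self):
        rng = np.random.default_rng(26)
        hits = 0
        for _ in range(40):
            df = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
            hits += abs(pearson_matrix(df, ["a", "b"]).r.loc["a", "b"]) < 0.1
        assert hits >= 38
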