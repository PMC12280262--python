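"""Mixed-model treatment inference: fits, ANOVA decision rule, contrasts."""

import warnings

import numpy as np
import pandas as pd
import pytest

from microcast import inference as inf

warnings.filterwarnings("ignore", message=".*singular.*")


@pytest.fixture(scope="module")
def dataset():
    return inf.simulate_lmm_dataset(seed=3)


class TestFitLmm:
    def test_zero_variance_components_degenerate_to_ols(self):
        """With all random-effect variances 0 the fixed-effect estimates
        match ordinary least squares."""
        d = inf.simulate_lmm_dataset(sd_taxon=0.0, sd_bottle=0.0,
                                     sd_incubator=0.0, sd_resid=0.3, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = inf.fit_lmm(d, inf.TAXA_ERROR_SPEC)
        import statsmodels.formula.api as smf

        dd, _ = inf.center_column(d, "richness", "bottle_id")
        ols = smf.ols("error ~ richness + light + richness:light", dd).fit()
        for name in ols.params.index:
            assert fit.params[name] == pytest.approx(ols.params[name], abs=1e-5)

    def test_balanced_intercept_equals_grand_mean(self):
        """Balanced groups with pure intercept shifts: the REML intercept of
        an intercept-only model is the grand mean."""
        rng = np.random.default_rng(0)
        rows = []
        for g in range(6):
            shift = rng.normal(0, 0.5)
            for i in range(20):
                rows.append((f"G{g}", 2.0 + shift + rng.normal(0, 0.1)))
        d = pd.DataFrame(rows, columns=["taxon", "error"])
        spec = inf.LMMSpec(response="error", fixed=(),
                           groups=("taxon",), center=None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = inf.fit_lmm(d, spec)
        assert fit.params["Intercept"] == pytest.approx(d["error"].mean(), abs=1e-6)

    def test_response_shift_moves_only_intercept(self, dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = inf.fit_lmm(dataset, inf.TAXA_ERROR_SPEC)
            d2 = dataset.copy()
            d2["error"] = d2["error"] + 10.0
            f2 = inf.fit_lmm(d2, inf.TAXA_ERROR_SPEC)
        # invariance holds up to the optimizer's convergence tolerance
        assert f2.params["Intercept"] == pytest.approx(f1.params["Intercept"] + 10.0,
                                                       abs=5e-3)
        for name in f1.params.index:
            if name != "Intercept":
                assert f2.params[name] == pytest.approx(f1.params[name], abs=5e-3)

    def test_missing_response_rejected(self, dataset):
        d = dataset.copy()
        d.loc[0, "error"] = np.nan
        with pytest.raises(ValueError):
            inf.fit_lmm(d, inf.TAXA_ERROR_SPEC)

    def test_single_level_grouping_rejected(self, dataset):
        d = dataset.copy()
        d["incubator"] = "I1"
        with pytest.raises(ValueError):
            inf.fit_lmm(d, inf.TAXA_ERROR_SPEC)

    def test_parameter_recovery_small(self):
        """Estimates concentrate near the generating coefficients."""
        ests = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(20):
                d = inf.simulate_lmm_dataset(seed=s)
                fit = inf.fit_lmm(d, inf.TAXA_ERROR_SPEC)
                ests.append([fit.params["Intercept"], fit.params["richness"],
                             fit.params["light[T.declining]"],
                             fit.params["richness:light[T.declining]"]])
        mean_est = np.mean(ests, axis=0)
        assert np.allclose(mean_est, inf.DEFAULT_BETA, atol=0.06)


class TestAnovaDecision:
    def test_decision_flag_is_pure_threshold(self):
        assert inf.retain_interaction(0.0999)
        assert not inf.retain_interaction(0.1001)
        assert not inf.retain_interaction(0.1)

    def test_strong_interaction_retained_with_type_iii(self):
        d = inf.simulate_lmm_dataset(beta=(0.7, 0.05, -0.1, -0.5), seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, table = inf.anova_decision(d, inf.TAXA_ERROR_SPEC)
        assert table.interaction_retained
        assert table.type == "III"
        assert "richness:light[T.declining]" in fit.params.index

    def test_null_interaction_usually_dropped(self):
        kept = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(30):
                d = inf.simulate_lmm_dataset(beta=(0.7, 0.05, -0.1, 0.0), seed=s)
                _, table = inf.anova_decision(d, inf.TAXA_ERROR_SPEC)
                kept += table.interaction_retained
        assert kept <= 10  # ~10% expected under the null screen

    def test_reduced_model_reports_type_ii_main_effects(self):
        d = inf.simulate_lmm_dataset(beta=(0.7, 0.3, -0.2, 0.0), seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, table = inf.anova_decision(d, inf.TAXA_ERROR_SPEC)
        if not table.interaction_retained:
            assert table.type == "II"
            assert {r.term for r in table.rows} == {"richness", "C(light, Sum)"}
            assert "richness:light[T.declining]" not in fit.params.index

    def test_spec_without_interaction_rejected(self, dataset):
        spec = inf.LMMSpec(response="error", fixed=("richness", "light"),
                           groups=("taxon", "bottle_id", "incubator"))
        with pytest.raises(ValueError):
            inf.anova_decision(dataset, spec)


class TestSlopesAndPercentChange:
    def test_printed_estimates_reproduce_percent_changes(self):
        """The taxa-abundance model coefficients translate into +5.6% per
        species in constant light and -4.6% in declining light."""
        coefs = {"Intercept": 0.685, "richness": 0.056,
                 "light[T.declining]": -0.095,
                 "richness:light[T.declining]": -0.102}
        out = inf.slopes_and_percent_change(coefs)
        assert out["percent_change_constant"] == pytest.approx(5.6)
        assert out["percent_change_declining"] == pytest.approx(-4.6)

    def test_zero_interaction_gives_equal_slopes(self):
        coefs = {"richness": 0.04, "light[T.declining]": -0.1,
                 "richness:light[T.declining]": 0.0}
        out = inf.slopes_and_percent_change(coefs)
        assert out["slope_constant"] == out["slope_declining"] == 0.04

    def test_works_on_fitted_model(self):
        d = inf.simulate_lmm_dataset(seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = inf.fit_lmm(d, inf.TAXA_ERROR_SPEC)
        out = inf.slopes_and_percent_change(fit)
        assert out["slope_declining"] == pytest.approx(
            fit.params["richness"] + fit.params["richness:light[T.declining]"])


class TestMarginalMeans:
    def test_contrast_at_centered_zero_equals_light_coefficient(self):
        d = inf.simulate_lmm_dataset(seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = inf.fit_lmm(d, inf.TAXA_ERROR_SPEC)
        mm = inf.marginal_means_contrast(fit, at_richness=[0.0])
        assert mm["estimate"][0] == pytest.approx(fit.params["light[T.declining]"])

    def test_no_light_effect_contrasts_cover_zero(self):
        d = inf.simulate_lmm_dataset(beta=(0.7, 0.0, 0.0, 0.0), seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = inf.fit_lmm(d, inf.TAXA_ERROR_SPEC)
        mm = inf.marginal_means_contrast(fit, at_richness=[-1.5, 1.5])
        assert ((mm["ci_lower"] <= 0) & (mm["ci_upper"] >= 0)).all()

    def test_out_of_range_richness_warns(self):
        d = inf.simulate_lmm_dataset(seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = inf.fit_lmm(d, inf.TAXA_ERROR_SPEC)
        with pytest.warns(UserWarning, match="outside"):
            inf.marginal_means_contrast(fit, at_richness=[50.0])


class TestAggregationComparison:
    @staticmethod
    def _aggregation_data(offset, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(30):
            light = "constant" if i < 15 else "declining"
            richness = [4.0, 5.5, 7.0][(i % 15) // 5]
            base = 0.7 + rng.normal(0, 0.05)
            rows.append((f"B{i:02d}", f"I{i % 8 + 1}", light, richness,
                         base, "taxa_mean"))
            rows.append((f"B{i:02d}", f"I{i % 8 + 1}", light, richness,
                         base + offset, "biomass"))
        return pd.DataFrame(rows, columns=["bottle_id", "incubator", "light",
                                           "richness", "error", "aggregation"])

    def _long(self, df):
        return df

    def test_constant_offset_recovered_as_main_effect(self):
        d = self._aggregation_data(offset=0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, table = inf.aggregation_comparison(d)
        agg_terms = [n for n in fit.params.index if "aggregation" in n and ":" not in n]
        assert fit.params[agg_terms[0]] == pytest.approx(-0.3, abs=0.02) or \
            fit.params[agg_terms[0]] == pytest.approx(0.3, abs=0.02)

    def test_identical_levels_give_zero_effect(self):
        d = self._aggregation_data(offset=0.0, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, table = inf.aggregation_comparison(d)
        agg_terms = [n for n in fit.params.index if "aggregation" in n and ":" not in n]
        assert abs(fit.params[agg_terms[0]]) < 0.02

    def test_single_level_rejected(self):
        d = self._aggregation_data(offset=0.1)
        d = d[d["aggregation"] == "biomass"]
        with pytest.raises(ValueError):
            inf.aggregation_comparison(d)
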