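import numpy as np
import pandas as pd
import pytest
from scipy import stats

from traitchange.core_io import LongPanel, score_scales
from traitchange.errors import FitError, UsageError
from traitchange.growth import (
    GrowthFit,
    compare_linear_quadratic,
    extract_slopes,
    fit_growth,
)
from traitchange.growth import test_random_slopes as random_slope_lrt
from traitchange.synthetic import generate_panel, make_scoring_key

from conftest import scale_panel_from_array, single_trait_config

MONTHS = np.array([0.0, 6.0, 13.0, 19.0])


def _scored(cfg):
    panel, truth = generate_panel(cfg)
    return score_scales(panel, make_scoring_key(cfg)), truth


class TestFitGrowth:
    def test_noise_free_data_recovers_slope_exactly(self):
        cfg = single_trait_config(fixed_slope=0.01, slope_sd=0.0,
                                  residual_sd=0.0, n_persons=30, seed=1)
        scores, _ = _scored(cfg)
        fit = fit_growth(scores, "T", "self", "linear", likelihood="ml")
        assert fit.slope == pytest.approx(0.01, abs=1e-6)
        assert fit.variance_components["residual_var"] == pytest.approx(0.0, abs=1e-8)

    def test_quadratic_needs_three_time_points(self):
        rng = np.random.default_rng(0)
        panel = scale_panel_from_array(rng.normal(3, 0.3, (10, 2)), [0.0, 6.0])
        with pytest.raises(FitError, match="3 distinct time points"):
            fit_growth(panel, "T", "self", "quadratic")

    def test_ml_and_reml_logliks_both_retained(self):
        cfg = single_trait_config(n_persons=40, residual_sd=0.3, seed=4)
        scores, _ = _scored(cfg)
        fit = fit_growth(scores, "T", "self", "linear", likelihood="both")
        assert fit.loglik_ml is not None and fit.loglik_reml is not None
        assert fit.loglik_ml != fit.loglik_reml

    def test_quadratic_coefficient_recovered_noise_free(self):
        cfg = single_trait_config(fixed_slope=-0.01, quad_coef=0.0006,
                                  slope_sd=0.0, residual_sd=0.0,
                                  n_persons=25, seed=2)
        scores, _ = _scored(cfg)
        fit = fit_growth(scores, "T", "self", "quadratic", likelihood="ml")
        est = fit.fixed_effects.set_index("term")
        assert est.loc["month2", "estimate"] == pytest.approx(0.0006, abs=1e-7)
        assert est.loc["month", "estimate"] == pytest.approx(-0.01, abs=1e-6)

    def test_richer_model_never_fits_worse(self):
        cfg = single_trait_config(n_persons=60, residual_sd=0.3,
                                  slope_sd=0.01, seed=5)
        scores, _ = _scored(cfg)
        lin = fit_growth(scores, "T", "self", "linear", likelihood="ml")
        quad = fit_growth(scores, "T", "self", "quadratic", likelihood="ml")
        assert quad.loglik_ml >= lin.loglik_ml - 1e-6

    def test_estimates_invariant_to_person_relabelling(self):
        cfg = single_trait_config(n_persons=50, residual_sd=0.3, seed=6)
        scores, _ = _scored(cfg)
        fit_a = fit_growth(scores, "T", "self", "linear", likelihood="ml")
        relabeled = scores.data.copy()
        mapping = {p: f"Q{i}" for i, p in
                   enumerate(sorted(relabeled["person_id"].unique())[::-1])}
        relabeled["person_id"] = relabeled["person_id"].map(mapping)
        fit_b = fit_growth(LongPanel(relabeled, item_level=False),
                           "T", "self", "linear", likelihood="ml")
        assert fit_b.slope == pytest.approx(fit_a.slope, abs=1e-8)
        assert fit_b.loglik_ml == pytest.approx(fit_a.loglik_ml, abs=1e-6)


class TestModelComparison:
    @staticmethod
    def _dummy_fit(ll, form):
        return GrowthFit(
            trait="T", rater_role="self", model_form=form, random_slope=True,
            fixed_effects=pd.DataFrame([{"term": "month", "estimate": 0.0,
                                         "se": 1.0, "t": 0.0, "approx_df": 10,
                                         "p": 1.0}]),
            variance_components={}, loglik_ml=ll, loglik_reml=None,
            n_obs=100, n_persons=25,
        )

    def test_identical_logliks_give_chi2_zero_p_one(self):
        res = compare_linear_quadratic(self._dummy_fit(-100.0, "linear"),
                                       self._dummy_fit(-100.0, "quadratic"))
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_loglik_difference_of_4245_gives_chi2_849(self):
        res = compare_linear_quadratic(self._dummy_fit(-100.0, "linear"),
                                       self._dummy_fit(-95.755, "quadratic"))
        assert res.chi2 == pytest.approx(8.49, abs=1e-10)
        assert res.p == pytest.approx(stats.chi2.sf(8.49, 1), abs=1e-12)
        assert res.p == pytest.approx(0.0036, abs=2e-4)

    def test_non_nested_fits_rejected(self):
        other = self._dummy_fit(-90.0, "quadratic")
        other.trait = "U"
        with pytest.raises(UsageError, match="same trait"):
            compare_linear_quadratic(self._dummy_fit(-100.0, "linear"), other)


class TestRandomSlopes:
    def test_heterogeneous_exact_lines_demand_random_slope(self):
        # noise-free lines with per-person slopes: only the random-slope
        # model can interpolate them
        rng = np.random.default_rng(7)
        n = 40
        slopes = rng.normal(0.01, 0.02, n)
        intercepts = rng.normal(3.4, 0.4, n)
        data = intercepts[:, None] + slopes[:, None] * MONTHS[None, :]
        panel = scale_panel_from_array(data, MONTHS)
        res = random_slope_lrt(panel, "T", "self")
        assert res.chi2 > 50
        assert res.p < 1e-6

    def test_power_against_true_slope_heterogeneity(self):
        cfg = single_trait_config(slope_sd=0.02, residual_sd=0.2,
                                  n_persons=259, seed=8)
        scores, _ = _scored(cfg)
        res = random_slope_lrt(scores, "T", "self")
        assert res.significant(0.01)

    def test_mixture_p_never_exceeds_naive_p(self):
        cfg = single_trait_config(slope_sd=0.01, residual_sd=0.3,
                                  n_persons=60, seed=9)
        scores, _ = _scored(cfg)
        res = random_slope_lrt(scores, "T", "self")
        assert res.p_mixture <= res.p + 1e-12


class TestExtractSlopes:
    def test_zero_slope_variance_noise_free_gives_fixed_slope_for_all(self):
        cfg = single_trait_config(fixed_slope=0.01, slope_sd=0.0,
                                  residual_sd=0.0, n_persons=20, seed=10)
        scores, _ = _scored(cfg)
        fit = fit_growth(scores, "T", "self", "linear", likelihood="ml")
        slopes = extract_slopes(fit)["slope"]
        np.testing.assert_allclose(slopes, 0.01, atol=1e-6)

    def test_noise_free_heterogeneous_lines_equal_per_person_ols(self):
        rng = np.random.default_rng(11)
        n = 30
        true_slopes = rng.normal(0.0, 0.02, n)
        data = 3.0 + rng.normal(0, 0.4, n)[:, None] + \
            true_slopes[:, None] * MONTHS[None, :]
        panel = scale_panel_from_array(data, MONTHS)
        fit = fit_growth(panel, "T", "self", "linear", likelihood="ml")
        extracted = extract_slopes(fit).set_index("person_id")["slope"]
        # per-person OLS oracle
        for i in range(n):
            ols = np.polyfit(MONTHS, data[i], 1)[0]
            assert extracted[f"P{i}"] == pytest.approx(ols, abs=1e-4)

    def test_blups_track_latent_truth(self):
        cfg = single_trait_config(fixed_slope=0.02, slope_sd=0.01,
                                  residual_sd=0.05, n_persons=500, seed=12)
        scores, truth = _scored(cfg)
        fit = fit_growth(scores, "T", "self", "linear", likelihood="ml")
        extracted = extract_slopes(fit).set_index("person_id")["slope"]
        t = truth[truth["rater_role"] == "self"].set_index("person_id")["slope"]
        joined = pd.concat([extracted, t], axis=1, keys=["est", "true"]).dropna()
        r = np.corrcoef(joined["est"], joined["true"])[0, 1]
        assert r > 0.9

    def test_mean_blup_deviation_is_near_zero(self):
        cfg = single_trait_config(slope_sd=0.015, residual_sd=0.2,
                                  n_persons=200, seed=13)
        scores, _ = _scored(cfg)
        fit = fit_growth(scores, "T", "self", "linear", likelihood="ml")
        devs = np.array(list(fit.person_slopes.values())) - fit.slope
        assert abs(devs.mean()) < 5e-4
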