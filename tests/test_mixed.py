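import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from taxalag import (ModelSpec, build_model_frame, collinearity_screen,
                     compare_null, covariate_frame, fit_lmm, lag_table,
                     null_spec, wald_anova)


@pytest.fixture(scope="module")
def model_frame(small_records, small_lags):
    return build_model_frame(covariate_frame(small_records), small_lags)


@pytest.fixture(scope="module")
def global_fit(model_frame):
    return fit_lmm(model_frame, ModelSpec())


class TestCollinearityScreen:
    def test_proportional_columns_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        pairs = collinearity_screen(df, 0.70)
        assert [(a, b) for a, b, _ in pairs] == [("x", "y")]
        assert pairs[0][2] == pytest.approx(1.0)

    def test_anticorrelated_columns_flagged_by_absolute_value(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [-1.0, -2, -3, -4]})
        pairs = collinearity_screen(df, 0.70)
        assert pairs and pairs[0][2] == pytest.approx(-1.0)

    def test_independent_large_sample_passes(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((10_000, 4)),
                          columns=list("abcd"))
        assert collinearity_screen(df, 0.70) == []

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1, 1], "y": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            collinearity_screen(df, 0.70)


class TestFitLMM:
    def test_matches_statsmodels_mixedlm_ml(self, model_frame):
        """Independent oracle: statsmodels MixedLM with crossed variance
        components, ML, on the same data."""
        fit = fit_lmm(model_frame, ModelSpec())
        df = model_frame.copy()
        df["one"] = 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM.from_formula(
                "log_description_y ~ genetics + n_authors + n_types + "
                "n_species_in_paper + n_trips + genus_richness",
                groups="one",
                vc_formula={"genus": "0 + C(genus)",
                            "region": "0 + C(region)"},
                data=df)
            oracle = md.fit(reml=False)
        # our profiled optimum must never be worse than the oracle's, and
        # the two optimisers should land on the same solution up to their
        # own convergence error
        assert fit.loglik >= oracle.llf - 1e-4
        assert fit.loglik == pytest.approx(oracle.llf, abs=0.01)
        np.testing.assert_allclose(fit.params, oracle.fe_params.values,
                                   atol=5e-3)
        np.testing.assert_allclose(
            sorted([fit.variance_components["genus"],
                    fit.variance_components["region"]]),
            sorted(oracle.vcomp), atol=5e-3)

    def test_zero_variance_data_reduces_to_ols(self):
        """With no group structure in the response the random variances
        pin to zero and coefficients equal OLS on the same design."""
        rng = np.random.default_rng(1)
        n = 400
        df = pd.DataFrame({
            "x1": rng.standard_normal(n),
            "genus": rng.choice([f"g{i}" for i in range(12)], n),
        })
        df["log_description_y"] = 0.5 + 0.3 * df.x1 + \
            rng.normal(0, 0.4, n)
        spec = ModelSpec(fixed=("x1",), random_intercepts=("genus",))
        fit = fit_lmm(df, spec)
        X = sm.add_constant(df["x1"].to_numpy())
        ols = sm.OLS(df["log_description_y"].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.params, ols.params, atol=1e-4)
        assert fit.variance_components["genus"] < 0.01

    def test_constant_response_collapses_to_intercept(self):
        df = pd.DataFrame({
            "genus": ["a", "a", "b", "b", "c", "c"],
            "log_description_y": [1.7] * 6,
        })
        spec = ModelSpec(fixed=(), random_intercepts=("genus",))
        with warnings.catch_warnings():
            # degenerate zero-variance data: the optimiser may not report
            # formal convergence, which is itself part of the contract
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_lmm(df, spec)
        assert fit.params[0] == pytest.approx(1.7, abs=1e-8)
        assert fit.sigma2_resid < 1e-6

    def test_aic_consistency_and_vc_nonnegative(self, global_fit):
        assert global_fit.aic == pytest.approx(
            2 * global_fit.k_params - 2 * global_fit.loglik)
        assert all(v >= 0 for v in
                   global_fit.variance_components.values())
        assert global_fit.sigma2_resid > 0

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"genus": ["a"] * 5,
                           "log_description_y": np.arange(5.0)})
        with pytest.raises(ValueError):
            fit_lmm(df, ModelSpec(fixed=(), random_intercepts=("genus",)))


class TestWaldAnova:
    def test_single_coefficient_term_is_z_squared(self, global_fit):
        table = wald_anova(global_fit)
        for _, row in table.iterrows():
            i = global_fit.exog_names.index(row["term"])
            z2 = (global_fit.params[i] / global_fit.bse[i]) ** 2
            assert row["chisq"] == pytest.approx(z2, rel=1e-10)
            assert row["df"] == 1

    def test_p_values_are_chi2_survival(self, global_fit):
        from scipy import stats
        table = wald_anova(global_fit)
        for _, row in table.iterrows():
            assert row["p"] == pytest.approx(
                stats.chi2.sf(row["chisq"], row["df"]), rel=1e-12)


class TestCompareNull:
    def test_identical_models_give_zero(self, model_frame, global_fit):
        out = compare_null(global_fit, global_fit)
        assert out["lr_statistic"] == 0.0 and out["aic_delta"] == 0.0

    def test_full_loglik_at_least_null(self, model_frame, global_fit):
        nfit = fit_lmm(model_frame, null_spec(ModelSpec()))
        assert global_fit.loglik >= nfit.loglik - 1e-6
        out = compare_null(global_fit, nfit)
        assert out["df"] == 6 and out["lr_statistic"] >= -1e-6

    def test_different_data_sizes_rejected(self, model_frame, global_fit):
        half = model_frame.iloc[: len(model_frame) // 2]
        small = fit_lmm(half, null_spec(ModelSpec()))
        with pytest.raises(ValueError):
            compare_null(global_fit, small)


def test_regional_spec_drops_region_effect():
    spec = ModelSpec().for_region("India")
    assert spec.random_intercepts == ("genus",)
    assert spec.scope == "India"


def test_model_frame_requires_positive_description(small_records,
                                                   small_lags):
    bad = small_lags.copy()
    bad.loc[bad.index[0], "description_y"] = 0.0
    with pytest.raises(ValueError):
        build_model_frame(covariate_frame(small_records), bad)
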