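import numpy as np
import pandas as pd
import pytest

from promperf import casemix
from promperf.casemix import (AnalysisFit, complete_cases, fit_analysis_model,
                              pool_rubin, standardize_providers)
from promperf.design import CASE_MIX_NAMES


def _linear_model_cohort(rng, n_providers=30, n_per=120, alpha=30.0, gamma=0.5,
                         sigma_u=1.5, sigma_eps=8.0, male_beta=0.8):
    """Data generated directly from the analysis model (no threshold map),
    so the configured coefficients are the exact estimands."""
    n = n_providers * n_per
    g = np.repeat(np.arange(n_providers), n_per)
    u = rng.normal(0, sigma_u, n_providers)
    df = pd.DataFrame({
        "provider_id": g,
        "age_band": rng.integers(0, 4, n),
        "male": rng.integers(0, 2, n),
        "nonwhite": rng.integers(0, 2, n).astype(float),
        "comorbidity_band": rng.integers(0, 3, n),
        "imd_quintile": rng.integers(0, 5, n),
        "symptom_duration": rng.integers(0, 3, n).astype(float),
        "y1_total": rng.normal(18, 8, n).round(0).clip(0, 48),
    })
    df["y2_total"] = (alpha + male_beta * df["male"] + gamma * df["y1_total"]
                      + u[g] + rng.normal(0, sigma_eps, n))
    return df, u


class TestFitAnalysisModel:
    def test_recovers_generating_parameters(self, rng):
        df, _ = _linear_model_cohort(rng, n_providers=40, n_per=250)
        fit = fit_analysis_model(df)
        # 3 Monte-Carlo SEs of the REML estimates
        assert fit.gamma == pytest.approx(0.5, abs=3 * float(fit.bse["y1_total"]))
        assert fit.params["male"] == pytest.approx(0.8, abs=3 * float(fit.bse["male"]))
        assert fit.sigma_eps == pytest.approx(8.0, rel=0.05)
        assert fit.sigma_u == pytest.approx(1.5, rel=0.35)

    def test_agrees_with_mixedlm_oracle(self, rng):
        """Independent cross-check: statsmodels MixedLM REML on the same data."""
        import statsmodels.api as sm
        from promperf.casemix import analysis_design

        df, _ = _linear_model_cohort(rng, n_providers=25, n_per=150)
        fit = fit_analysis_model(df)
        X = analysis_design(df)
        res = sm.MixedLM(df["y2_total"].to_numpy(), X.to_numpy(),
                         groups=df["provider_id"].to_numpy()).fit(reml=True)
        assert np.allclose(fit.params.to_numpy(), res.fe_params, atol=1e-3)
        assert fit.sigma_eps == pytest.approx(float(np.sqrt(res.scale)), abs=1e-3)
        assert fit.sigma_u == pytest.approx(
            float(np.sqrt(np.asarray(res.cov_re)[0, 0])), abs=1e-2)
        assert np.allclose(fit.bse.to_numpy(), res.bse_fe, atol=1e-3)
        blup = np.array([float(v.iloc[0]) for v in res.random_effects.values()])
        assert np.allclose(np.sort(fit.u_hat.to_numpy()), np.sort(blup), atol=1e-2)

    def test_null_provider_effect_boundary(self, rng):
        df, _ = _linear_model_cohort(rng, n_providers=15, n_per=400, sigma_u=0.0)
        fit = fit_analysis_model(df)
        assert fit.sigma_u < 0.5
        assert np.abs(fit.u_hat).max() < 1.0

    def test_location_equivariance(self, rng):
        df, _ = _linear_model_cohort(rng, n_providers=15, n_per=80)
        fit0 = fit_analysis_model(df)
        shifted = df.copy()
        shifted["y2_total"] = shifted["y2_total"] + 7.0
        fit1 = fit_analysis_model(shifted)
        assert fit1.alpha == pytest.approx(fit0.alpha + 7.0, abs=0.02)
        assert fit1.gamma == pytest.approx(fit0.gamma, abs=1e-3)
        assert fit1.sigma_u == pytest.approx(fit0.sigma_u, abs=0.05)
        assert fit1.sigma_eps == pytest.approx(fit0.sigma_eps, abs=0.02)

    def test_singular_design_reports_columns(self, rng):
        df, _ = _linear_model_cohort(rng, n_providers=5, n_per=30)
        df["male"] = 1  # constant -> collinear with intercept
        with pytest.raises(ValueError, match="male|singular"):
            fit_analysis_model(df)

    def test_single_provider_rejected(self, rng):
        df, _ = _linear_model_cohort(rng, n_providers=1, n_per=50)
        with pytest.raises(ValueError, match="two providers"):
            fit_analysis_model(df)


def _fit_with_constant_expectation(expected: float, ybar2: float) -> AnalysisFit:
    params = pd.Series(0.0, index=["const"] + CASE_MIX_NAMES + ["y1_total"])
    params["const"] = expected
    return AnalysisFit(params=params, sigma_u=0.0, sigma_eps=1.0,
                       u_hat=pd.Series(dtype=float), ybar2=ybar2,
                       bse=params * 0.0)


def _reference_patients(y2, provider_id=0):
    n = len(y2)
    return pd.DataFrame({
        "provider_id": provider_id if np.ndim(provider_id) else [provider_id] * n,
        "age_band": 0, "male": 0, "nonwhite": 0.0, "comorbidity_band": 0,
        "imd_quintile": 0, "symptom_duration": 0.0,
        "y1_total": 0.0, "y2_total": np.asarray(y2, dtype=float),
    })


class TestStandardizeProviders:
    def test_hand_worked_ratio(self):
        # provider with outcomes (30, 45), expected (30, 30), national mean 30
        fit = _fit_with_constant_expectation(expected=30.0, ybar2=30.0)
        df = _reference_patients([30.0, 45.0])
        est = standardize_providers(df, fit)
        assert est.loc[0, "rho"] == pytest.approx(1.25)
        assert est.loc[0, "y_tilde"] == pytest.approx(37.5)

    def test_identity_standardisation(self):
        fit = _fit_with_constant_expectation(expected=30.0, ybar2=30.0)
        df = _reference_patients([30.0] * 8)
        est = standardize_providers(df, fit)
        assert est.loc[0, "rho"] == pytest.approx(1.0)
        assert est.loc[0, "y_tilde"] == pytest.approx(30.0)
        assert est.loc[0, "se"] == pytest.approx(0.0)

    @pytest.mark.parametrize("volume", [5, 50])
    def test_uniform_overperformance_scales_mean(self, volume):
        fit = _fit_with_constant_expectation(expected=30.0, ybar2=30.0)
        df = _reference_patients([33.0] * volume)  # 10% above expectation
        est = standardize_providers(df, fit)
        assert est.loc[0, "y_tilde"] == pytest.approx(1.1 * 30.0)

    def test_volume_weighted_mean_rho_is_one(self, complete_cohort):
        _, _, patients, _ = complete_cohort
        fit = fit_analysis_model(patients)
        est = standardize_providers(patients, fit)
        weighted = float(np.average(est["rho"], weights=est["n"]))
        # each patient's ratio contributes once; mean ratio ~ 1 up to Jensen-type slack
        assert weighted == pytest.approx(1.0, abs=0.01)

    def test_nonpositive_expectation_rejected(self):
        fit = _fit_with_constant_expectation(expected=-1.0, ybar2=30.0)
        df = _reference_patients([30.0, 40.0])
        with pytest.raises(ValueError, match="ratio undefined|<= 0"):
            standardize_providers(df, fit)


class TestPoolRubin:
    def test_hand_worked_example(self):
        pooled = pool_rubin([1.0, 3.0], [1.0, 1.0])
        assert pooled.estimate == pytest.approx(2.0)
        assert pooled.var_within == pytest.approx(1.0)
        assert pooled.var_between == pytest.approx(2.0)
        assert pooled.var_total == pytest.approx(1.0 + 1.5 * 2.0)

    def test_identical_estimates_have_no_between_variance(self):
        pooled = pool_rubin([5.0] * 4, [2.0] * 4)
        assert pooled.var_between == 0.0
        assert pooled.var_total == pytest.approx(pooled.var_within)

    def test_single_imputation(self):
        pooled = pool_rubin([5.0], [2.0])
        assert pooled.estimate == 5.0
        assert pooled.var_total == pytest.approx(2.0)
        assert np.isinf(pooled.df)

    def test_total_at_least_within(self, rng):
        est = rng.normal(size=12)
        var = rng.uniform(0.1, 2.0, 12)
        pooled = pool_rubin(est, var)
        assert pooled.var_total >= pooled.var_within

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([], [])


class TestCompleteCases:
    def test_complete_cohort_is_unchanged(self, complete_cohort):
        _, _, patients, _ = complete_cohort
        assert len(complete_cases(patients)) == len(patients)

    def test_subsets_on_outcomes_and_covariates(self, mar_cohort):
        _, _, patients, _ = mar_cohort
        cc = complete_cases(patients)
        assert cc["y1_total"].notna().all()
        assert cc["y2_total"].notna().all()
        assert cc["nonwhite"].notna().all()
        assert cc["symptom_duration"].notna().all()
        assert len(cc) < len(patients)
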