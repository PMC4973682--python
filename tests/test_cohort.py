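import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import ks_2samp

from promperf.cohort import (CohortConfig, MissingnessConfig, apply_missingness,
                             fit_selection_model, generate_cohort)


def _expected_total_closed_form(h, config):
    """E[total | linear predictor h]: marginal of each item latent is
    N((h - center)/scale, 1), so E[item] = sum_m Phi(mu - alpha_m)."""
    mu = (np.asarray(h) - config.latent_center) / config.latent_scale
    return sum(ndtr(mu[:, None] - config.thresholds[k]).sum(axis=1)
               for k in range(12)) / 12 * 12


class TestGenerateCohort:
    def test_no_missingness_identity(self, complete_cohort):
        _, _, patients, truth = complete_cohort
        assert (patients["R1"] == 1).all() and (patients["R2"] == 1).all()
        pd.testing.assert_frame_equal(
            patients, truth.drop(columns=["u_true", "eps_true"]))

    def test_null_provider_effect_and_noise(self):
        config = CohortConfig(n_providers=10, volume_mean=400, volume_log_sd=0.1,
                              sigma_u=0.0, sigma_eps=1e-6,
                              missingness=MissingnessConfig(enabled=False))
        _, patients, truth = generate_cohort(config, seed=5)
        # each provider's mean equals its own case-mix expectation
        h2 = (config.alpha
              + truth["y1_total"].to_numpy() * config.gamma
              + _case_mix_part(truth, config))
        exp_total = _expected_total_closed_form(h2, config)
        grp = pd.DataFrame({"provider_id": truth["provider_id"],
                            "y2": truth["y2_total"], "exp": exp_total})
        per = grp.groupby("provider_id").mean()
        # residual item-level categorisation noise leaves ~0.2 SE per provider mean
        assert np.allclose(per["y2"], per["exp"], atol=0.7)

    def test_preop_mean_against_direct_simulation(self):
        """Oracle: direct large-sample simulation of the generative equations."""
        config = CohortConfig(n_providers=50, volume_mean=200)
        _, _, truth = generate_cohort(config, seed=9)

        rng = np.random.default_rng(12345)
        n = 1_000_000
        # independent re-simulation of the pre-op threshold model
        probs = [np.asarray(p) for p in (config.age_probs,)]
        comorb = rng.choice(3, n, p=config.comorbidity_probs)
        dur = rng.choice(3, n, p=config.duration_probs)
        h1 = (config.preop_intercept
              + config.preop_beta["comorb_1"] * (comorb == 1)
              + config.preop_beta["comorb_2plus"] * (comorb == 2)
              + config.preop_beta["dur_1_5y"] * (dur == 1)
              + config.preop_beta["dur_over5y"] * (dur == 2)
              + config.preop_sd * rng.standard_normal(n))
        mu = (h1 - config.latent_center) / config.latent_scale
        # one item suffices for the mean: items are exchangeable here
        z = mu + rng.standard_normal(n)
        item = np.searchsorted(config.thresholds[0], z, side="left")
        oracle_mean = 12 * item.mean()
        mc_err = 3 * truth["y1_total"].std() / np.sqrt(len(truth))
        assert truth["y1_total"].mean() == pytest.approx(oracle_mean, abs=3 * mc_err + 0.15)

    def test_same_seed_bitwise_reproducible(self):
        config = CohortConfig(n_providers=8, volume_mean=50)
        p1 = generate_cohort(config, seed=77)
        p2 = generate_cohort(config, seed=77)
        for a, b in zip(p1, p2):
            pd.testing.assert_frame_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(thresholds=np.zeros((12, 4)))
        with pytest.raises(ValueError):
            CohortConfig(sigma_eps=0.0)
        with pytest.raises(ValueError):
            CohortConfig(age_probs=(0.5, 0.5, 0.5, 0.5))

    def test_config_yaml_roundtrip(self, tmp_path):
        config = CohortConfig(n_providers=7, seed=3)
        config.save_yaml(tmp_path / "c.yaml")
        loaded = CohortConfig.load_yaml(tmp_path / "c.yaml")
        assert loaded.n_providers == 7
        assert np.allclose(loaded.thresholds, config.thresholds)


def _case_mix_part(df, config):
    from promperf.design import linear_predictor
    return linear_predictor(df, 0.0, config.beta)


class TestApplyMissingness:
    def _neutral_missingness(self, **kw):
        base = dict(q1_intercept=20.0, q1_coefficients={},
                    q2_intercept=0.0, q2_coefficients={}, delta=0.0,
                    phi_sd=0.0, ethnicity_mcar=0.0, duration_mcar=0.0)
        base.update(kw)
        return MissingnessConfig(**base)

    def test_neutral_logit_gives_half_response(self, complete_cohort):
        _, providers, _, truth = complete_cohort
        out = apply_missingness(truth, providers, self._neutral_missingness(),
                                np.random.default_rng(0))
        rate = out["R2"].mean()
        se = np.sqrt(0.25 / len(out))
        assert rate == pytest.approx(0.5, abs=4 * se)

    def test_saturated_link_observes_everyone(self, complete_cohort):
        _, providers, _, truth = complete_cohort
        out = apply_missingness(truth, providers,
                                self._neutral_missingness(q2_intercept=20.0),
                                np.random.default_rng(0))
        assert (out["R1"] == 1).all() and (out["R2"] == 1).all()
        assert out["y2_total"].notna().all()

    def test_q2_observed_implies_q1_observed(self, mar_cohort):
        _, _, patients, _ = mar_cohort
        assert (patients.loc[patients["R2"] == 1, "R1"] == 1).all()
        gone = patients["R1"] == 0
        assert patients.loc[gone, [f"q1_item_{k}" for k in range(1, 13)]].isna().all().all()
        assert (patients.loc[gone, "R2"] == 0).all()

    def test_delta_selects_on_outcome(self, complete_cohort):
        _, providers, _, truth = complete_cohort
        out = apply_missingness(truth, providers,
                                self._neutral_missingness(delta=0.3),
                                np.random.default_rng(1))
        resp = truth.loc[(out["R2"] == 1).to_numpy(), "y2_total"]
        nonresp = truth.loc[(out["R2"] == 0).to_numpy(), "y2_total"]
        assert resp.mean() > nonresp.mean()

    def test_mcar_leaves_covariates_balanced(self, complete_cohort):
        _, providers, _, truth = complete_cohort
        pvals = []
        for seed in range(8):
            out = apply_missingness(truth, providers, self._neutral_missingness(),
                                    np.random.default_rng(seed))
            r = (out["R2"] == 1).to_numpy()
            pvals.append(ks_2samp(truth.loc[r, "y2_total"],
                                  truth.loc[~r, "y2_total"]).pvalue)
        # under MCAR the responder/non-responder outcome distributions agree
        assert np.median(pvals) > 0.05

    def test_delta_recovered_by_selection_model_refit(self):
        from promperf.studies import delta_calibration
        result = delta_calibration(delta=0.3, n_providers=30, volume=300, seed=4)
        assert result["delta_hat"] == pytest.approx(0.3, abs=4 * result["se"])

    def test_item_level_mcar_optional(self, complete_cohort):
        _, providers, _, truth = complete_cohort
        out = apply_missingness(truth, providers,
                                self._neutral_missingness(q2_intercept=20.0, item_mcar=0.1),
                                np.random.default_rng(2))
        q2 = out[[f"q2_item_{k}" for k in range(1, 13)]]
        assert q2.isna().to_numpy().mean() == pytest.approx(0.1, abs=0.02)
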