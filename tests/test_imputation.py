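import inspect

import numpy as np
import pandas as pd
import pytest

from promperf.cohort import MissingnessConfig, apply_missingness
from promperf.imputation import (LatentNormalGibbs, _cs_inverse, _cs_loglik,
                                 fit_and_impute, impute_pipeline, q1_model_spec,
                                 q2_model_spec)

Q1 = [f"q1_item_{k}" for k in range(1, 13)]
Q2 = [f"q2_item_{k}" for k in range(1, 13)]


class TestCompoundSymmetryAlgebra:
    """The hand-derived CS formulas against dense linear algebra."""

    @pytest.mark.parametrize("rho", [-0.05, 0.0, 0.3, 0.7])
    @pytest.mark.parametrize("K", [2, 5, 14])
    def test_inverse_matches_linalg(self, rho, K):
        R = np.full((K, K), rho) + (1 - rho) * np.eye(K)
        assert np.allclose(_cs_inverse(rho, K), np.linalg.inv(R), atol=1e-10)

    def test_loglik_matches_multivariate_normal(self, rng):
        K, rho = 6, 0.4
        R = np.full((K, K), rho) + (1 - rho) * np.eye(K)
        E = rng.standard_normal((40, K))
        from scipy.stats import multivariate_normal
        dense = multivariate_normal(cov=R).logpdf(E).sum()
        const = -0.5 * 40 * K * np.log(2 * np.pi)
        assert _cs_loglik(E, rho) == pytest.approx(dense - const, abs=1e-8)

    def test_conditional_moments_match_partitioning(self, rng):
        # the per-item Gibbs update uses closed-form CS conditionals
        K, rho = 8, 0.35
        R = np.full((K, K), rho) + (1 - rho) * np.eye(K)
        e = rng.standard_normal(K)
        k = 3
        idx = [i for i in range(K) if i != k]
        Sig12 = R[k, idx]
        Sig22inv = np.linalg.inv(R[np.ix_(idx, idx)])
        cond_mean = Sig12 @ Sig22inv @ e[idx]
        cond_var = 1.0 - Sig12 @ Sig22inv @ Sig12
        denom = 1 + (K - 2) * rho
        assert cond_mean == pytest.approx(rho / denom * e[idx].sum(), abs=1e-10)
        assert cond_var == pytest.approx((1 - rho) * (1 + (K - 1) * rho) / denom, abs=1e-10)


class TestFitAndImpute:
    def test_no_missing_returns_identical_copies(self, complete_cohort, mar_cohort):
        _, providers, patients, _ = complete_cohort
        imp, _ = fit_and_impute(patients, q2_model_spec(), m=3, providers=providers)
        assert imp.m == 3
        for d in imp.datasets:
            pd.testing.assert_frame_equal(d, patients)

    def test_draw_count_semantics(self, mar_cohort):
        """Retained states are every thinning-th post-burn-in iteration, so
        iterations/thinning must cover M; the defaults keep the published
        ratio (every 100th of 10,000 draws for M = 100)."""
        defaults = inspect.signature(impute_pipeline).parameters
        assert defaults["iterations"].default // defaults["thinning"].default == 100

        _, providers, patients, _ = mar_cohort
        with pytest.raises(ValueError, match="fewer than"):
            fit_and_impute(patients, q1_model_spec(), m=10, iterations=90,
                           thinning=10, burnin=10, providers=providers)

    def test_mcar_item_frequencies_recovered(self, complete_cohort):
        """Delete 30% of one item MCAR; the pooled imputed category
        frequencies should match the deleted truth's frequencies."""
        _, providers, patients, truth = complete_cohort
        rng = np.random.default_rng(11)
        damaged = patients.copy()
        mask = rng.random(len(damaged)) < 0.3
        damaged.loc[mask, "q2_item_5"] = np.nan
        imp, _ = fit_and_impute(damaged, q2_model_spec(), m=8, iterations=120,
                                thinning=15, burnin=100, seed=2, providers=providers)
        imputed = np.concatenate([d.loc[mask, "q2_item_5"].to_numpy() for d in imp.datasets])
        true_vals = truth.loc[mask, "q2_item_5"].to_numpy()
        freq_imp = np.bincount(imputed.astype(int), minlength=5) / imputed.size
        freq_true = np.bincount(true_vals.astype(int), minlength=5) / true_vals.size
        assert np.abs(freq_imp - freq_true).max() < 0.05

    def test_observed_cells_never_altered(self, mar_cohort):
        _, providers, patients, _ = mar_cohort
        imp, _ = fit_and_impute(patients, q1_model_spec(), m=4, iterations=60,
                                thinning=15, burnin=40, seed=3, providers=providers)
        obs = patients[Q1].notna().to_numpy()
        orig = patients[Q1].to_numpy()
        for d in imp.datasets:
            vals = d[Q1].to_numpy()
            assert np.array_equal(vals[obs], orig[obs])

    def test_fixed_seed_reproducible(self, mar_cohort):
        _, providers, patients, _ = mar_cohort
        kw = dict(m=3, iterations=45, thinning=15, burnin=30, providers=providers)
        a, _ = fit_and_impute(patients, q1_model_spec(), seed=9, **kw)
        b, _ = fit_and_impute(patients, q1_model_spec(), seed=9, **kw)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)


class TestImputePipeline:
    def test_completed_datasets_have_no_missing_values(self, mar_cohort):
        _, providers, patients, _ = mar_cohort
        imp = impute_pipeline(patients, providers, m=3, iterations=60,
                              thinning=20, burnin=50, seed=4)
        assert imp.m == 3
        for d in imp.datasets:
            assert not d[Q1 + Q2 + ["nonwhite", "symptom_duration"]].isna().any().any()
            assert d["y1_total"].between(0, 48).all()
            assert d["y2_total"].between(0, 48).all()
            items = d[Q1 + Q2].to_numpy()
            assert items.min() >= 0 and items.max() <= 4
            assert d["nonwhite"].isin([0.0, 1.0]).all()
            assert d["symptom_duration"].isin([0.0, 1.0, 2.0]).all()

    def test_q2_only_missingness_skips_stage_one(self, complete_cohort):
        _, providers, patients, _ = complete_cohort
        rng = np.random.default_rng(8)
        damaged = patients.copy()
        drop = rng.random(len(damaged)) < 0.3
        damaged.loc[drop, Q2] = np.nan
        damaged.loc[drop, "R2"] = 0
        damaged["y2_total"] = np.where(drop, np.nan, damaged["y2_total"])
        imp = impute_pipeline(damaged, providers, m=3, iterations=60,
                              thinning=20, burnin=50, seed=5)
        assert imp.diagnostics["stage1"].get("skipped")
        for d in imp.datasets:
            # pre-op block untouched
            assert np.array_equal(d[Q1].to_numpy(), patients[Q1].to_numpy())

    def test_provider_with_no_observed_outcomes_shrinks_to_case_mix(self, complete_cohort):
        """A provider whose post-op data are entirely missing (MCAR) draws
        its effect from the prior, so its imputed mean should land near the
        population case-mix expectation rather than any extreme."""
        _, providers, patients, truth = complete_cohort
        damaged = patients.copy()
        target = providers["provider_id"].iloc[0]
        sel = damaged["provider_id"] == target
        damaged.loc[sel, Q2] = np.nan
        damaged.loc[sel, "R2"] = 0
        damaged["y2_total"] = np.where(sel, np.nan, damaged["y2_total"])
        imp = impute_pipeline(damaged, providers, m=6, iterations=120,
                              thinning=20, burnin=350, seed=6)
        imputed_mean = np.mean([d.loc[sel, "y2_total"].mean() for d in imp.datasets])
        national = patients.loc[~sel, "y2_total"].mean()
        assert abs(imputed_mean - national) < 2.5

    def test_reproducible_end_to_end(self, mar_cohort):
        _, providers, patients, _ = mar_cohort
        kw = dict(m=2, iterations=40, thinning=20, burnin=30, seed=12)
        a = impute_pipeline(patients, providers, **kw)
        b = impute_pipeline(patients, providers, **kw)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)

    def test_serialisation_roundtrip(self, mar_cohort, tmp_path):
        _, providers, patients, _ = mar_cohort
        imp = impute_pipeline(patients, providers, m=2, iterations=40,
                              thinning=20, burnin=30, seed=13)
        imp.save(tmp_path / "imps")
        assert (tmp_path / "imps" / "manifest.json").exists()
        assert len(list((tmp_path / "imps").glob("imputation_*.csv"))) == 2
        long = imp.long_format()
        assert set(long["dataset_id"]) == {1, 2}
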