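"""Replicate simulation studies over the synthetic cohort generator.

These are the package's evaluation experiments: each function defines one
study's data-generating conditions and runs it end to end through the
pipeline stages, returning tidy per-replicate results.  The analysis
scripts drive them at full scale; the test suite runs them at reduced
replicate counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from . import casemix, funnel
from .cohort import CohortConfig, MissingnessConfig, fit_selection_model, generate_cohort
from .imputation import impute_pipeline


# ---------------------------------------------------------------------------
# funnel nominal coverage under the null
# ---------------------------------------------------------------------------

def null_funnel_coverage(n_providers: int, volume: int, mean: float = 38.0,
                         sigma: float = 9.5, seed: int | None = None,
                         exact_sd: bool = False) -> dict:
    """Simulate providers sharing one true mean and classify them.

    Patient outcomes are normal around the common mean; provider points
    are the observed means, classified against limits built from the known
    population SD.  Returns the percentage of providers inside each band,
    which should sit at the nominal levels.
    """
    rng = np.random.default_rng(seed)
    provider_means = mean + sigma / np.sqrt(volume) * rng.standard_normal(n_providers)
    z_in, z_out = funnel.z_multipliers(exact_sd)
    status = funnel.classify(provider_means, np.full(n_providers, volume),
                             mean, sigma, z_in, z_out)
    status = np.asarray(status, dtype=object)
    inside_inner = np.isin(status, ["in_control"])
    inside_outer = ~np.isin(status, ["positive_alarm", "negative_alarm"])
    return {
        "n": n_providers,
        "pct_inside_inner": 100.0 * inside_inner.mean(),
        "pct_inside_outer": 100.0 * inside_outer.mean(),
    }


def null_funnel_coverage_patient_level(n_providers: int, volume: int,
                                       mean: float = 38.0, sigma: float = 9.5,
                                       seed: int | None = None,
                                       exact_sd: bool = False) -> dict:
    """As above but simulating every patient outcome explicitly."""
    rng = np.random.default_rng(seed)
    y = mean + sigma * rng.standard_normal((n_providers, volume))
    provider_means = y.mean(axis=1)
    z_in, z_out = funnel.z_multipliers(exact_sd)
    status = np.asarray(funnel.classify(provider_means, np.full(n_providers, volume),
                                        mean, sigma, z_in, z_out), dtype=object)
    return {
        "n": n_providers,
        "pct_inside_inner": 100.0 * float(np.mean(status == "in_control")),
        "pct_inside_outer": 100.0 * float(
            np.mean(~np.isin(status, ["positive_alarm", "negative_alarm"]))),
    }


# ---------------------------------------------------------------------------
# selection-model calibration (the delta -> odds-ratio identity)
# ---------------------------------------------------------------------------

def delta_calibration(delta: float = 0.3, n_providers: int = 50,
                      volume: float = 400.0, seed: int | None = None) -> dict:
    """Generate at a given delta and recover it by refitting the selection model.

    Provider response effects are switched off so the plain ML logistic
    refit is correctly specified; the recovered coefficient should match
    the configured log-odds per score unit (odds ratio exp(delta)).
    """
    miss = MissingnessConfig(
        q1_intercept=20.0, q1_coefficients={},
        q2_intercept=0.3, q2_coefficients={"length_of_stay": -0.03, "lives_alone": -0.3},
        delta=delta, phi_sd=0.0, ethnicity_mcar=0.0, duration_mcar=0.0)
    config = CohortConfig(n_providers=n_providers, volume_mean=volume,
                          volume_log_sd=0.3, missingness=miss)
    providers, patients, truth = generate_cohort(config, seed=seed)
    sub = truth.copy()
    sub["R2"] = patients["R2"]
    res = fit_selection_model(sub, providers, miss.q2_coefficients,
                              outcome_col="y2_total", y2_center=miss.y2_center)
    d_hat = float(res.params["outcome"])
    return {"delta_true": delta, "delta_hat": d_hat,
            "odds_ratio_hat": float(np.exp(d_hat)),
            "se": float(res.bse["outcome"]), "n": int(len(sub))}


# ---------------------------------------------------------------------------
# MAR recovery: MI coverage vs complete-case bias
# ---------------------------------------------------------------------------

def mar_study_config(n_providers: int = 20, volume: float = 100.0) -> CohortConfig:
    """Study conditions: post-op-only MAR missingness driven by length of
    stay, which is itself correlated with the outcome residual, so the
    complete cases over-represent good outcomes."""
    miss = MissingnessConfig(
        q1_intercept=20.0, q1_coefficients={},
        q2_intercept=1.5, q2_coefficients={"length_of_stay": -0.15},
        delta=0.0, phi_sd=0.2, ethnicity_mcar=0.0, duration_mcar=0.0)
    return CohortConfig(n_providers=n_providers, volume_mean=volume,
                        volume_log_sd=0.3, los_outcome_effect=-0.08,
                        missingness=miss)


def reference_estimands(config: CohortConfig, n_providers: int = 200,
                        volume: float = 500.0, seed: int = 20_260_101) -> dict:
    """Large-sample full-data analysis-model estimands under a config.

    The generator writes the outcome through an ordinal threshold map, so
    the exact score-scale coefficients are defined operationally as the
    full-data REML estimates at large n; these are the targets MI should
    recover under MAR.
    """
    import dataclasses
    big = dataclasses.replace(config, n_providers=n_providers, volume_mean=volume,
                              missingness=MissingnessConfig(enabled=False), seed=None)
    _, patients, _ = generate_cohort(big, seed=seed)
    fit = casemix.fit_analysis_model(patients)
    return {"gamma": fit.gamma, "alpha": fit.alpha, "ybar2": fit.ybar2,
            "sigma_u": fit.sigma_u, "sigma_eps": fit.sigma_eps,
            "params": fit.params, "n": int(len(patients))}


def mar_recovery_study(n_replicates: int = 100, m: int = 10,
                       iterations: int = 150, thinning: int = 15, burnin: int = 100,
                       seed: int = 0, config: CohortConfig | None = None,
                       reference: dict | None = None) -> pd.DataFrame:
    """Replicate MI-then-analyse vs complete-case analysis under MAR.

    Per replicate: the Rubin-pooled MI estimate and t-interval for gamma
    (the pre-op score coefficient), whether it covers the reference
    estimand, and the complete-case national-mean bias relative to that
    replicate's own full-data mean.
    """
    if config is None:
        config = mar_study_config()
    if reference is None:
        reference = reference_estimands(config)
    gamma_ref = reference["gamma"]

    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        providers, patients, truth = generate_cohort(config, seed=rep_seed)

        imp = impute_pipeline(patients, providers, m, iterations=iterations,
                              thinning=thinning, burnin=burnin, seed=rep_seed)
        gammas, variances = [], []
        for d in imp.datasets:
            f = casemix.fit_analysis_model(d)
            gammas.append(f.gamma)
            variances.append(float(f.bse["y1_total"]) ** 2)
        pooled = casemix.pool_rubin(gammas, variances)
        crit = t_dist.ppf(0.975, pooled.df) if np.isfinite(pooled.df) else 1.959964
        lo, hi = pooled.estimate - crit * pooled.se, pooled.estimate + crit * pooled.se

        cc = casemix.complete_cases(patients)
        cc_fit = casemix.fit_analysis_model(cc)
        rows.append({
            "replicate": rep,
            "gamma_mi": pooled.estimate, "gamma_se": pooled.se,
            "ci_lo": lo, "ci_hi": hi,
            "covered": bool(lo <= gamma_ref <= hi),
            "gamma_cca": cc_fit.gamma,
            "cca_mean_bias": cc_fit.ybar2 - float(truth["y2_total"].mean()),
            "mi_mean_bias": float(np.mean([d["y2_total"].mean() for d in imp.datasets])
                                  - truth["y2_total"].mean()),
            "response_rate": float(patients["y2_total"].notna().mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MNAR: complete-case vs MI provider classification
# ---------------------------------------------------------------------------

def mnar_study_config(n_providers: int = 40, volume: float = 150.0,
                      delta: float = 0.3) -> CohortConfig:
    """Missingness concentrated among poor outcomes (positive delta) with a
    substantial true provider spread so alarms genuinely exist."""
    miss = MissingnessConfig(
        q1_intercept=20.0, q1_coefficients={},
        q2_intercept=0.5, q2_coefficients={"length_of_stay": -0.05},
        delta=delta, phi_sd=0.3, ethnicity_mcar=0.0, duration_mcar=0.0)
    return CohortConfig(n_providers=n_providers, volume_mean=volume,
                        volume_log_sd=0.4, sigma_u=2.5, missingness=miss)


def mnar_comparison_study(n_replicates: int = 6, m: int = 8,
                          iterations: int = 120, thinning: int = 15, burnin: int = 100,
                          seed: int = 0, config: CohortConfig | None = None) -> pd.DataFrame:
    """Count alarm statuses under CCA and MI on MNAR cohorts.

    The qualitative expectation: complete-case analysis misses
    under-performers (fewer negative alarms) because each provider is
    judged at its shrunken complete-case volume and its selectively
    observed outcomes.
    """
    from .pipeline import RunConfig, analyse_cca, analyse_mi

    if config is None:
        config = mnar_study_config()
    run_cfg = RunConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        providers, patients, _ = generate_cohort(config, seed=rep_seed)
        cca = analyse_cca(patients, run_cfg)
        imp = impute_pipeline(patients, providers, m, iterations=iterations,
                              thinning=thinning, burnin=burnin, seed=rep_seed)
        mi = analyse_mi(patients, imp, run_cfg)
        for mode, result in (("cca", cca), ("mi", mi)):
            counts = dict(zip(result["table"]["status"], result["table"]["n"]))
            rows.append({"replicate": rep, "mode": mode,
                         **{s: int(counts.get(s, 0)) for s in funnel.STATUSES}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delta-sweep validity: re-weighting toward the generating delta
# ---------------------------------------------------------------------------

def delta_truth_study(n_replicates: int = 5, delta_true: float = 0.2,
                      m: int = 10, iterations: int = 150, thinning: int = 15,
                      burnin: int = 100, seed: int = 0) -> pd.DataFrame:
    """Generate MNAR at a known delta; check the re-weighted national mean.

    For each replicate, the full-data truth mean is retained; the sweep's
    national mean at the generating delta should be closer to it than the
    equal-weight (delta = 0) mean.
    """
    from .pipeline import analyse_mi, RunConfig
    from .sensitivity import DeltaGrid, delta_sweep

    config = mnar_study_config(n_providers=15, volume=100.0, delta=delta_true)
    run_cfg = RunConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        providers, patients, truth = generate_cohort(config, seed=rep_seed)
        imp = impute_pipeline(patients, providers, m, iterations=iterations,
                              thinning=thinning, burnin=burnin, seed=rep_seed)
        mi = analyse_mi(patients, imp, run_cfg)
        missing = patients["y2_total"].isna()
        sums = np.array([d.loc[missing, "y2_total"].sum() for d in imp.datasets])
        sweep = delta_sweep(mi["per_imputation"], mi["means"], mi["sigmas"], sums,
                            DeltaGrid(np.array([0.0, delta_true])))
        truth_mean = float(truth["y2_total"].mean())
        rows.append({
            "replicate": rep,
            "truth_mean": truth_mean,
            "mean_at_0": float(sweep.national_means[0.0]),
            "mean_at_delta": float(sweep.national_means[delta_true]),
            "abs_bias_0": abs(sweep.national_means[0.0] - truth_mean),
            "abs_bias_delta": abs(sweep.national_means[delta_true] - truth_mean),
        })
    return pd.DataFrame(rows)
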