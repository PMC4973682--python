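"""End-to-end orchestration: simulate, impute, analyse, profile, sweep.

``run(RunConfig)`` executes the enabled stages in order and writes all
artifacts (CSV tables, a JSON summary) into a run directory.  Outputs are
deterministic functions of (inputs, config, seed): the summary contains
no timestamps, so re-running the same configuration reproduces it byte
for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import casemix, funnel, sensitivity
from .cohort import CohortConfig, generate_cohort
from .imputation import impute_pipeline

log = logging.getLogger("promperf")

EXIT_VALIDATION = 2
EXIT_CONVERGENCE = 3


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Desk-scale defaults; the published survey's scale (298 providers,
    M = 100, 10,000 iterations thinned every 100th) is a configuration,
    reachable by overriding these fields.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_path: str | None = None          # load instead of simulating
    providers_path: str | None = None
    seed: int = 0
    modes: tuple = ("cca", "mi")
    m_imputations: int = 20
    iterations: int = 600
    thinning: int = 30
    burnin: int = 300
    delta_grid: tuple = (-0.3, -0.2, -0.1, 0.0, 0.1, 0.2, 0.3)
    bpt_threshold: float = 0.5
    exact_sd: bool = False
    save_imputations: bool = False
    make_figure: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        for key in ("modes", "delta_grid"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def provider_response_rates(patients: pd.DataFrame) -> pd.Series:
    """Fraction of eligible patients with both questionnaires fully observed."""
    complete = patients["y1_total"].notna() & patients["y2_total"].notna()
    return complete.groupby(patients["provider_id"]).mean()


def analyse_cca(patients: pd.DataFrame, config: RunConfig):
    """Complete-case analysis: volumes are observed complete-case counts."""
    cc = casemix.complete_cases(patients)
    if cc["provider_id"].nunique() < 2:
        raise ValueError("fewer than two providers with complete cases")
    fit = casemix.fit_analysis_model(cc)
    est = casemix.standardize_providers(cc, fit)
    est["response_rate"] = provider_response_rates(patients).reindex(est.index).to_numpy()
    sigma = casemix.population_sigma(cc, fit)
    assessed, table = funnel.assess_all(est, fit.ybar2, sigma,
                                        exact_sd=config.exact_sd,
                                        bpt_threshold=config.bpt_threshold)
    return {"fit": fit, "assessments": assessed, "table": table,
            "mean": fit.ybar2, "sigma_pop": sigma}


def analyse_mi(patients: pd.DataFrame, imp_set, config: RunConfig):
    """MI analysis: fit each completed dataset, pool by Rubin's rules.

    Volumes are the full eligible counts (the volume effect).  Also
    returns the per-imputation pieces the delta sweep re-weights.
    """
    per_imp, means, sigmas = [], [], []
    for d in imp_set.datasets:
        fit = casemix.fit_analysis_model(d)
        per_imp.append(casemix.standardize_providers(d, fit))
        means.append(fit.ybar2)
        sigmas.append(casemix.population_sigma(d, fit))

    providers_idx = per_imp[0].index
    theta = np.column_stack([e["y_tilde"].to_numpy() for e in per_imp])
    var = np.column_stack([e["se"].to_numpy() ** 2 for e in per_imp])
    pooled = [casemix.pool_rubin(theta[i], var[i]) for i in range(theta.shape[0])]
    est = pd.DataFrame({
        "n": per_imp[0]["n"].to_numpy(),
        "y_tilde": [p.estimate for p in pooled],
        "se": [p.se for p in pooled],
    }, index=providers_idx)
    est["response_rate"] = provider_response_rates(patients).reindex(est.index).to_numpy()
    mean = float(np.mean(means))
    sigma = float(np.mean(sigmas))
    assessed, table = funnel.assess_all(est, mean, sigma,
                                        exact_sd=config.exact_sd,
                                        bpt_threshold=config.bpt_threshold)
    return {"assessments": assessed, "table": table, "mean": mean, "sigma_pop": sigma,
            "per_imputation": per_imp, "means": means, "sigmas": sigmas}


def run(config: RunConfig, out_dir) -> dict:
    """Execute the pipeline; returns the machine-readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # -- cohort -------------------------------------------------------------
    if config.cohort_path:
        patients = pd.read_csv(config.cohort_path)
        providers = pd.read_csv(config.providers_path)
        truth = None
    else:
        providers, patients, truth = generate_cohort(config.cohort, seed=config.seed)
        providers.to_csv(out / "providers.csv", index=False)
        patients.to_csv(out / "cohort.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
    Path(out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    (out / "meta.json").write_text(json.dumps({"seed": config.seed, "schema_version": 1}, indent=2))
    log.info("cohort ready: %d patients, %d providers (%.1fs)",
             len(patients), len(providers), time.time() - t0)

    summary: dict = {"seed": config.seed, "schema_version": 1,
                     "n_patients": int(len(patients)), "n_providers": int(len(providers)),
                     "modes": {}}

    def record(mode: str, result: dict) -> None:
        assessed, table = result["assessments"], result["table"]
        assessed = assessed.copy()
        assessed.insert(0, "provider_id", assessed.index)
        assessed["analysis_mode"] = mode
        assessed.to_csv(out / f"{mode}_providers.csv", index=False)
        table.to_csv(out / f"{mode}_status.csv", index=False)
        summary["modes"][mode] = {
            "national_mean": round(result["mean"], 6),
            "sigma_pop": round(result["sigma_pop"], 6),
            "status_counts": {r["status"]: int(r["n"]) for _, r in table.iterrows()},
            "n_assessed": int(len(assessed)),
            "bpt_ineligible": int((~assessed["bpt_eligible"]).sum()),
        }

    # -- complete cases -----------------------------------------------------
    if "cca" in config.modes:
        t = time.time()
        record("cca", analyse_cca(patients, config))
        log.info("CCA done (%.1fs)", time.time() - t)

    # -- multiple imputation ------------------------------------------------
    mi_result = None
    imp_set = None
    if "mi" in config.modes or "mnar" in config.modes:
        t = time.time()
        imp_set = impute_pipeline(patients, providers, config.m_imputations,
                                  iterations=config.iterations, thinning=config.thinning,
                                  burnin=config.burnin, seed=config.seed)
        if config.save_imputations:
            imp_set.save(out / "imputations")
        mi_result = analyse_mi(patients, imp_set, config)
        record("mi", mi_result)
        log.info("MI done: M=%d (%.1fs)", imp_set.m, time.time() - t)

    # -- MNAR sensitivity sweep --------------------------------------------
    if "mnar" in config.modes:
        t = time.time()
        missing_mask = patients["y2_total"].isna()
        sums = np.array([d.loc[missing_mask, "y2_total"].sum() for d in imp_set.datasets])
        result = sensitivity.delta_sweep(
            mi_result["per_imputation"], mi_result["means"], mi_result["sigmas"],
            sums, sensitivity.DeltaGrid(np.asarray(config.delta_grid)),
            response_rates=provider_response_rates(patients),
            exact_sd=config.exact_sd)
        result.table_wide().to_csv(out / "sensitivity_table.csv", index=False)
        mnar_frames = []
        for d, assessed in result.assessments.items():
            frame = assessed.copy()
            frame.insert(0, "provider_id", frame.index)
            frame.insert(0, "delta", d)
            frame["analysis_mode"] = "mnar"
            mnar_frames.append(frame)
        pd.concat(mnar_frames, ignore_index=True).to_csv(out / "mnar_providers.csv", index=False)
        diag = {
            "ess": {f"{d:g}": round(float(v), 4) for d, v in result.ess.items()},
            "warnings": result.warnings_by_delta,
        }
        (out / "weights.json").write_text(json.dumps(diag, indent=2))
        summary["mnar"] = {
            f"{d:g}": {r["status"]: int(r["n"])
                        for _, r in result.tables[result.tables["delta"] == d].iterrows()}
            for d in result.grid
        }
        log.info("MNAR sweep done over %d deltas (%.1fs)", len(result.grid), time.time() - t)

    if config.make_figure and mi_result is not None:
        funnel.plot_funnel(mi_result["assessments"], mi_result["mean"],
                           mi_result["sigma_pop"], exact_sd=config.exact_sd,
                           path=out / "funnel_mi.png")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("pipeline complete (%.1fs total)", time.time() - t0)
    return summary
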