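"""Synthetic PROM survey cohorts: patients nested in providers.

The generator is the testbed for the whole pipeline.  It emulates the
structure of a national PROM collection for elective hip replacement:

* providers drawn first, each with a true outcome effect ``u_true`` (the
  random intercept of the analysis model) and a true response-propensity
  effect ``phi_true`` (the random intercept of the missingness model);
* per patient: case-mix covariates sampled categorically, a latent pre-op
  health score, 12 pre-op ordinal items from a threshold model, a post-op
  linear predictor  alpha + X beta + y1 gamma + u_j + eps  in score units,
  12 post-op items from the threshold model around it;
* missingness applied last, questionnaire-wise, through logistic selection
  models: the post-op response indicator R2 follows
  ``logit P(R2=1) = eta0 + W eta1 + Z eta2 + phi_j + delta * (y2 - y2_center)``,
  which collapses to MAR at delta = 0; the pre-op indicator R1 has its own
  logistic model (provider-level predictors, no outcome term by default),
  and R2 is forced to 0 whenever R1 = 0 because the post-op questionnaire
  is only sent to pre-op responders.

The complete pre-deletion data ("truth") is retained so downstream stages
can be validated against the values that were deleted.

Default parameter values are loose emulations of the published descriptive
statistics of the 2011-12 English hip-replacement PROM cohort (post-op OHS
mean ~38, SD ~9.5; pre-op ~17.5, SD ~8.4; 61% pre-op and 52% post-op
response; covariate category frequencies as reported).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .design import linear_predictor
from .scoring import N_ITEMS, score_totals_frame

Q1_ITEM_COLS = [f"q1_item_{k}" for k in range(1, N_ITEMS + 1)]
Q2_ITEM_COLS = [f"q2_item_{k}" for k in range(1, N_ITEMS + 1)]

#: documented column dictionary for cohort / truth CSVs
COLUMN_DICTIONARY = {
    "patient_id": "unique patient identifier (int)",
    "provider_id": "provider identifier (int)",
    "age_band": "0 under 55, 1 55-65, 2 65-75, 3 over 75",
    "male": "1 male, 0 female",
    "nonwhite": "ethnicity: 1 non-white, 0 white; may be missing",
    "comorbidity_band": "Charlson band: 0 none, 1 one, 2 two or more",
    "imd_quintile": "deprivation: 0 most deprived ... 4 least deprived",
    "symptom_duration": "0 up to 1y, 1 1-5y, 2 over 5y; may be missing",
    "length_of_stay": "hospital length of stay, days",
    "waiting_time": "elective waiting time, days",
    "previous_surgery": "1 if previous hip surgery",
    "pre_admission_q1": "1 if Q1 administered before admission",
    "assisted_q2": "1 if assistance required completing Q2",
    "lives_alone": "1 if patient lives alone",
    "q1_item_k": "pre-op OHS item k in 0..4; blank when missing",
    "q2_item_k": "post-op OHS item k in 0..4; blank when missing",
    "R1": "1 if the pre-op questionnaire was observed",
    "R2": "1 if the post-op questionnaire was observed",
    "y1_total": "pre-op OHS total (0-48); blank unless all 12 items observed",
    "y2_total": "post-op OHS total (0-48); blank unless all 12 items observed",
}


@dataclass
class MissingnessConfig:
    """Logistic selection models for the two questionnaires.

    Coefficient dicts are keyed by patient or provider columns
    (``is_private``, ``is_teaching`` and ``log_volume`` are provider-level).
    ``delta`` is the log-odds of post-op response per unit of the
    (possibly unobserved) post-op total score; delta = 0 is MAR.
    """

    enabled: bool = True
    q1_intercept: float = -0.18
    q1_coefficients: dict[str, float] = field(default_factory=lambda: {
        "length_of_stay": -0.02,
        "waiting_time": -0.002,
        "is_private": 0.3,
        "is_teaching": -0.2,
        "log_volume": 0.15,
    })
    q2_intercept: float = 2.0
    q2_coefficients: dict[str, float] = field(default_factory=lambda: {
        "length_of_stay": -0.03,
        "waiting_time": -0.002,
        "lives_alone": -0.4,
        "pre_admission_q1": 0.2,
    })
    delta: float = 0.0
    y2_center: float = 38.0
    phi_sd: float = 0.25
    ethnicity_mcar: float = 0.11
    duration_mcar: float = 0.39
    item_mcar: float = 0.0


def _default_thresholds() -> np.ndarray:
    return np.tile(np.array([-1.5, -0.5, 0.5, 1.5]), (N_ITEMS, 1))


@dataclass
class CohortConfig:
    """Full generative configuration; defaults are the desk-scale study conditions."""

    n_providers: int = 50
    volume_mean: float = 200.0
    volume_log_sd: float = 0.8
    prob_private: float = 0.49
    prob_teaching: float = 0.11

    age_probs: tuple = (0.12, 0.22, 0.35, 0.31)
    male_prob: float = 0.40
    nonwhite_prob: float = 0.13
    comorbidity_probs: tuple = (0.72, 0.21, 0.07)
    imd_probs: tuple = (0.13, 0.17, 0.23, 0.26, 0.21)
    duration_probs: tuple = (0.14, 0.67, 0.19)

    # post-op analysis model, score units: y2 = alpha + X beta + y1 gamma + u + eps
    alpha: float = 30.2
    beta: dict[str, float] = field(default_factory=lambda: {
        "age_55_65": 0.5, "age_65_75": 0.5, "age_over75": -0.5,
        "male": 0.5, "nonwhite": -1.5,
        "comorb_1": -1.0, "comorb_2plus": -2.5,
        "imd_2": 0.5, "imd_3": 1.0, "imd_4": 1.2, "imd_least": 1.5,
        "dur_1_5y": -0.5, "dur_over5y": -1.5,
    })
    gamma: float = 0.5
    sigma_u: float = 1.5
    sigma_eps: float = 8.0

    # pre-op latent score, score units: h1 = preop_intercept + X c + s1 xi
    preop_intercept: float = 18.9
    preop_beta: dict[str, float] = field(default_factory=lambda: {
        "comorb_1": -1.0, "comorb_2plus": -2.0,
        "dur_1_5y": -1.0, "dur_over5y": -2.0,
    })
    preop_sd: float = 6.0

    # threshold model: item latent mean = (h - latent_center) / latent_scale
    thresholds: np.ndarray = field(default_factory=_default_thresholds)
    rho: float = 0.3
    latent_center: float = 24.0
    latent_scale: float = 11.5

    # auxiliary-variable generation
    los_log_mean: float = 1.6
    los_log_sd: float = 0.55
    los_comorb_effect: float = 0.15
    los_outcome_effect: float = -0.03  # per unit of the post-op residual eps
    waiting_shape: float = 2.1
    waiting_scale: float = 42.0
    previous_surgery_prob: float = 0.89
    pre_admission_prob: float = 0.82
    assisted_prob: float = 0.94
    lives_alone_prob: float = 0.26

    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape != (N_ITEMS, 4):
            raise ValueError(f"thresholds must have shape ({N_ITEMS}, 4)")
        if not np.all(np.diff(self.thresholds, axis=1) > 0):
            raise ValueError("item thresholds must be strictly increasing")
        if self.sigma_u < 0 or self.sigma_eps <= 0 or self.preop_sd <= 0:
            raise ValueError("sigma_u must be >= 0 and sigma_eps, preop_sd > 0")
        if self.n_providers < 1:
            raise ValueError("need at least one provider")
        K = N_ITEMS
        if not (-1.0 / (K - 1) < self.rho < 1.0):
            raise ValueError("rho outside the valid compound-symmetry range")
        for name in ("age_probs", "comorbidity_probs", "imd_probs", "duration_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if isinstance(self.missingness, dict):
            self.missingness = MissingnessConfig(**self.missingness)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = self.thresholds.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "thresholds" in d:
            d["thresholds"] = np.asarray(d["thresholds"], dtype=float)
        if "missingness" in d and isinstance(d["missingness"], dict):
            d["missingness"] = MissingnessConfig(**d["missingness"])
        return cls(**d)

    def save_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load_yaml(cls, path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def sample_correlated_latents(mu: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Draw Z = mu + e with e ~ N(0, R), R compound symmetry, unit diagonal.

    mu has shape (n, K).  Uses the one-factor representation for rho >= 0
    and a Cholesky factor otherwise.
    """
    n, K = mu.shape
    if rho >= 0:
        common = rng.standard_normal((n, 1))
        e = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * rng.standard_normal((n, K))
    else:
        R = np.full((K, K), rho) + (1.0 - rho) * np.eye(K)
        e = rng.standard_normal((n, K)) @ np.linalg.cholesky(R).T
    return mu + e


def _categorize_items(Z: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Vectorised threshold map per item column: (n, K) latents -> categories."""
    out = np.zeros(Z.shape, dtype=float)
    for k in range(Z.shape[1]):
        out[:, k] = np.searchsorted(thresholds[k], Z[:, k], side="left")
    return out


def generate_providers(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_providers
    volume = np.maximum(
        1,
        np.round(
            rng.lognormal(np.log(config.volume_mean) - config.volume_log_sd**2 / 2.0,
                          config.volume_log_sd, n)
        ).astype(int),
    )
    return pd.DataFrame({
        "provider_id": np.arange(n),
        "is_private": rng.binomial(1, config.prob_private, n),
        "is_teaching": rng.binomial(1, config.prob_teaching, n),
        "target_volume": volume,
        "u_true": rng.normal(0.0, config.sigma_u, n),
        "phi_true": rng.normal(0.0, config.missingness.phi_sd, n),
    })


def generate_cohort(config: CohortConfig, seed: int | None = None):
    """Generate (providers, patients, truth).

    ``truth`` is the complete cohort before any deletion (items always
    observed, totals always defined); ``patients`` carries the response
    indicators and the post-deletion items.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    providers = generate_providers(config, rng)

    reps = providers["target_volume"].to_numpy()
    n = int(reps.sum())
    g = np.repeat(np.arange(config.n_providers), reps)

    df = pd.DataFrame({
        "patient_id": np.arange(n),
        "provider_id": g,
        "age_band": rng.choice(4, n, p=config.age_probs),
        "male": rng.binomial(1, config.male_prob, n),
        "nonwhite": rng.binomial(1, config.nonwhite_prob, n).astype(float),
        "comorbidity_band": rng.choice(3, n, p=config.comorbidity_probs),
        "imd_quintile": rng.choice(5, n, p=config.imd_probs),
        "symptom_duration": rng.choice(3, n, p=config.duration_probs).astype(float),
    })

    # pre-op latent health (score units) and items
    h1 = linear_predictor(df, config.preop_intercept, config.preop_beta)
    h1 = h1 + config.preop_sd * rng.standard_normal(n)
    mu1 = (h1 - config.latent_center) / config.latent_scale
    Z1 = sample_correlated_latents(np.tile(mu1[:, None], (1, N_ITEMS)), config.rho, rng)
    q1 = _categorize_items(Z1, config.thresholds)
    y1 = q1.sum(axis=1)

    # post-op linear predictor in score units (analysis model), then items
    eps = config.sigma_eps * rng.standard_normal(n)
    u = providers["u_true"].to_numpy()[g]
    h2 = linear_predictor(df, config.alpha, config.beta) + config.gamma * y1 + u + eps
    mu2 = (h2 - config.latent_center) / config.latent_scale
    Z2 = sample_correlated_latents(np.tile(mu2[:, None], (1, N_ITEMS)), config.rho, rng)
    q2 = _categorize_items(Z2, config.thresholds)
    y2 = q2.sum(axis=1)

    # auxiliaries; length of stay depends on comorbidity and (negatively) on
    # the post-op residual, making it an outcome-correlated MAR driver
    los_log = (config.los_log_mean
               + config.los_comorb_effect * df["comorbidity_band"].to_numpy()
               + config.los_outcome_effect * eps
               + config.los_log_sd * rng.standard_normal(n))
    df["length_of_stay"] = np.round(np.exp(los_log), 1)
    df["waiting_time"] = np.round(rng.gamma(config.waiting_shape, config.waiting_scale, n), 1)
    df["previous_surgery"] = rng.binomial(1, config.previous_surgery_prob, n)
    df["pre_admission_q1"] = rng.binomial(1, config.pre_admission_prob, n)
    df["assisted_q2"] = rng.binomial(1, config.assisted_prob, n)
    df["lives_alone"] = rng.binomial(1, config.lives_alone_prob, n)

    df[Q1_ITEM_COLS] = q1
    df[Q2_ITEM_COLS] = q2
    df["R1"] = 1
    df["R2"] = 1
    df["y1_total"] = y1
    df["y2_total"] = y2

    truth = df.copy()
    truth["u_true"] = u
    truth["eps_true"] = eps

    patients = apply_missingness(truth, providers, config.missingness, rng)
    return providers, patients, truth


def _selection_logit(df: pd.DataFrame, providers: pd.DataFrame,
                     intercept: float, coefficients: dict[str, float]) -> np.ndarray:
    prov = providers.set_index("provider_id")
    merged = df.copy()
    merged["is_private"] = prov["is_private"].to_numpy()[df["provider_id"].to_numpy()]
    merged["is_teaching"] = prov["is_teaching"].to_numpy()[df["provider_id"].to_numpy()]
    merged["log_volume"] = np.log(prov["target_volume"].to_numpy())[df["provider_id"].to_numpy()]
    eta = np.full(len(df), float(intercept))
    for name, coef in coefficients.items():
        eta += coef * merged[name].to_numpy(dtype=float)
    return eta


def apply_missingness(truth: pd.DataFrame, providers: pd.DataFrame,
                      mconfig: MissingnessConfig,
                      rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Delete questionnaires and covariates from a complete cohort.

    Returns a new frame with R1/R2 set, item blocks deleted per
    questionnaire, MCAR covariate deletion applied, and totals recomputed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    df = truth.drop(columns=[c for c in ("u_true", "eps_true") if c in truth.columns]).copy()
    n = len(df)
    if not mconfig.enabled:
        return df

    phi = truth["provider_id"].map(
        dict(zip(providers["provider_id"], providers["phi_true"]))).to_numpy()

    eta1 = _selection_logit(df, providers, mconfig.q1_intercept, mconfig.q1_coefficients) + phi
    R1 = rng.binomial(1, expit(eta1))

    eta2 = _selection_logit(df, providers, mconfig.q2_intercept, mconfig.q2_coefficients) + phi
    eta2 = eta2 + mconfig.delta * (truth["y2_total"].to_numpy() - mconfig.y2_center)
    R2 = rng.binomial(1, expit(eta2))
    R2 = R2 * R1  # Q2 sent only to Q1 responders

    df["R1"] = R1
    df["R2"] = R2
    q1 = df[Q1_ITEM_COLS].to_numpy(dtype=float)
    q2 = df[Q2_ITEM_COLS].to_numpy(dtype=float)
    q1[R1 == 0, :] = np.nan
    q2[R2 == 0, :] = np.nan
    if mconfig.item_mcar > 0:
        q1[rng.random((n, N_ITEMS)) < mconfig.item_mcar] = np.nan
        q2[rng.random((n, N_ITEMS)) < mconfig.item_mcar] = np.nan
        q1[R1 == 0, :] = np.nan
        q2[R2 == 0, :] = np.nan
    df[Q1_ITEM_COLS] = q1
    df[Q2_ITEM_COLS] = q2

    if mconfig.ethnicity_mcar > 0:
        df.loc[rng.random(n) < mconfig.ethnicity_mcar, "nonwhite"] = np.nan
    if mconfig.duration_mcar > 0:
        df.loc[rng.random(n) < mconfig.duration_mcar, "symptom_duration"] = np.nan

    df["y1_total"] = score_totals_frame(q1)
    df["y2_total"] = score_totals_frame(q2)
    return df


def fit_selection_model(df: pd.DataFrame, providers: pd.DataFrame,
                        coefficients: dict[str, float], outcome_col: str | None,
                        y2_center: float = 38.0, indicator: str = "R2",
                        subset_r1: bool = True):
    """Refit the post-op selection model by ML logistic regression.

    Used to verify that the generator embeds the configured response
    log-odds (including delta when ``outcome_col`` names the true post-op
    total).  Returns the fitted statsmodels result; the delta estimate is
    ``res.params["outcome"]`` when an outcome column is given.
    """
    import statsmodels.api as sm

    sub = df[df["R1"] == 1] if subset_r1 else df
    eta_cols = {}
    prov = providers.set_index("provider_id")
    for name in coefficients:
        if name in ("is_private", "is_teaching"):
            eta_cols[name] = prov[name].to_numpy()[sub["provider_id"].to_numpy()]
        elif name == "log_volume":
            eta_cols[name] = np.log(prov["target_volume"].to_numpy())[sub["provider_id"].to_numpy()]
        else:
            eta_cols[name] = sub[name].to_numpy(dtype=float)
    X = pd.DataFrame(eta_cols, index=sub.index)
    if outcome_col is not None:
        X["outcome"] = sub[outcome_col].to_numpy(dtype=float) - y2_center
    X = sm.add_constant(X)
    return sm.Logit(sub[indicator].to_numpy(), X).fit(disp=False)
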