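"""Case-mix adjustment and indirect standardisation of provider outcomes.

The analysis model is a random-intercept linear model for the post-op
total score,

    y2_ij = alpha + X_ij beta + y1_ij gamma + u_j + eps_ij,
    u_j ~ N(0, sigma_u^2),  eps_ij ~ N(0, sigma_eps^2),

fitted by REML.  Provider performance is summarised by indirect
standardisation: the ratio of each provider's observed outcomes to its
case-mix-expected outcomes (fixed part only),

    rho_j = (1/n_j) sum_i y2_ij / yhat2_ij,    ytilde_j = rho_j * ybar2,

so ytilde_j is on the score scale and equals the national mean for a
provider performing exactly as its case mix predicts.  Estimates from
multiply imputed datasets are pooled by Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .design import CASE_MIX_NAMES, case_mix_matrix


def analysis_design(df: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects design: intercept, case-mix dummies, pre-op total."""
    X = case_mix_matrix(df)
    X.insert(0, "const", 1.0)
    X["y1_total"] = df["y1_total"].to_numpy(dtype=float)
    return X


@dataclass
class AnalysisFit:
    """REML estimates of the analysis model on one completed dataset."""

    params: pd.Series          # const, case-mix dummies, y1_total
    sigma_u: float
    sigma_eps: float
    u_hat: pd.Series           # shrunken provider effects, by provider_id
    ybar2: float               # national mean outcome in the dataset
    bse: pd.Series

    @property
    def alpha(self) -> float:
        return float(self.params["const"])

    @property
    def gamma(self) -> float:
        return float(self.params["y1_total"])

    @property
    def beta(self) -> pd.Series:
        return self.params[CASE_MIX_NAMES]

    def expected_outcome(self, df: pd.DataFrame) -> np.ndarray:
        """Case-mix expected outcome yhat2 (fixed part only, no u_j)."""
        X = analysis_design(df)
        return X.to_numpy() @ self.params.reindex(X.columns).to_numpy()


def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-provider sufficient statistics for the profiled REML criterion."""
    ids = pd.unique(groups)
    stats = []
    for j in ids:
        rows = groups == j
        Xj, yj = X[rows], y[rows]
        stats.append((Xj.T @ Xj, Xj.T @ yj, Xj.sum(axis=0),
                      float(yj.sum()), float(yj @ yj), int(rows.sum())))
    return ids, stats


def _reml_pieces(lam: float, stats, p: int):
    """A = X'V~^{-1}X, b = X'V~^{-1}y, y'V~^{-1}y and log|V~| for V~_j = I + lam J."""
    A = np.zeros((p, p))
    b = np.zeros(p)
    yy = 0.0
    logdet = 0.0
    for XtX, Xty, s, t, y2, n in stats:
        c = lam / (1.0 + n * lam)
        A += XtX - c * np.outer(s, s)
        b += Xty - c * t * s
        yy += y2 - c * t * t
        logdet += np.log1p(n * lam)
    return A, b, yy, logdet


def fit_analysis_model(df: pd.DataFrame) -> AnalysisFit:
    """Fit the random-intercept analysis model by REML.

    Profiled REML for the single variance component: the criterion is
    optimised over the variance ratio lambda = sigma_u^2 / sigma_eps^2
    (closed-form GLS for the coefficients at each lambda), which is exact,
    deterministic and fast for this model class.  Requires a completed
    dataset with at least two providers; raises on singular designs,
    naming the collinear columns.
    """
    if df["provider_id"].nunique() < 2:
        raise ValueError("need at least two providers to estimate provider effects")
    y = df["y2_total"].to_numpy(dtype=float)
    if np.isnan(y).any() or df["y1_total"].isna().any():
        raise ValueError("analysis model requires complete outcome totals")
    X = analysis_design(df)
    Xa = X.to_numpy()
    n, p = Xa.shape
    if np.linalg.matrix_rank(Xa) < p:
        _, R = np.linalg.qr(Xa)
        bad = [X.columns[i] for i in range(p) if abs(R[i, i]) < 1e-8]
        raise ValueError(f"singular design; collinear columns: {bad or 'undetermined'}")

    groups = df["provider_id"].to_numpy()
    ids, stats = _group_stats(Xa, y, groups)

    def neg_restricted_loglik(log_lam: float) -> float:
        lam = np.exp(log_lam)
        A, b, yy, logdet = _reml_pieces(lam, stats, p)
        beta = np.linalg.solve(A, b)
        rss = max(yy - b @ beta, 1e-12)
        sign, logdetA = np.linalg.slogdet(A)
        return (n - p) * np.log(rss) + logdet + logdetA

    # boundary-aware search: compare the interior optimum with lambda -> 0
    res = minimize_scalar(neg_restricted_loglik, bounds=(-14.0, 6.0), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    if neg_restricted_loglik(-30.0) <= res.fun + 1e-10:
        lam = 0.0

    A, b, yy, _ = _reml_pieces(lam, stats, p)
    beta = np.linalg.solve(A, b)
    rss = max(yy - b @ beta, 1e-12)
    sigma_eps2 = rss / (n - p)
    sigma_u2 = lam * sigma_eps2
    params = pd.Series(beta, index=X.columns)
    bse = pd.Series(np.sqrt(np.diag(np.linalg.inv(A)) * sigma_eps2), index=X.columns)

    # BLUP of the provider effects: shrunken mean residuals
    u_hat = {}
    for j, (XtX, Xty, s, t, y2, nj) in zip(ids, stats):
        resid_sum = t - s @ beta
        u_hat[j] = lam / (1.0 + nj * lam) * resid_sum
    return AnalysisFit(
        params=params,
        sigma_u=float(np.sqrt(sigma_u2)),
        sigma_eps=float(np.sqrt(sigma_eps2)),
        u_hat=pd.Series(u_hat),
        ybar2=float(np.mean(y)),
        bse=bse,
    )


def standardize_providers(df: pd.DataFrame, fit: AnalysisFit) -> pd.DataFrame:
    """Indirectly standardised outcome per provider.

    Returns a frame indexed by provider_id with columns
    ``n, rho, y_tilde, se``.  The standard error is the plug-in
    delta-method choice  ybar2 * sd(y2/yhat2) / sqrt(n_j),  treating ybar2
    and yhat2 as fixed.
    """
    yhat = fit.expected_outcome(df)
    if np.any(yhat <= 0):
        raise ValueError("case-mix expected outcome <= 0; standardisation ratio undefined")
    ratio = df["y2_total"].to_numpy(dtype=float) / yhat
    tmp = pd.DataFrame({"provider_id": df["provider_id"].to_numpy(), "ratio": ratio})
    grouped = tmp.groupby("provider_id")["ratio"]
    out = pd.DataFrame({
        "n": grouped.size(),
        "rho": grouped.mean(),
    })
    sd = grouped.std(ddof=1).fillna(0.0)
    out["y_tilde"] = out["rho"] * fit.ybar2
    out["se"] = fit.ybar2 * sd / np.sqrt(out["n"])
    return out


def population_sigma(df: pd.DataFrame, fit: AnalysisFit) -> float:
    """Between-patient SD of the standardised outcome, ybar2 * sd(y2/yhat2).

    This is the dispersion that sets the funnel control-limit width.
    """
    ratio = df["y2_total"].to_numpy(dtype=float) / fit.expected_outcome(df)
    return float(fit.ybar2 * np.std(ratio, ddof=1))


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of M completed-data estimates."""

    estimate: float
    var_within: float
    var_between: float
    var_total: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_total))

    @property
    def df(self) -> float:
        """Rubin's large-sample degrees of freedom for the pooled t interval."""
        if self.var_between <= 0 or self.m < 2:
            return np.inf
        r = (1.0 + 1.0 / self.m) * self.var_between / max(self.var_within, 1e-300)
        return (self.m - 1) * (1.0 + 1.0 / r) ** 2


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Classical Rubin's rules: T = V_W + (1 + 1/M) V_B."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.size == 0:
        raise ValueError("cannot pool an empty set of estimates")
    if est.shape != var.shape or np.any(var < 0):
        raise ValueError("estimates and variances must match and variances be >= 0")
    m = est.size
    vw = float(var.mean())
    vb = float(np.sum((est - est.mean()) ** 2) / (m - 1)) if m > 1 else 0.0
    return PooledEstimate(
        estimate=float(est.mean()),
        var_within=vw,
        var_between=vb,
        var_total=vw + (1.0 + 1.0 / m) * vb,
        m=m,
    )


def complete_cases(df: pd.DataFrame) -> pd.DataFrame:
    """Complete-case subset: both questionnaires fully observed plus covariates.

    Providers whose every patient is incomplete simply disappear from the
    subset (they cannot be assessed under complete-case analysis).
    """
    mask = (
        df["y1_total"].notna()
        & df["y2_total"].notna()
        & df["nonwhite"].notna()
        & df["symptom_duration"].notna()
    )
    return df[mask]
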