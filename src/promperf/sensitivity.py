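"""MNAR sensitivity analysis by importance re-weighting of MAR imputations.

After imputing under MAR, departures from MAR indexed by delta (the
log-odds of response per unit of the possibly-unobserved post-op score)
are explored without re-imputing: imputation m receives weight

    w~_m = exp(-delta * S_m),       S_m = sum over missing-outcome
                                          patients of the m-th imputed
                                          post-op total,

normalised to sum to one.  Positive delta means patients with better
outcomes respond more, so MAR imputations over-represent good outcomes;
the weights up-weight imputations whose imputed totals are small.  The
per-provider estimates are then pooled by weighted Rubin's rules,

    est = sum_m w_m theta_m,
    V_W = sum_m w_m sigma^2_m,   V_B = sum_m w_m (theta_m - est)^2,
    total = V_W + (1 + 1/M) V_B.

Note the between-imputation term uses the weighted (1/M-style) dispersion
with no M-1 correction, so at delta = 0 it is smaller than the classical
Rubin V_B by the factor (M-1)/M; this discrepancy is intentional and kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .casemix import PooledEstimate
from .funnel import assess_all, status_table


@dataclass
class DeltaGrid:
    """Ordered grid of delta values; must include 0 (the MAR reference)."""

    values: np.ndarray = field(default_factory=lambda: np.round(np.arange(-0.3, 0.31, 0.1), 10))

    def __post_init__(self) -> None:
        v = np.sort(np.asarray(self.values, dtype=float))
        if not np.isclose(v, 0.0).any():
            raise ValueError("delta grid must include 0")
        self.values = v


def imputation_weights(imputed_sums, delta: float) -> np.ndarray:
    """Normalised weights w_m from the imputed-outcome sums S_m.

    Stabilised in log space (sums are in the thousands on realistic
    cohorts, so raw exponentials would underflow); invariant to adding a
    constant to every S_m.
    """
    s = np.asarray(imputed_sums, dtype=float)
    if s.size == 0 or not np.all(np.isfinite(s)):
        raise ValueError("imputed sums must be a non-empty finite vector")
    log_w = -delta * s
    log_w -= log_w.max()
    w = np.exp(log_w)
    return w / w.sum()


def effective_sample_size(weights) -> float:
    w = np.asarray(weights, dtype=float)
    return float(1.0 / np.sum(w**2))


def pool_weighted(estimates, variances, weights) -> PooledEstimate:
    """Weighted Rubin's rules (see module docstring for the V_B convention)."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (est.shape == var.shape == w.shape):
        raise ValueError("estimates, variances and weights must have equal length")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    m = est.size
    pooled = float(np.sum(w * est))
    vw = float(np.sum(w * var))
    vb = float(np.sum(w * (est - pooled) ** 2))
    if effective_sample_size(w) < 1.0 + 1e-12 and m > 1:
        warnings.warn("imputation weights are degenerate (all mass on one imputation)")
    return PooledEstimate(estimate=pooled, var_within=vw, var_between=vb,
                          var_total=vw + (1.0 + 1.0 / m) * vb, m=m)


@dataclass
class SensitivityResult:
    """Per-delta re-weighted provider assessments and status tables."""

    grid: np.ndarray
    weights: pd.DataFrame            # one row per delta, columns w_1..w_M
    ess: pd.Series                   # effective sample size per delta
    assessments: dict[float, pd.DataFrame]
    tables: pd.DataFrame             # long table: delta x status counts
    national_means: pd.Series
    warnings_by_delta: dict[float, str]

    def table_wide(self) -> pd.DataFrame:
        """One row per delta, one count (and %) column per status."""
        rows = []
        for delta in self.grid:
            t = self.tables[self.tables["delta"] == delta]
            row = {"delta": delta}
            for _, r in t.iterrows():
                row[r["status"]] = int(r["n"])
                row[f"{r['status']}_pct"] = r["percent"]
            rows.append(row)
        return pd.DataFrame(rows)


def delta_sweep(per_imputation_estimates: list[pd.DataFrame],
                national_means, sigma_pops, imputed_sums,
                grid: DeltaGrid | None = None,
                response_rates: pd.Series | None = None,
                exact_sd: bool = False,
                ess_floor: float = 2.0) -> SensitivityResult:
    """Re-weight, re-pool, and re-classify across the delta grid.

    Parameters
    ----------
    per_imputation_estimates
        One ``standardize_providers`` frame per imputation (same provider
        index, columns n / y_tilde / se).
    national_means, sigma_pops
        Per-imputation national mean ybar2 and population SD of the
        standardised outcome.
    imputed_sums
        S_m: per-imputation sum of imputed post-op totals over the
        patients whose post-op outcome was missing.
    """
    if grid is None:
        grid = DeltaGrid()
    m = len(per_imputation_estimates)
    providers = per_imputation_estimates[0].index
    theta = np.column_stack([e["y_tilde"].to_numpy() for e in per_imputation_estimates])
    sig2 = np.column_stack([e["se"].to_numpy() ** 2 for e in per_imputation_estimates])
    volumes = per_imputation_estimates[0]["n"]
    ybar = np.asarray(national_means, dtype=float)
    spop = np.asarray(sigma_pops, dtype=float)

    weight_rows, ess_vals, tables, assessments = [], [], [], {}
    nat_means, warns = {}, {}
    for delta in grid.values:
        w = imputation_weights(imputed_sums, delta)
        weight_rows.append(w)
        ess = effective_sample_size(w)
        ess_vals.append(ess)
        if ess < ess_floor:
            warns[float(delta)] = (
                f"effective sample size of weights {ess:.2f} below floor {ess_floor}")

        est = theta @ w
        vw = sig2 @ w
        vb = ((theta - est[:, None]) ** 2) @ w
        frame = pd.DataFrame({
            "n": volumes.to_numpy(),
            "y_tilde": est,
            "se": np.sqrt(vw + (1.0 + 1.0 / m) * vb),
        }, index=providers)
        if response_rates is not None:
            frame["response_rate"] = response_rates.reindex(providers).to_numpy()
        mean_d = float(ybar @ w)
        sigma_d = float(spop @ w)
        assessed, table = assess_all(frame, mean_d, sigma_d, exact_sd=exact_sd)
        assessments[float(delta)] = assessed
        nat_means[float(delta)] = mean_d
        table = table.copy()
        table.insert(0, "delta", delta)
        tables.append(table)

    return SensitivityResult(
        grid=grid.values,
        weights=pd.DataFrame(weight_rows, index=grid.values,
                             columns=[f"w_{i+1}" for i in range(m)]),
        ess=pd.Series(ess_vals, index=grid.values),
        assessments=assessments,
        tables=pd.concat(tables, ignore_index=True),
        national_means=pd.Series(nat_means),
        warnings_by_delta=warns,
    )
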