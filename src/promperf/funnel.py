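"""Funnel-plot construction, provider classification, and the bonus rule.

Providers are plotted as standardised outcome against volume.  Control
limits around the national mean shrink with volume as

    mean +/- z * sigma_pop / sqrt(n),

with nominal 95% (z = 1.96) and 99.8% (z = 3.09) bands by default; the
literal 2- and 3-SD multipliers are available behind a flag.  A provider
outside the 95% band is an *alert*, outside the 99.8% band an *alarm*
(alarm supersedes alert), signed by the side of the mean.  A point exactly
on a limit is inside.

The best-practice-tariff (BPT) pay-for-performance rule: a provider is
eligible for the bonus iff it is not a negative alarm and it collected
PROMs for over 50% of its eligible patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

STATUSES = ["positive_alarm", "positive_alert", "in_control", "negative_alert", "negative_alarm"]

Z_95 = float(norm.ppf(0.975))      # 1.959964
Z_998 = float(norm.ppf(0.999))     # 3.090232


def z_multipliers(exact_sd: bool = False) -> tuple[float, float]:
    """(inner, outer) multipliers; exact_sd=True gives the literal 2 and 3."""
    return (2.0, 3.0) if exact_sd else (Z_95, Z_998)


@dataclass
class FunnelLimits:
    """Control limits evaluated on a grid of volumes."""

    mean: float
    sigma_pop: float
    volumes: np.ndarray
    z_inner: float = Z_95
    z_outer: float = Z_998
    lower_95: np.ndarray = field(init=False)
    upper_95: np.ndarray = field(init=False)
    lower_998: np.ndarray = field(init=False)
    upper_998: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma_pop <= 0:
            raise ValueError("sigma_pop must be positive")
        v = np.asarray(self.volumes, dtype=float)
        if np.any(v < 1):
            raise ValueError("volumes must be >= 1")
        self.volumes = v
        half = self.sigma_pop / np.sqrt(v)
        self.lower_95 = self.mean - self.z_inner * half
        self.upper_95 = self.mean + self.z_inner * half
        self.lower_998 = self.mean - self.z_outer * half
        self.upper_998 = self.mean + self.z_outer * half

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n": self.volumes,
            "lower_998": self.lower_998, "lower_95": self.lower_95,
            "mean": self.mean,
            "upper_95": self.upper_95, "upper_998": self.upper_998,
        })


def control_limits(mean: float, sigma_pop: float, volumes, exact_sd: bool = False) -> FunnelLimits:
    z_in, z_out = z_multipliers(exact_sd)
    return FunnelLimits(mean=mean, sigma_pop=sigma_pop,
                        volumes=np.atleast_1d(volumes), z_inner=z_in, z_outer=z_out)


def classify(y_tilde, n, mean: float, sigma_pop: float,
             z_inner: float = Z_95, z_outer: float = Z_998):
    """Status of provider points against the funnel bands.

    Vectorised; strict inequality for "outside", so a point exactly on a
    limit is inside.  Alarm supersedes alert.
    """
    y = np.atleast_1d(np.asarray(y_tilde, dtype=float))
    half = sigma_pop / np.sqrt(np.atleast_1d(np.asarray(n, dtype=float)))
    dev = y - mean
    # a point exactly on a limit is inside; the epsilon absorbs float error
    # in mean + z * half round trips
    eps = 1e-9 * np.maximum(1.0, np.abs(half))
    out = np.full(y.shape, "in_control", dtype=object)
    out[dev > z_inner * half + eps] = "positive_alert"
    out[dev > z_outer * half + eps] = "positive_alarm"
    out[dev < -(z_inner * half + eps)] = "negative_alert"
    out[dev < -(z_outer * half + eps)] = "negative_alarm"
    return out if out.size > 1 else str(out[0])


def bpt_eligibility(status, response_rate) -> bool | np.ndarray:
    """Bonus eligibility: not a negative alarm AND response rate over 50%."""
    status_arr = np.atleast_1d(np.asarray(status, dtype=object))
    rate = np.atleast_1d(np.asarray(response_rate, dtype=float))
    if np.any((rate < 0) | (rate > 1)):
        raise ValueError("response_rate must lie in [0, 1]")
    ok = (status_arr != "negative_alarm") & (rate > 0.5)
    return ok if ok.size > 1 else bool(ok[0])


def status_table(statuses) -> pd.DataFrame:
    """Five-row count/percentage table in the conventional display order."""
    s = pd.Series(list(statuses))
    counts = s.value_counts().reindex(STATUSES, fill_value=0)
    order = ["negative_alarm", "negative_alert", "in_control", "positive_alert", "positive_alarm"]
    counts = counts.reindex(order)
    return pd.DataFrame({
        "status": order,
        "n": counts.to_numpy(),
        "percent": np.round(100.0 * counts.to_numpy() / max(len(s), 1), 1),
    })


def assess_all(estimates: pd.DataFrame, mean: float, sigma_pop: float,
               exact_sd: bool = False, bpt_threshold: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every provider and build the status frequency table.

    ``estimates`` is indexed by provider_id with columns ``y_tilde``, ``n``
    and optionally ``response_rate`` (defaults to 1, i.e. BPT judged on
    performance only).  Volumes should be complete-case counts in CCA mode
    and full eligible counts in MI mode (the volume effect).
    """
    z_in, z_out = z_multipliers(exact_sd)
    df = estimates.copy()
    df["status"] = classify(df["y_tilde"].to_numpy(), df["n"].to_numpy(),
                            mean, sigma_pop, z_in, z_out)
    if "response_rate" not in df.columns:
        df["response_rate"] = 1.0
    df["bpt_eligible"] = (df["status"].to_numpy() != "negative_alarm") & \
                         (df["response_rate"].to_numpy() > bpt_threshold)
    return df, status_table(df["status"])


def plot_funnel(assessments: pd.DataFrame, mean: float, sigma_pop: float,
                exact_sd: bool = False, ax=None, path=None):
    """Optional funnel figure: provider points over shaded control bands."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    vmax = float(assessments["n"].max()) * 1.05
    grid = np.linspace(max(1.0, assessments["n"].min() * 0.5), vmax, 200)
    lim = control_limits(mean, sigma_pop, grid, exact_sd)
    ax.plot(grid, lim.upper_95, "C0--", lw=1, label="95% limits")
    ax.plot(grid, lim.lower_95, "C0--", lw=1)
    ax.plot(grid, lim.upper_998, "C3-", lw=1, label="99.8% limits")
    ax.plot(grid, lim.lower_998, "C3-", lw=1)
    ax.axhline(mean, color="k", lw=1)
    ax.scatter(assessments["n"], assessments["y_tilde"], s=14, c="C7", zorder=3)
    ax.set_xlabel("volume (patients)")
    ax.set_ylabel("standardised post-op score")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
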