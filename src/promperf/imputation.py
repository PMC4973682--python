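"""Multilevel latent-normal multiple imputation of ordinal items.

Each ordinal response k (an OHS item, or a categorical covariate treated
as ordinal) is represented by a latent normal variable

    Z_ijk = x_ij' b_k + u_jk + e_ijk,

cut at ordered thresholds to produce the observed category.  The level-1
errors e_ij have unit variances (the probit identification constraint)
and a single compound-symmetry cross-item correlation rho; the
provider-level effects u_jk are independent across items (the cross-item
level-2 correlation is fixed at zero to avoid over-parameterisation) with
item-specific variances tau_k^2.

The sampler is Metropolis-within-Gibbs:

1. latent Z: truncated-normal draw on the category interval for observed
   cells, unconstrained normal for missing cells, using the exact
   compound-symmetry conditionals across items;
2. coefficients B: matrix-normal conditional draw (flat prior);
3. provider effects: a shared factor v_j (one common shift across the
   item block, capturing the cross-item correlation of provider effects
   that a sum-score provider effect induces) plus item-specific w_jk,
   each from its normal conditional per provider (providers with no
   observed rows draw from the prior);
4. variance components tau_k^2 and omega^2: inverse-gamma conditionals
   (IG(0.001, 0.001) priors);
5. thresholds: random-walk Metropolis on the free cut-points (first
   cut-point fixed at 0 for identification) targeting the marginal
   ordinal likelihood given the current linear predictor, adapted to
   20-50% acceptance during burn-in;
6. rho: random-walk Metropolis on the compound-symmetry correlation
   given the latent residuals (closed-form CS likelihood).

Every ``thinning``-th post-burn-in state emits a completed dataset by
categorising missing-cell latents through the current thresholds.
Observed cells are never altered.

Two model patterns mirror the survey design: the Q1-pattern model imputes
pre-op items jointly with incomplete categorical covariates using
provider-level auxiliaries, and the Q2-pattern model imputes post-op
items from the completed pre-op score and patient-level auxiliaries,
fitted on pre-op responders only and applied to everyone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri

from .cohort import Q1_ITEM_COLS, Q2_ITEM_COLS
from .design import CASE_MIX_TERMS
from .scoring import score_totals_frame

_TINY = 1e-12


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class ImputationModelSpec:
    """One latent-normal model: which responses, which predictors."""

    pattern: str                                  # "q1" or "q2"
    responses: list[tuple[str, int]]              # (column, n categories)
    case_mix_sources: list[str]                   # fully-observed covariates entering X
    extra_predictors: list[str]                   # auxiliary columns entering X
    include_y1: bool = False

    def predictor_frame(self, df: pd.DataFrame) -> pd.DataFrame:
        cols = {"const": np.ones(len(df))}
        for name, src, level in CASE_MIX_TERMS:
            if src in self.case_mix_sources:
                vals = df[src].to_numpy(dtype=float)
                if np.isnan(vals).any():
                    raise ValueError(f"predictor '{src}' has missing values")
                cols[name] = (vals == level).astype(float)
        if self.include_y1:
            vals = df["y1_total"].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError("y1_total predictor has missing values")
            cols["y1_total"] = vals
        for name in self.extra_predictors:
            vals = df[name].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"predictor '{name}' has missing values")
            cols[name] = vals
        out = pd.DataFrame(cols, index=df.index)
        # constant columns (e.g. no teaching hospital in a small cohort) would
        # make the design singular; the intercept already spans them
        keep = ["const"] + [c for c in out.columns[1:] if out[c].nunique() > 1]
        return out[keep]

    def describe(self) -> dict:
        return {
            "pattern": self.pattern,
            "responses": [list(r) for r in self.responses],
            "case_mix_sources": self.case_mix_sources,
            "extra_predictors": self.extra_predictors,
            "include_y1": self.include_y1,
        }


def q1_model_spec() -> ImputationModelSpec:
    """Pre-op pattern: 12 items + ethnicity + symptom duration as responses;
    provider-level auxiliaries (ownership, teaching status, volume) plus
    length of stay and waiting time as predictors."""
    return ImputationModelSpec(
        pattern="q1",
        responses=[(c, 5) for c in Q1_ITEM_COLS] + [("nonwhite", 2), ("symptom_duration", 3)],
        case_mix_sources=["age_band", "male", "comorbidity_band", "imd_quintile"],
        extra_predictors=["length_of_stay", "waiting_time", "is_private", "is_teaching", "log_volume"],
    )


def q2_model_spec() -> ImputationModelSpec:
    """Post-op pattern: 12 items as responses; all case-mix covariates, the
    completed pre-op total, and patient-level auxiliaries as predictors."""
    return ImputationModelSpec(
        pattern="q2",
        responses=[(c, 5) for c in Q2_ITEM_COLS],
        case_mix_sources=["age_band", "male", "nonwhite", "comorbidity_band", "imd_quintile", "symptom_duration"],
        extra_predictors=["length_of_stay", "waiting_time", "previous_surgery",
                          "pre_admission_q1", "assisted_q2", "lives_alone"],
        include_y1=True,
    )


def with_provider_columns(df: pd.DataFrame, providers: pd.DataFrame) -> pd.DataFrame:
    """Attach is_private / is_teaching / log_volume to a patient frame."""
    prov = providers.set_index("provider_id")
    out = df.copy()
    idx = df["provider_id"].to_numpy()
    out["is_private"] = prov["is_private"].to_numpy()[idx]
    out["is_teaching"] = prov["is_teaching"].to_numpy()[idx]
    out["log_volume"] = np.log(prov["target_volume"].to_numpy(dtype=float))[idx]
    return out


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------

def _cs_inverse(rho: float, K: int) -> np.ndarray:
    """Closed-form inverse of the compound-symmetry correlation matrix."""
    lam1 = 1.0 + (K - 1) * rho
    return (np.eye(K) - (rho / lam1) * np.ones((K, K))) / (1.0 - rho)


def _cs_loglik(E: np.ndarray, rho: float) -> float:
    """Gaussian log-likelihood of residual rows under CS correlation."""
    n, K = E.shape
    lam1 = 1.0 + (K - 1) * rho
    lam2 = 1.0 - rho
    logdet = np.log(lam1) + (K - 1) * np.log(lam2)
    row_sums = E.sum(axis=1)
    quad = (np.sum(E * E) - (rho / lam1) * np.sum(row_sums**2)) / lam2
    return -0.5 * (n * logdet + quad)


def _split_rhat(trace: np.ndarray) -> float:
    """Split potential-scale-reduction statistic for a scalar trace."""
    x = np.asarray(trace, dtype=float)
    half = x.size // 2
    if half < 4:
        return np.nan
    chains = np.stack([x[:half], x[half:2 * half]])
    within = chains.var(axis=1, ddof=1).mean()
    between = half * chains.mean(axis=1).var(ddof=1)
    if within <= 0:
        return 1.0
    var_plus = (half - 1) / half * within + between / half
    return float(np.sqrt(var_plus / within))


class LatentNormalGibbs:
    """Metropolis-within-Gibbs sampler for the multilevel latent model.

    Parameters
    ----------
    Y : (n, K) float array of category codes with NaN for missing cells.
    ncats : number of categories per response column.
    X : (n, p) fully observed design matrix (with intercept).
    groups : (n,) provider index in 0..n_groups-1.
    n_groups : total number of providers (may exceed those present in Y).
    """

    def __init__(self, Y, ncats, X, groups, n_groups, rng,
                 prior_a: float = 0.001, prior_b: float = 0.001,
                 factor_loadings=None):
        self.Y = np.asarray(Y, dtype=float)
        self.n, self.K = self.Y.shape
        self.ncats = list(ncats)
        self.X = np.asarray(X, dtype=float)
        self.p = self.X.shape[1]
        self.groups = np.asarray(groups, dtype=int)
        self.J = int(n_groups)
        self.rng = rng
        self.prior_a, self.prior_b = prior_a, prior_b

        self.obs = ~np.isnan(self.Y)
        self.Ycat = np.where(self.obs, self.Y, -1).astype(int)
        self.any_missing = bool((~self.obs).any())

        XtX = self.X.T @ self.X
        self._Lx = np.linalg.cholesky(XtX)
        self._group_rows = [np.flatnonzero(self.groups == j) for j in range(self.J)]
        self._group_sizes = np.array([len(r) for r in self._group_rows])

        # state
        self.thresholds = []
        for k in range(self.K):
            M = self.ncats[k]
            cum = np.clip(np.cumsum(np.bincount(
                self.Ycat[self.obs[:, k], k], minlength=M))[:-1]
                / max(self.obs[:, k].sum(), 1), 0.01, 0.99)
            t = ndtri(cum)
            t = t - t[0]                           # identification: first cut-point at 0
            t = np.maximum.accumulate(t + np.arange(M - 1) * 1e-6)
            self.thresholds.append(t)
        self.B = np.zeros((self.p, self.K))
        self.W = np.zeros((self.J, self.K))       # item-specific provider effects
        self.V = np.zeros(self.J)                 # shared provider factor
        # the shared factor carries the provider's common shift across the
        # item block; responses with loading 0 (categorical covariates) keep
        # independent effects only
        if factor_loadings is None:
            factor_loadings = np.ones(self.K)
        self.loadings = np.asarray(factor_loadings, dtype=float)
        self.use_factor = bool(np.any(self.loadings != 0))
        self.tau2 = np.full(self.K, 0.1)
        self.omega2 = 0.1
        self.rho = 0.0 if self.K == 1 else 0.1
        self.Z = np.where(self.obs, self._init_latents(), 0.0)

        self._thr_scale = np.full(self.K, 0.05)
        self._thr_acc = np.zeros(self.K)
        self._thr_tries = np.zeros(self.K)
        self._rho_scale = 0.03
        self._rho_acc = 0
        self._rho_tries = 0
        self._trace: dict[str, list] = {"rho": [], "mean_tau2": [], "omega2": [], "mean_b": []}

    def _init_latents(self) -> np.ndarray:
        Z = np.zeros((self.n, self.K))
        for k in range(self.K):
            M = self.ncats[k]
            mid = (self.Ycat[:, k] + 0.5) / M
            Z[:, k] = ndtri(np.clip(mid, 0.02, 0.98))
        return Z

    # -- individual updates -------------------------------------------------

    def _bounds(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        t = self.thresholds[k]
        edges = np.concatenate(([-np.inf], t, [np.inf]))
        cat = np.clip(self.Ycat[:, k], 0, None)
        return edges[cat], edges[cat + 1]

    def _update_latents(self, Mlin: np.ndarray) -> None:
        K, rho = self.K, self.rho
        E = self.Z - Mlin
        S = E.sum(axis=1)
        if K > 1:
            denom = 1.0 + (K - 2) * rho
            c = rho / denom
            v = (1.0 - rho) * (1.0 + (K - 1) * rho) / denom
        else:
            c, v = 0.0, 1.0
        sd = np.sqrt(v)
        for k in range(K):
            S_minus = S - E[:, k]
            m = Mlin[:, k] + c * S_minus
            z = np.empty(self.n)
            obs = self.obs[:, k]
            if obs.any():
                lo, hi = self._bounds(k)
                a = ndtr((lo[obs] - m[obs]) / sd)
                b = ndtr((hi[obs] - m[obs]) / sd)
                u = self.rng.random(obs.sum())
                pr = np.clip(a + u * (b - a), _TINY, 1.0 - _TINY)
                z[obs] = m[obs] + sd * ndtri(pr)
            miss = ~obs
            if miss.any():
                z[miss] = m[miss] + sd * self.rng.standard_normal(miss.sum())
            E[:, k] = z - Mlin[:, k]
            S = S_minus + E[:, k]
            self.Z[:, k] = z

    def _update_B(self) -> None:
        target = self.Z - self.U[self.groups]
        B_hat = cho_solve((self._Lx, True), self.X.T @ target)
        G = self.rng.standard_normal((self.p, self.K))
        A = solve_triangular(self._Lx, G, lower=True, trans="T")
        R = np.full((self.K, self.K), self.rho) + (1.0 - self.rho) * np.eye(self.K)
        self.B = B_hat + A @ np.linalg.cholesky(R).T

    @property
    def U(self) -> np.ndarray:
        """Combined provider effects u_jk = v_j * l_k + w_jk."""
        return self.V[:, None] * self.loadings + self.W

    def _update_provider_effects(self) -> None:
        resid = self.Z - self.X @ self.B
        Rinv = _cs_inverse(self.rho, self.K) if self.K > 1 else np.eye(1)
        # shared factor v_j given w
        if self.use_factor:
            l = self.loadings
            lRl = float(l @ Rinv @ l)
            lR = l @ Rinv
            for j in range(self.J):
                rows = self._group_rows[j]
                nj = rows.size
                prec = 1.0 / self.omega2 + nj * lRl
                b = float(lR @ (resid[rows].sum(axis=0) - nj * self.W[j])) if nj else 0.0
                self.V[j] = b / prec + self.rng.standard_normal() / np.sqrt(prec)
        # item-specific effects w_jk given v
        Dinv = np.diag(1.0 / self.tau2)
        for j in range(self.J):
            rows = self._group_rows[j]
            nj = rows.size
            P = Dinv + nj * Rinv
            if nj:
                r = resid[rows].sum(axis=0) - nj * self.V[j] * self.loadings
                b = Rinv @ r
            else:
                b = np.zeros(self.K)
            L = np.linalg.cholesky(P)
            mean = cho_solve((L, True), b)
            draw = solve_triangular(L, self.rng.standard_normal(self.K), lower=True, trans="T")
            self.W[j] = mean + draw

    def _update_tau2(self) -> None:
        shape = self.prior_a + 0.5 * self.J
        rates = self.prior_b + 0.5 * np.sum(self.W**2, axis=0)
        self.tau2 = rates / self.rng.gamma(shape, 1.0, size=self.K)
        if self.use_factor:
            rate = self.prior_b + 0.5 * float(np.sum(self.V**2))
            self.omega2 = rate / self.rng.gamma(self.prior_a + 0.5 * self.J, 1.0)

    def _ordinal_loglik(self, k: int, t: np.ndarray, mu: np.ndarray) -> float:
        edges = np.concatenate(([-np.inf], t, [np.inf]))
        obs = self.obs[:, k]
        cat = self.Ycat[obs, k]
        m = mu[obs]
        pr = ndtr(edges[cat + 1] - m) - ndtr(edges[cat] - m)
        return float(np.sum(np.log(np.clip(pr, _TINY, None))))

    def _update_thresholds(self, Mlin: np.ndarray, adapt: bool) -> None:
        for k in range(self.K):
            M = self.ncats[k]
            if M <= 2:
                continue            # single cut-point, fixed at 0
            t = self.thresholds[k]
            prop = t.copy()
            prop[1:] = t[1:] + self._thr_scale[k] * self.rng.standard_normal(M - 2)
            self._thr_tries[k] += 1
            if np.any(np.diff(np.concatenate(([0.0], prop[1:]))) <= 0):
                continue
            mu = Mlin[:, k]
            log_ratio = self._ordinal_loglik(k, prop, mu) - self._ordinal_loglik(k, t, mu)
            if np.log(self.rng.random()) < log_ratio:
                self.thresholds[k] = prop
                self._thr_acc[k] += 1
        if adapt:
            self._adapt_scales()

    def _adapt_scales(self) -> None:
        for k in range(self.K):
            if self._thr_tries[k] >= 50:
                rate = self._thr_acc[k] / self._thr_tries[k]
                if rate > 0.5:
                    self._thr_scale[k] *= 1.2
                elif rate < 0.2:
                    self._thr_scale[k] *= 0.8
                self._thr_acc[k] = self._thr_tries[k] = 0
        if self._rho_tries >= 50:
            rate = self._rho_acc / self._rho_tries
            if rate > 0.5:
                self._rho_scale *= 1.2
            elif rate < 0.2:
                self._rho_scale *= 0.8
            self._rho_acc = self._rho_tries = 0

    def _update_rho(self, Mlin: np.ndarray) -> None:
        if self.K == 1:
            return
        lo = -1.0 / (self.K - 1) + 1e-3
        prop = self.rho + self._rho_scale * self.rng.standard_normal()
        self._rho_tries += 1
        if not (lo < prop < 0.995):
            return
        E = self.Z - Mlin
        log_ratio = _cs_loglik(E, prop) - _cs_loglik(E, self.rho)
        if np.log(self.rng.random()) < log_ratio:
            self.rho = prop
            self._rho_acc += 1

    # -- main loop ----------------------------------------------------------

    def run(self, iterations: int, burnin: int, thinning: int, n_draws: int,
            psr_bound: float = 1.2):
        """Run the chain; returns (completed category draws, state snapshots).

        Completed draws are (n, K) integer matrices; snapshots carry
        (B, U, rho, thresholds) for posterior-predictive imputation of
        rows outside the fitting sample.
        """
        if iterations // thinning < n_draws:
            raise ValueError(
                f"{iterations} iterations at thinning {thinning} yield fewer than {n_draws} states")
        draws, states = [], []
        total = burnin + iterations
        for it in range(total):
            in_burnin = it < burnin
            Mlin = self.X @ self.B + self.U[self.groups]
            self._update_latents(Mlin)
            self._update_B()
            self._update_provider_effects()
            self._update_tau2()
            Mlin = self.X @ self.B + self.U[self.groups]
            self._update_thresholds(Mlin, adapt=in_burnin)
            self._update_rho(Mlin)
            if not in_burnin:
                t = it - burnin
                self._trace["rho"].append(self.rho)
                self._trace["mean_tau2"].append(float(self.tau2.mean()))
                self._trace["omega2"].append(self.omega2)
                self._trace["mean_b"].append(float(self.B.mean()))
                if (t + 1) % thinning == 0 and len(draws) < n_draws:
                    draws.append(self._complete())
                    states.append({
                        "B": self.B.copy(), "U": self.U.copy(), "rho": self.rho,
                        "tau2": self.tau2.copy(),
                        "thresholds": [t_.copy() for t_ in self.thresholds],
                    })
        self._check_convergence(psr_bound)
        return draws, states

    def _complete(self) -> np.ndarray:
        out = self.Ycat.copy()
        for k in range(self.K):
            miss = ~self.obs[:, k]
            if miss.any():
                out[miss, k] = np.searchsorted(self.thresholds[k], self.Z[miss, k], side="left")
        return out

    def _check_convergence(self, bound: float) -> None:
        for name, tr in self._trace.items():
            r = _split_rhat(np.asarray(tr))
            if np.isfinite(r) and r > bound:
                warnings.warn(
                    f"potential scale reduction {r:.2f} for '{name}' exceeds {bound}; "
                    "consider more iterations", RuntimeWarning)

    def acceptance_rates(self) -> dict:
        return {
            "rho_scale": self._rho_scale,
            "threshold_scales": self._thr_scale.tolist(),
        }


def predictive_categories(state: dict, X: np.ndarray, groups: np.ndarray,
                          ncats: list[int], rng) -> np.ndarray:
    """Posterior-predictive ordinal draws for rows outside the fitted sample."""
    K = len(ncats)
    mu = X @ state["B"] + state["U"][groups]
    rho = state["rho"]
    R = np.full((K, K), rho) + (1.0 - rho) * np.eye(K)
    Z = mu + rng.standard_normal((X.shape[0], K)) @ np.linalg.cholesky(R).T
    out = np.empty(Z.shape, dtype=int)
    for k in range(K):
        out[:, k] = np.searchsorted(state["thresholds"][k], Z[:, k], side="left")
    return out


# ---------------------------------------------------------------------------
# imputation sets and the two-stage pipeline
# ---------------------------------------------------------------------------

@dataclass
class ImputationSet:
    """M completed patient frames plus sampler metadata."""

    datasets: list[pd.DataFrame]
    seed: int | None
    iterations: int
    thinning: int
    burnin: int
    spec: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def long_format(self) -> pd.DataFrame:
        frames = []
        for i, d in enumerate(self.datasets, start=1):
            f = d.copy()
            f.insert(0, "dataset_id", i)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, d in enumerate(self.datasets, start=1):
            d.to_csv(directory / f"imputation_{i:03d}.csv", index=False)
        manifest = {
            "m": self.m, "seed": self.seed, "iterations": self.iterations,
            "thinning": self.thinning, "burnin": self.burnin,
            "spec": self.spec, "diagnostics": self.diagnostics,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "ImputationSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        datasets = [pd.read_csv(p) for p in sorted(directory.glob("imputation_*.csv"))]
        if len(datasets) != manifest["m"]:
            raise ValueError(f"manifest lists {manifest['m']} datasets, found {len(datasets)}")
        return cls(datasets, manifest["seed"], manifest["iterations"],
                   manifest["thinning"], manifest["burnin"],
                   manifest.get("spec", {}), manifest.get("diagnostics", {}))


def _recompute_totals(df: pd.DataFrame) -> pd.DataFrame:
    df["y1_total"] = score_totals_frame(df[Q1_ITEM_COLS].to_numpy(dtype=float))
    df["y2_total"] = score_totals_frame(df[Q2_ITEM_COLS].to_numpy(dtype=float))
    return df


def fit_and_impute(patients: pd.DataFrame, spec: ImputationModelSpec, m: int,
                   iterations: int = 10_000, thinning: int = 100,
                   burnin: int = 1_000, seed: int | None = None,
                   providers: pd.DataFrame | None = None):
    """Fit one pattern model on ``patients`` and impute its responses.

    Returns (ImputationSet of frames with this pattern's responses
    completed, state snapshots).  With no missing cells among the
    responses the sampler is skipped and M identical copies are returned.
    """
    rng = np.random.default_rng(seed)
    df = patients
    if providers is not None:
        df = with_provider_columns(df, providers)
    cols = [c for c, _ in spec.responses]
    Y = df[cols].to_numpy(dtype=float)
    ncats = [nc for _, nc in spec.responses]

    if not np.isnan(Y).any():
        out = ImputationSet([patients.copy() for _ in range(m)], seed,
                            iterations, thinning, burnin, spec.describe(),
                            {"skipped": "no missing responses"})
        return out, []

    X = spec.predictor_frame(df).to_numpy()
    groups = df["provider_id"].to_numpy(dtype=int)
    n_groups = int(groups.max()) + 1 if providers is None else len(providers)
    loadings = np.array([1.0 if "item" in c else 0.0 for c in cols])
    sampler = LatentNormalGibbs(Y, ncats, X, groups, n_groups, rng,
                                factor_loadings=loadings)
    draws, states = sampler.run(iterations, burnin, thinning, n_draws=m)

    datasets = []
    for d in draws:
        comp = patients.copy()
        comp[cols] = d.astype(float)
        datasets.append(_recompute_totals(comp))
    out = ImputationSet(datasets, seed, iterations, thinning, burnin,
                        spec.describe(), sampler.acceptance_rates())
    return out, states


def impute_pipeline(patients: pd.DataFrame, providers: pd.DataFrame, m: int,
                    iterations: int = 10_000, thinning: int = 100,
                    burnin: int = 1_000, seed: int | None = None) -> ImputationSet:
    """Two-stage imputation producing M jointly completed datasets.

    Stage 1 (Q1 pattern) imputes pre-op items and incomplete categorical
    covariates for all patients.  Stage 2 (Q2 pattern) is fitted on
    pre-op responders with fully observed predictors and applied to
    everyone: fitted rows take their in-chain draws, all other rows take
    posterior-predictive draws from the aligned retained state using
    stage 1's completed covariates and pre-op score for that imputation.
    """
    ss = np.random.SeedSequence(seed)
    seed1, seed2 = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    spec1, spec2 = q1_model_spec(), q2_model_spec()
    stage1, _ = fit_and_impute(patients, spec1, m, iterations, thinning,
                               burnin, seed1, providers)

    q1_complete = patients["y1_total"].notna()
    pred_complete = patients["nonwhite"].notna() & patients["symptom_duration"].notna()
    fit_mask = (patients["R1"] == 1) & q1_complete & pred_complete
    fit_rows = patients[fit_mask]
    if fit_rows.empty:
        raise ValueError("no pre-op responders with complete predictors to fit the Q2 model")

    rng2 = np.random.default_rng(seed2)
    Y2 = fit_rows[Q2_ITEM_COLS].to_numpy(dtype=float)
    ncats2 = [nc for _, nc in spec2.responses]
    need_stage2 = patients[Q2_ITEM_COLS].isna().to_numpy().any()
    datasets = []
    if not need_stage2:
        for d1 in stage1.datasets:
            datasets.append(_recompute_totals(d1.copy()))
        diag2 = {"skipped": "no missing post-op responses"}
    else:
        X2 = spec2.predictor_frame(with_provider_columns(fit_rows, providers)).to_numpy()
        sampler = LatentNormalGibbs(Y2, ncats2, X2,
                                    fit_rows["provider_id"].to_numpy(dtype=int),
                                    len(providers), rng2,
                                    factor_loadings=np.ones(len(ncats2)))
        draws2, states2 = sampler.run(iterations, burnin, thinning, n_draws=m)
        diag2 = sampler.acceptance_rates()

        out_mask = ~fit_mask
        for d1, dr2, st in zip(stage1.datasets, draws2, states2):
            comp = d1.copy()
            comp.loc[fit_mask, Q2_ITEM_COLS] = dr2.astype(float)
            if out_mask.any():
                sub = comp[out_mask]
                Xo = spec2.predictor_frame(with_provider_columns(sub, providers)).to_numpy()
                cats = predictive_categories(st, Xo,
                                             sub["provider_id"].to_numpy(dtype=int),
                                             [5] * 12, rng2)
                comp.loc[out_mask, Q2_ITEM_COLS] = cats.astype(float)
            datasets.append(_recompute_totals(comp))

    # observed post-op cells are authoritative: restore them verbatim
    obs_q2 = patients[Q2_ITEM_COLS].notna().to_numpy()
    orig_q2 = patients[Q2_ITEM_COLS].to_numpy(dtype=float)
    for d in datasets:
        block = d[Q2_ITEM_COLS].to_numpy(dtype=float)
        block[obs_q2] = orig_q2[obs_q2]
        d[Q2_ITEM_COLS] = block
        _recompute_totals(d)

    return ImputationSet(datasets, seed, iterations, thinning, burnin,
                         {"stage1": spec1.describe(), "stage2": spec2.describe()},
                         {"stage1": stage1.diagnostics, "stage2": diag2})
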