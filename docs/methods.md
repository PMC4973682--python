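# Methods

This note records the models, the generative assumptions behind the
synthetic cohorts, and the numerical choices that were genuinely open.

## The analysis model and indirect standardisation

Provider outcomes are compared through a random-intercept linear model
for the post-operative total score,

    y2_ij = α + X_ij β + y1_ij γ + u_j + ε_ij,
    u_j ~ N(0, σ_u²),   ε_ij ~ N(0, σ_ε²),

with case-mix covariates X (age band, sex, ethnicity, comorbidity band,
deprivation quintile, symptom duration) and the pre-operative score y1.
Estimation is by REML.  Because the model has a single variance
component, the REML criterion is profiled analytically: for each
variance ratio λ = σ_u²/σ_ε² the GLS coefficients, the residual sum of
squares and the two log-determinants have closed forms from per-provider
sufficient statistics, and λ is found by bounded 1-D optimisation with
an explicit comparison against the λ = 0 boundary.  This is exact for
the model class, deterministic, and fast enough to sit inside replicate
studies; the test suite cross-checks coefficients, variance components,
standard errors and BLUPs against an independent general-purpose
mixed-model implementation.

Each provider is summarised by indirect standardisation:
ŷ2_ij = α̂ + X_ij β̂ + y1_ij γ̂ (fixed part only — including û_j would
force every ratio to 1 and erase the comparison), ρ̂_j the provider mean
of y2/ŷ2, and ỹ_j = ρ̂_j · ȳ2 on the score scale.  The within-dataset
standard error of ỹ_j is the plug-in choice ȳ2 · sd(y2/ŷ2)/√n_j with ȳ2
and ŷ2 treated as fixed; the same dispersion, ȳ2 · sd(y2/ŷ2) over all
patients, is the population σ that sets funnel-limit width, so provider
SEs and control limits are built from one consistent quantity.

## Funnel limits and classification

Control limits are mean ± z·σ/√n with z = 1.959964 (nominal 95%) and
z = 3.090232 (nominal 99.8%); the literal 2- and 3-SD multipliers are
available behind a flag (`exact_sd`).  Alarm supersedes alert; a point
exactly on a limit is inside (strict inequality, with a 1e-9 relative
epsilon so that a point constructed *as* mean + z·σ/√n classifies as
inside despite floating-point round trips).  No over-dispersion
adjustment is applied.  Best-practice-tariff eligibility requires not
being a negative alarm and collecting complete PROMs (both
questionnaires fully observed) for strictly more than 50% of eligible
patients; the denominator choice — both questionnaires rather than Q1
alone — is a declared convention, configurable via the threshold.

Under complete-case analysis a provider is judged at its complete-case
volume; under MI at its full eligible volume.  This "volume effect" is
deliberate and is the main driver of the CCA-versus-MI differences the
pipeline studies.

## The imputation model

Missing ordinal items and categorical covariates are imputed jointly
from a multilevel latent-normal model.  Response k of patient i in
provider j has a latent

    Z_ijk = x_ij' b_k + u_jk + e_ijk,

cut at ordered thresholds (first cut-point fixed at 0, intercept free;
a latent exactly on a cut-point belongs to the lower category).  The
level-1 errors have unit variances (probit identification) and a single
compound-symmetry correlation ρ across responses.  Provider effects
decompose as u_jk = v_j·l_k + w_jk: a shared factor v_j ~ N(0, ω²) with
loading 1 on every OHS item and 0 on categorical-covariate responses,
plus independent item-specific w_jk ~ N(0, τ_k²).  The shared factor is
essential for the profiling application: a provider that is genuinely
better or worse shifts all 12 items together, and a purely diagonal
level-2 covariance cannot carry that common shift into the imputed
values — in experiments it shrinks the imputed rows' provider signal
nearly to zero (the τ_k² chain collapses), which washes providers toward
the national mean and inverts the complete-case-versus-MI comparison.
The factor gives the level-2 covariance the printed one-cross-parameter
form at the cost of one extra variance component; setting the loadings
to zero recovers the diagonal model.

Two pattern models mirror the survey design.  The Q1-pattern model
imputes the 12 pre-op items jointly with incomplete ethnicity and
symptom-duration (as 2- and 3-category ordinal responses) for all
patients, with fully observed case-mix covariates plus the
pattern-specific auxiliaries: length of stay, waiting time, and the
provider-level ownership, teaching and (log) volume variables.  The
Q2-pattern model imputes the 12 post-op items given the completed
pre-op total, the full case mix, and patient-level auxiliaries (length
of stay, waiting time, previous surgery, pre-admission flag, assistance
flag, lives alone).  It is fitted on pre-op responders with fully
observed predictors and applied to everyone: fitted rows take their
in-chain draws; all other rows (pre-op non-responders, rows with
imputed covariates) take posterior-predictive draws at each retained
state, using the matching first-stage imputation's completed covariates
and pre-op score.  This chaining makes every patient complete in every
dataset, which the full-volume MI funnel requires.

### Sampler

Metropolis-within-Gibbs, per iteration: (1) latent draws — truncated
normal on the category interval for observed cells, unconstrained for
missing cells, using the exact compound-symmetry cross-response
conditionals (closed forms, unit-tested against dense linear algebra);
(2) coefficients B — matrix-normal conditional under a flat prior;
(3) v_j then w_j per provider from their normal conditionals (a provider
with no observed rows draws from the prior — documented behaviour);
(4) ω², τ_k² from inverse-gamma conditionals with IG(0.001, 0.001)
priors; (5) thresholds — random-walk Metropolis on the free cut-points
targeting the ordinal likelihood of the observed categories given the
current linear predictor, using the product of per-response marginals
(exact when ρ = 0, a working approximation otherwise — the exact joint
would need 12-dimensional normal probabilities per patient); (6) ρ —
random-walk Metropolis with the closed-form compound-symmetry Gaussian
likelihood of the latent residuals.  Proposal scales adapt toward
20–50% acceptance during burn-in only.  A split potential-scale-
reduction heuristic on scalar traces (ρ, mean τ², ω², mean of B) warns
above 1.2 but never fails a run.

Defaults follow common multilevel-MI practice: burn-in 1,000 before
10,000 sampling iterations thinned every 100th for M = 100 when run at
survey scale.  The analysis scripts and tests run reduced chains
(burn-in 100–350, M = 8–20); this is a problem-size choice for the
desk-scale cohorts, not a semantics change.  One caution found in
testing: imputing a provider with *no* observed post-op data depends
entirely on (B, thresholds, v_j) stationarity, and short burn-ins leave
a visible transient; the defaults above are chosen so that pipeline
runs are past it.

Observed cells are never altered; every completed dataset is fully
complete among the modelled variables; a fixed seed reproduces the
entire imputation set bitwise.

## The synthetic cohort generator

The generator is the study's data-generating twin.  Providers come
first: lognormal volumes, private/teaching flags, a true outcome effect
u_j ~ N(0, σ_u) and a true response-propensity effect φ_j ~ N(0, sd_φ).
Per patient, covariates are sampled at the published category
frequencies; a pre-op health score h1 (score units) produces the 12
pre-op items through the threshold model; the post-op linear predictor
α + Xβ + y1γ + u_j + ε (score units) produces the post-op items the
same way.  Item latents are (h − 24)/11.5 plus compound-symmetry noise
(ρ = 0.3); the 11.5 scaling makes the expected total's slope in h
approximately 1 at the centre of the scale.  Because four cut-points
cannot make the map linear everywhere — the instrument has a ceiling at
48, matching the left-skew of real post-op scores — the configured
score-scale coefficients are only approximately the estimands.  The
exact estimands are therefore *defined operationally* as the full-data
REML estimates at large n under the same configuration
(`studies.reference_estimands`), and parameter-recovery and coverage
tests target those.

Missingness is applied last, questionnaire-wise.  The post-op indicator
follows logit P(R2=1) = η0 + Wη1 + Zη2 + φ_j + δ(y2 − 38): a logistic
selection model whose δ is the log-odds of response per score unit
(δ = 0 is MAR; the centring at 38 only re-bases the intercept).  The
pre-op indicator has its own logistic model with provider-level
predictors and no outcome term by default; R2 is forced to 0 when
R1 = 0 because the post-op questionnaire is only sent to pre-op
responders.  Ethnicity and symptom duration are deleted MCAR at 11% and
39% to mimic the published observed fractions; optional independent
per-item deletion (default off) emulates item non-response, for which
no mechanism is documented.  Default calibration reproduces the
published descriptives loosely: pre-op 17.8 (8.6) vs 17.5 (8.4),
post-op 37.1 (8.8) vs 38.1 (9.5), response 63/54% vs 61/52%.  The
auxiliaries' generating distributions are invented (only means/SDs are
published); length of stay is made to depend on the outcome residual so
that auxiliary-driven MAR missingness is outcome-correlated — the
regime in which complete-case analysis is biased and auxiliary-aware MI
is not.

What the generator does *not* emulate: linkage failure as a distinct
mechanism (folded into Q1 non-response), multi-year cohorts, item-level
response styles, and any real-data covariance between case mix and
provider effects.  Passing tests therefore establish internal validity
of the methods under the stated model, not conclusions about any real
provider.

## MNAR sensitivity by re-weighting

After MAR imputation, departures are indexed by δ: imputation m gets
weight w̃_m = exp(−δ·S_m), S_m the sum of that imputation's imputed
post-op totals over missing-outcome patients (pre-op imputations do not
enter), normalised in log space (S_m is in the thousands; raw
exponentials underflow).  Weighted Rubin's rules follow the printed
convention exactly: V̄_B = Σ w_m(θ_m − θ̄_w)² with no M−1 correction, so
at δ = 0 the between component is (M−1)/M of the classical value — a
documented discrepancy that is asserted, not "fixed".  Weights are
global (one vector per δ, shared by all providers).  The effective
sample size 1/Σw_m² is reported per δ and a floor (default 2) attaches
a warning; at desk scale the weights degenerate quickly away from
δ = 0, which is the method's known behaviour and the reason the
published sweep stops at |δ| = 0.3.

## Evaluation studies

`promperf.studies` packages the replicate experiments: funnel coverage
under the null (no provider effect: the percentages inside the bands
match the nominal 95/99.8 levels); selection-model calibration
(refitting the logistic model on data generated at δ = 0.3 recovers a
response odds ratio of e^0.3 ≈ 1.35 per score unit); MAR recovery (100
cohorts of 20 providers × ~100 patients, M = 10: the Rubin interval for
γ covers the reference estimand at near-nominal rate while the
complete-case national mean is biased upward, because long-stay — hence
poorer-outcome — patients respond less); the MNAR comparison (CCA
flags fewer negative alarms than MI when missingness concentrates among
poor outcomes); and δ re-weighting validity (at the generating δ the
re-weighted national mean beats the equal-weight MAR mean).

## Known limitations

* The threshold-Metropolis target ignores the cross-response
  correlation (exact only at ρ = 0); with ρ ≈ 0.5 the thresholds carry
  a small approximation that the MCAR item-frequency and recovery tests
  bound in practice.
* The Q2-pattern model is fitted only on complete-predictor pre-op
  responders; rows imputed at stage 1 contribute to prediction but not
  to the stage-2 likelihood (a mild incompatibility, standard for
  chained approaches).
* Provider effects in the imputation model are exchangeable across
  providers; differential within-provider selection (MNAR at the
  provider level) attenuates them, which is precisely the regime the δ
  sweep is for.
* The weighted V̄_B convention makes δ = 0 variances slightly smaller
  than classical Rubin pooling (factor (M−1)/M on the between part).
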