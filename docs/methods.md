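# Methods

## The model

`mjm` fits a Bayesian multilevel joint model (MJM) for trials in which an
intervention is randomized at the group level (classrooms, clinics),
subjects are nested in groups, and two linked outcomes are recorded per
subject: a continuous longitudinal marker measured on a schedule, and a
time to event under administrative censoring.

**Longitudinal submodel** — a three-level linear mixed model.  For subject
j in group l at time t (years),

    y_jl(t) = m_jl(t) + eps,        eps ~ N(0, sigma_eps^2)
    m_jl(t) = x(t)' beta + z(t)' u_jl + v_l

with fixed effects `beta` (intercept, time trend, group-level treatment,
treatment-by-time interaction, optionally quadratic time), subject random
effects `u_jl ~ N(0, Sigma_u)` on intercept and slope, and a group random
intercept `v_l ~ N(0, sigma_v^2)`.

**Survival submodel** — a proportional-hazards model whose baseline hazard
is piecewise constant on a grid 0 = tau_0 < ... < tau_Q:

    lambda_jl(t) = lambda_q exp( omega' gamma + alpha * m_jl(t) + g_l ),
    t in [tau_{q-1}, tau_q)

The *current value* m_jl(t) of the noise-free trajectory links the two
submodels; `alpha` measures how strongly the marker level drives the
hazard, and the group frailty `g_l ~ N(0, sigma_g^2)` captures residual
between-group differences in risk.  Setting `multilevel=False` removes
v and g, giving the standard two-level joint model (JM) used as the
comparator for quantifying the cost of ignoring the group level.

**Poisson re-expression.**  The piecewise-exponential likelihood is carried
by interval-level pseudo-observations: each subject contributes, for every
interval entered, a record with binary outcome d (1 only in the interval
of an observed event), exposure t_jlq (time spent in the interval) and a
Poisson likelihood with offset log t_jlq,

    log mu_jlq = log t_jlq + log lambda_q + omega' gamma
                 + alpha * m_jl(t_eval) + g_l .

The two likelihoods are proportional — the exact offset constant is
`sum_{d=1} log t_jlq` — so posteriors over shared parameters coincide.
This identity is asserted exactly in the test suite against an
independently coded piecewise-exponential likelihood.

**Within-interval evaluation time.**  The piecewise construction does not
fix where inside an interval the current value is evaluated.  The default
`interval_start` (tau_{q-1}) matches splitting the follow-up consistently
with the measurement schedule so that interval starts coincide with
measurement occasions; `interval_mid` and `event_or_end` are selectable.
This choice matters at coarse grids (see "Known limitations").

## Priors

Weakly-informative defaults (all configurable through `PriorSpec`):
`beta_s, gamma_s, alpha ~ N(0, 1000)` (precision 0.001);
`sigma_eps^2 ~ Inverse-Gamma(0.01, 0.01)` (the prior targets the variance,
equivalently a Gamma(0.01, 0.01) prior on the precision — the common
BUGS-family convention; a variant targeting the SD is selectable);
`Sigma_u ~ Inverse-Wishart(I_p, p)`;
`sigma_v^2, sigma_g^2 ~ Inverse-Wishart(I_1, 1)`, which is exactly
Inverse-Gamma(1/2, 1/2) on the variance and is implemented through that
reduction; `lambda_q ~ Gamma(0.01, 0.01)` (shape, rate).

## Posterior computation

The posterior over parameters and random effects is sampled with a blocked
Metropolis-within-Gibbs kernel written for this model's structure:

* `(beta, v)` and each `u_jl` are proposed from their *exact* Gaussian
  conditionals under the longitudinal likelihood and priors and accepted
  with a Metropolis correction for the survival factor (through which they
  enter only via `alpha * m`).  With no association these steps are exact
  Gibbs draws — the conjugate normal–normal and Poisson–gamma sub-cases in
  the test suite exploit this to compare against closed-form posteriors.
* `sigma_eps^2`, `Sigma_u`, `sigma_v^2`, `sigma_g^2` and every `lambda_q`
  have conjugate conditionals and are drawn exactly.
* `alpha`, `gamma` and the frailties `g` use adaptive random-walk
  Metropolis (Robbins–Monro adaptation toward 44% acceptance, frozen after
  burn-in).  The `alpha` proposal shifts `log lambda_q` by
  `-d_alpha * mbar_q` (frozen per-interval reference means of m) to walk
  along the posterior ridge between the association and the hazard level.
* Exact "translation" Gibbs moves resample the likelihood-invariant
  directions of hierarchical models — e.g. `beta_0 + delta, v_l - delta`
  or `beta_time + delta, u1_jl - delta` — which are otherwise the slowest
  directions of a Gibbs sweep.  A matching joint shift of
  `(log lambda, g)` handles the hazard level against the mean frailty.

The kernel targets the density over the original (variance-scale)
parameters; an unconstrained parameterization (log variances, log hazard
pieces, log-diagonal Cholesky of Sigma_u) with exact Jacobians and a
hand-derived analytic gradient is exposed via
`MultilevelJointModel.unconstrained()` for gradient-based samplers, and is
verified against finite differences to 1e-5 relative error in the tests.

**Initialization** is a two-stage warm start (longitudinal least squares
for beta and the residual scale, crude per-subject intercept/slope spreads
for Sigma_u, event counts over exposure for lambda_q, random effects at
zero, group variances at 1/3), jittered per chain.  A non-finite
log-posterior at initialization raises an error with diagnostics.

**Workflow defaults** mirror the reference analysis: 3 chains, 100
adaptation sweeps, 4000 burn-in, thinning 150, 200 retained draws per
chain.  Convergence is declared when the split-chain Gelman–Rubin R-hat is
below 1.1 for all gated parameters (fixed effects, association, variance
components); the verdict is part of the fit report and non-converged
replicates are excluded (but counted) in study metrics.  ESS uses the
autocorrelation-sum estimator with Geyer pairing; it is reported, not
gated.  DIC uses the conditional-on-random-effects deviance
`D = -2 (loglik_long + loglik_surv)` with `p_D = Dbar - D(thetabar)`,
where `thetabar` plugs in posterior means of every sampled quantity — the
convention of BUGS-family samplers, stated explicitly because DIC variants
differ.

## The data generator

`mjm.simulate.generate_dataset` draws data from the model itself at the
study's generating values: fixed effects (16, 1.6, -0.8, -2), subject
variances 10/10 with zero correlation, residual variance 33, association
-0.2; design factors are the group-level variances (var_v in {5, 18},
i.e. group-level ICC 0.10/0.30 given var_u0=10 and var_eps=33; var_g in
{0.4, 1}), censoring targets {20%, 60%}, group counts {50, 100, 200} of
size 30, and interval counts Q in {11, 7, 3}.  Subjects are measured
every 6 months from 0 to 5 years (11 occasions) and followed 9 years for
the event; measurements strictly after the true event time are never
generated.  Half the groups (rounded down) are treated.

Event times invert the cumulative hazard: with a linear trajectory
m(t) = a + b t and Weibull baseline `lambda0(t) = scale*shape*t^(shape-1)`,

    Lambda(t) = scale * shape * exp(alpha a + g) *
                int_0^t s^(shape-1) exp(alpha b s) ds ,

solved for `Lambda(T) = -log U` by adaptive Gauss–Kronrod quadrature and
Brent root finding (tolerance 1e-8 years; closed forms for shape=1 and
b=0 serve as oracles in the tests).  Vectorized screening computes
Lambda(9) for all subjects via Gauss–Legendre quadrature after the
substitution s = x^2 (which removes the fractional-power endpoint
singularity for shape >= 0.5), so root finding runs only for subjects who
actually fail the censoring check.  The Weibull *shape* is not determined
by the study design; the package default is 1.5 (increasing hazard,
qualitatively matching the survival curves of the motivating cohort) and
is echoed in all outputs.  The *scale* is calibrated to the censoring
target by solving `E[exp(-scale*K)] = target` over a Monte-Carlo draw of
the random effects with common random numbers (a smooth, strictly
monotone function of the scale), with a fixed internal calibration seed so
the scale is a deterministic function of the design cell.

Seed management: one master seed per scenario spawns independent
substreams for treatment assignment, group effects, subject effects,
event-time uniforms and measurement noise, so the survival table is
bitwise invariant to the residual variance (asserted in the tests) and
every replicate is reproducible in isolation.

**What the generator does not emulate:** dropout or migration (censoring
is purely administrative), missing visits, measurement-schedule jitter,
floor/ceiling effects of bounded questionnaire scores, or informative
censoring.  Passing tests therefore demonstrate correctness of the
machinery and estimator behavior under the stated generative model, not
robustness to those real-data features.

## Study harness and problem sizes

The full 72-cell x 200-replicate design is cluster-scale by construction;
the package runs it through the same `run_study` entry point.  Desk-scale
presets (30 groups of 15 subjects, Q = 3, chains of a few thousand
sweeps) exercise every stage in minutes and are what the tests and the
acceptance script use; the acceptance script's paired MJM-vs-JM
comparison runs two replicates of the first full-scale design cell
(50 groups of 30, Q = 11, 20% censoring, var_v 5, var_g 0.4).  Replicate
counts and chain lengths at desk scale are chosen so each check's
Monte-Carlo error is small relative to the effect it asserts.

## Numerical choices

* Interval boundary times belong to the interval *ending* there, so no
  zero-exposure pseudo-record (undefined log offset) can arise; the final
  cut is closed at the administrative end of follow-up.
* Exposure conservation per subject holds to 1e-12 and event counts are
  conserved exactly through the split.
* Gauss–Legendre order 64 for the vectorized cumulative-hazard integral;
  adaptive quadrature (1e-10) plus Brent (1e-8) for per-subject event
  times; calibration root solved to 1e-12 on the log-scale.
* Survival Metropolis ratios use expm1 and reject non-finite proposals,
  so overflowing proposals cannot corrupt a chain.
* `cov_u01` has true value 0 in the study design, so its relative bias is
  undefined and reported as null.

## Known limitations

* At coarse interval grids (Q = 3) the within-interval evaluation of
  m(t) makes the hazard covariate a step approximation of a continuously
  declining trajectory.  Under heavy event-driven truncation of the
  longitudinal record this leaves residual attenuation in the control-arm
  time slope (beta100) and small shifts in alpha and the subject
  covariance — behavior that grows as Q falls, matching the reference
  simulation's reported pattern.  Q = 11 aligned with the measurement
  schedule essentially removes it for alpha, and beta101 (the
  treatment-by-time contrast) is robust throughout because the
  discretization affects both arms symmetrically.
* DIC is the only model-comparison criterion implemented (no WAIC/LOO).
* Only the current-value association is supported; shared-random-effects
  and current-slope linkages are out of scope.
* Survival covariates must be time-fixed subject- or group-level columns.
* The sampler is a single-machine implementation; the full factorial
  study is intended to be distributed one scenario per job.
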