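# Methods

## Model

`shrinksurv` fits a piecewise-exponential ("dynamic") survival model.  A
grid `S = {s0 = 0 < s1 < … < sJ}` partitions the time axis (relative to
each subject's origin); within interval `j = (s_{j-1}, s_j]` the hazard of
subject `i` is constant,

    λ_ij = exp( φ_{g(i)} f_j + β_{0j} + Σ_k z_ik β_kj ),

with the grouped-frailty term `φ_g f_j` present only when group labels are
supplied.  The log-hazard coefficients follow independent Gaussian random
walks,

    β_kj = β_{k,j-1} + w_kj,  w_kj ~ N(0, θ_k),   β_k0 ~ N(β_k, θ_k),

so each covariate's behaviour is summarised by two scalars: the initial
mean `β_k` and the innovation variance `θ_k`.  `θ_k = 0` freezes the effect
(a static coefficient); `β_k = θ_k = 0` removes the covariate.  Because the
model is an absolute-risk model, any posterior draw defines a complete
hazard for a new covariate vector, which is what prediction uses.

The grid is data-driven: a cut is placed after every `m`-th observed event
(default `m = 2`), so every interior interval carries the same amount of
event information.  Tied event times are collapsed to one candidate cut but
still count toward the tally, which prevents zero-length intervals.
Intervals are half-open on the left; a time equal to a grid point belongs
to the interval ending there.  Censored times beyond the last event extend
`sJ`.

## Shrinkage

Both `β_k` and `θ_k` carry global-local shrinkage:

* `θ_k | λ_kθ, τ_θ ~ Gamma(1/2, rate 1/(2 λ_kθ τ_θ))` with
  `λ_kθ ~ F(2a_θ, 2c_θ)`, `τ_θ ~ F(2c_θ, 2a_θ)` (triple gamma);
* `β_k | λ_kβ, τ_β ~ N(0, λ_kβ τ_β)` with the same F-scale hierarchy
  (normal-gamma-gamma).

The pole parameter `a` controls mass at zero, the tail parameter `c` tail
heaviness; both live in (0, 0.5) via scaled-beta hyperpriors
`2a ~ Beta(α_a, β_a)`, `2c ~ Beta(α_c, β_c)` and are learned by
MH-within-Gibbs.  Defaults set every first shape to 5 and every second
shape to 10, a prior that favours small `a` and `c` — a sharp peak at zero
with heavy tails, appropriate for sparse, possibly high-dimensional
settings.  Fixing `a = c = 0.5` recovers horseshoe-type behaviour; fixing
the local scales at 1 reduces the `β` prior to `N(0, τ_β)`.  The intercept
(baseline log-hazard) is included in both layers.

Each F scale is represented exactly as a ratio of independent
`Gamma(a, a) / Gamma(c, c)` variates.  Conditioning on the gamma factors
makes every scale conditionally conjugate (generalized-inverse-Gaussian or
gamma); `a` and `c` see the gamma factors' likelihood plus their scaled-beta
prior through a logit random walk whose scale adapts toward ~35% acceptance
during burn-in and is frozen afterwards.

## Estimation

Data augmentation makes the model conditionally Gaussian.  Each at-risk
(subject, interval) pair contributes an exposure `u_ij`; pairs the subject
survives get an exponential residual time (memorylessness), giving total
times `τ_ij` with `-ln τ_ij = z_i β_j + ε_ij`, `ε_ij` standard Gumbel.  A
10-component normal mixture — fitted once by weighted EM (equivalently, KL
minimisation from the target to the mixture) on a fixed quadrature grid
[-10, 15] and shipped as plain-text package data — approximates the Gumbel
density; its component indicators yield Gaussian pseudo-observations.  The
fit achieves |mean − γ| ≈ 5e-6, |var − π²/6| ≈ 7e-5 and a CDF sup-distance
≈ 9e-5, far inside the acceptance tolerances (0.01 / 0.02 / 0.01).

One property of this augmentation deserves emphasis: every censored
(subject, interval) pair behaves like a complete exponential
pseudo-observation, so the augmented data carry far more nominal
information than the observed events (tens of thousands of pairs versus a
few hundred events at typical sizes).  The conditionally Gaussian blocks
therefore move each coefficient's *global level* in very small steps.  The
sampler opens every sweep with an exact-likelihood remedy: a Metropolis
"level shift" per coefficient that proposes adding one constant to the
whole path (and its initial mean) and accepts against the exact
piecewise-exponential likelihood plus the initial-mean prior.  Placed
immediately before the augmentation redraw, the move targets the marginal
posterior and the subsequent exact conditional draw of the residual times
and indicators restores the joint — a standard collapsed-move composition.
Its proposal scales adapt per coefficient during burn-in.

The sweep order is fixed: (0) exact-likelihood level shifts, (1) residual
times, (2) mixture indicators,
(3) FFBS for the coefficient paths, (4) initial means, (5) innovation
variances, (6) local/global scales, (7) MH for a and c, (8) the factor
block.  Step (5) uses ancillarity-sufficiency interweaving: a centered GIG
draw of `θ_k` given the path, followed by one joint conjugate draw of all
`(β_k, ±√θ_k)` in the non-centered parameterisation (the standardised path
enters the pseudo-observation equation linearly), which keeps mixing
healthy when `θ_k` is shrunk toward zero.  The constant-coefficient
baseline model (`time_varying=False`) pins `θ` at the variance floor and
replaces (3)–(5) with a single conjugate regression draw of the constant
coefficient vector — its exact conditional in that limit.

The Kalman filter uses information-form measurement updates
(`P⁻¹ + Z'V⁻¹Z`) rather than sequential univariate Joseph-form updates:
same `O(n_j m²)` cost, symmetric covariances by construction, and the
marginal log-likelihood follows from the Woodbury identity without forming
an `n_j × n_j` matrix.  A variance floor of 1e-12 on `θ` keeps the
transition non-singular while shrinkage drives `θ → 0`; the initial state
is an extra latent node sampled in the backward pass so the `β_k`
conditional can see `β_k0`.

### Factor block

The factor `f_j` has conjugate normal conditionals per interval; loadings
`φ_g` are conjugate under their triple-gamma scale mixture (suffix `φ`,
same machinery as the `β` layer).  The log-variance path `h` of the
stochastic-volatility law of motion is linearised through
`ln(f_j² + 1e-8)` with a 10-component auxiliary mixture for `ln χ²₁`
(fitted with the same EM machinery on [-40, 8] and shipped as package
data), then sampled by a scalar AR(1) FFBS; `φ_sv` uses MH on `atanh(φ)`
under its translated-beta prior including the stationary term of `h_0`, and
`σ_f²` has a GIG conditional.  Sign identification (`φ_1 ≥ 0`) is enforced
post-hoc by flipping whole draws; products `φ_g f_j` are unchanged.  The
shared-frailty regime assumes `G < N`; `G = N` needs an explicit override.
Default SV hyperparameters `a_sv = 5, b_sv = 1.5, B_sv = 1` are
conventional weakly-informative values and fully configurable.

### Validation strategy

Every non-standard conditional is checked against an independent oracle:
FFBS against dense joint-Gaussian conditioning; the filter log-likelihood
against the dense marginal; the scale-layer Gibbs against 2-D quadrature of
`p(λ, τ | θ)`; the MH steps against direct prior samplers; the augmentation
against the exact exponential-likelihood identity.  A Geweke-style
successive-conditional test (data re-simulated from the model between full
sweeps on a 3-subject, 3-interval toy) validates the joint of the
augmentation, FFBS, mean and variance conditionals with the scale layer
pinned at `λ = τ = 1`.  With the full learned hierarchy the same test is
not informative at toy scale: tiny `θ` and tiny `λτ` are mutually
reinforcing under the F-tailed prior, so the chain's excursions through the
deep shrinkage basin are far longer than any feasible toy-scale run — a
mixing property, not a correctness defect, which is why the scale layer is
verified by exact quadrature instead.

## Prediction and evaluation

Survival times for a new covariate vector are simulated by pairing a
uniformly chosen posterior draw with one exact inversion of the
piecewise-linear cumulative hazard (truncated-exponential within-interval
times).  Beyond `sJ` the last interval's hazard is carried forward by
default; `horizon_rule="extend_rw"` instead propagates the random walk one
step with innovation variances `θ` before computing the tail hazard.  New
subjects without a group omit the factor term (marginal prediction); with a
group label the group's loading and factor path are included.  The risk
score is the negative mean of (by default) 10,000 predictive survival
times; Harrell's C counts a pair comparable when the earlier observed time
is an event, concordant when that subject has the larger score, with score
ties worth one half.

## Synthetic-data generator

The generator emulates the simulation study's conditions.  Trajectories on
a fine grid (5000 steps of 0.02 over a 100-unit horizon):

* constant: `β_k ~ Uniform(−5, 5)` drawn once (the study does not state the
  constant magnitudes; this matches the other kinds' amplitude 5 and has
  variance 25/3);
* sinusoidal: `5 sin(2π t/100 − s_k)`, `s_k ~ U[0, 1.6π]` — the phase is
  read in radians inside the sine by default (`phase_in_radians=False`
  switches to a shift in time units, since the printed formula is ambiguous);
* tanh: `d_k · 5 tanh(5(t − i_k)/100)`, `d_k = ±1`, `i_k ~ U[0, 100]`.

`⌊s·K⌋` randomly chosen trajectories are zeroed.  Covariates are standard
normal.  The hazard at step `t` is `b(t) exp(Σ_k z_ik β_k(t))` with the
baseline rescaled by the cross-sectional mean multiplier,
`b(t) = c / mean_i exp(Σ_k z_ik β_k(t))`.  Given covariates and
trajectories, the probability of surviving the horizon has the closed form
`mean_i exp(−c A_i)`, monotone in `c`, so the single global constant is
found by Brent root-finding at the 30% censoring target — exact and
deterministic, no pilot simulation needed; calibration is per dataset.
Censoring is administrative at the horizon (the study states the
proportion, not the mechanism; this is the simplest mechanism consistent
with the stated grid).

What the generator does *not* emulate: covariate correlation or
non-Gaussian covariates, random (non-administrative) censoring, competing
risks, delayed entry, measurement error.  Passing tests therefore speak to
the estimator's behaviour under independent Gaussian covariates with a
single administrative-censoring horizon, not to robustness against those
features of real data.

## Numerical choices

* variance floor 1e-12 on `θ` inside the filter; `ln f²` offset 1e-8;
* linear predictors clipped at ±500 before exponentiation (active only in
  early unconverged sweeps or absurd prior tails);
* GIG draws use `scipy.stats.geninvgauss` with exact gamma / inverse-gamma
  limiting laws when one GIG parameter degenerates below 1e-12;
* Cholesky factorisations fall back to an eigenvalue square root for
  numerically semidefinite conditionals; a jitter of 1e-12 is added first;
* subjects with observed time exactly 0 are rejected at construction;
* degenerate all-zero standardised paths revert the signed scale to its
  prior automatically through the conjugate regression.

## Problem sizes used in the test suite

The simulation-study protocol is exercised at desk scale, chosen as the
smallest sizes at which the qualitative findings are stable: the
selection check runs one constant-DGP dataset (N=500, K=10, s=0.9) with
5,000/1,000/5 chains; the model-comparison check runs five paired
sinusoidal replicates (N=120 train, 200 test, K=10) at 2,000/500/3 with
500 predictive draws per risk score; oracle-based distributional checks
use 1e5 draws.  The full study grid (`run_study`) accepts the original
settings (50 replicates, 50,000/10,000/10, 10,000 predictive draws)
unchanged; they are simply not run inside the test suite.

## Known limitations

* `θ_k` is constant over time: the model decides globally between static
  and time-varying effects and cannot express local activation windows.
* No left truncation, interval censoring or competing risks.
* Single factor only, with time-invariant loadings.
* The Gumbel mixture is an approximation; its error (CDF sup-distance
  ~1e-4) is negligible relative to Monte-Carlo error at desk scale but is
  not corrected by an exact MH step.
* Deep-shrinkage mixing: chains can dwell long in the `θ ≈ 0` basin; the
  interweaving step mitigates but does not eliminate this, and short chains
  may understate uncertainty about weakly identified `θ_k`.
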