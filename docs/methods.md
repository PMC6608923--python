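# Methods

This note records the modeling assumptions, numerical choices, and design
decisions behind `sutse`, and what the synthetic-data tests do and do not
establish about real data.

## Model

The observation vector is the natural log of C monthly counts. Gaussianity
on the log scale is an assumption, not a consequence: it is reasonable when
counts are large (hundreds and up, so that a lognormal approximates the
count distribution well) and untenable for rare events, where a Poisson
observation model (a dynamic *generalized* linear model) would be needed.
The package checks the assumption empirically with an energy test of
multivariate normality on the residuals rather than assuming it silently.

Each series carries a local linear trend in which only the slope receives
noise. This makes the level an integrated random walk: trends are smooth,
and a "trend change" is exactly a slope innovation `δ̃_t`. The C-vector of
slope innovations has unstructured covariance `Σ_δ̃ = diag(γ) Ω_δ diag(γ)`;
`Ω_δ` is the object of scientific interest (evolution correlations), and
the partial correlations derived from `Σ_δ̃⁻¹` give conditional trend
dependence. Observation errors are likewise unstructured
(`Σ_ε = diag(σ) Ω_ε diag(σ)`), capturing transient same-month co-deviation.

Seasonality uses the Fourier form: `q ≤ s/2` harmonic/conjugate pairs per
series, propagated by rotation blocks of the transition matrix; at
`q = s/2` the final harmonic has frequency π and collapses to one
alternating coordinate with transition −1. The state dimension is
`C(2+2q)` in general and `C(2+2q−1)` at `q = s/2` (for C = 6, s = 12:
12 states trend-only, 78 at q = 6). Seasonal states receive no evolution
noise — the seasonal pattern is fixed in time, which keeps it from
absorbing trend variation. The harmonic phase origin is the first observed
month (t = 1); any consistent origin is equivalent because the phase is
absorbed into the initial seasonal state.

## Parameters, units, defaults

| parameter | meaning | units | default/prior |
|---|---|---|---|
| σ_i | observation error sd, series i | log counts | half-Cauchy Ca⁺(0, 1) |
| γ_i | slope innovation sd | log counts / month² | half-Cauchy Ca⁺(0, 1) |
| Ω_ε, Ω_δ | error / evolution correlations | — | LKJ(v = 1), uniform |
| κ | initial-state prior variance | (log counts)² | 10⁷ |
| q | seasonal harmonics | — | 4 (configurable 0…s/2) |
| s | seasonal period | months | 12 |

The half-Cauchy scale of 1 is weakly informative on the log-count scale
(typical posteriors concentrate near σ ≈ 0.05, γ ≈ 0.001–0.01, far inside
the prior's bulk). LKJ with v = 1 is uniform over valid correlation
matrices but still shrinks individual correlations toward zero — each
marginal is a rescaled Beta(d/2, d/2) — so sign probabilities are mildly
conservative. q = 4 is the default because DIC comparisons on data of this
kind favor it over the full q = 6 while leaving correlation inference
essentially unchanged; both are available.

## Inference

The posterior over `(σ, γ, Ω_ε, Ω_δ)` is evaluated with the latent states
integrated out exactly by the Kalman filter, on an unconstrained scale:
log for standard deviations, and the canonical partial-correlation /
Cholesky bijection (tanh of free parameters) for correlation matrices, with
the analytic log-Jacobian (verified against finite differences in the test
suite).

The built-in sampler is an **adaptive independence Metropolis–Hastings**
kernel: BFGS (restarted, with finite-difference steps held above the
filter's numerical noise floor) finds the posterior mode; an explicit
central-difference Hessian at the mode provides the initial proposal
covariance; during warm-up the multivariate-t (df = 20) proposal is
re-estimated from the chain's own history, and the frozen sampling-phase
proposal is a mixture of the adapted component and the mode–Hessian
component (so a poorly adapted component cannot collapse the acceptance
rate), plus a 2% random-walk mixture for tail robustness. On the
low-dimensional, near-Gaussian unconstrained posteriors this model class
produces, acceptance rates run 0.65–0.75 and effective sample sizes exceed
40% of the draw count. The sampler contract is backend-agnostic: anything
that targets `exp(log_posterior_hyper)` and passes the convergence gates
(split-chain Gelman–Rubin upper bounds < 1.01, correlation-parameter ESS
> 5000 at the default 3 × (1000 warm-up + 4000 kept) configuration) is an
acceptable replacement. Chain initial points are drawn from the priors with
standard deviations truncated to (0.001, 2); per-chain generators are
spawned deterministically from the configured seed, so runs are bitwise
reproducible.

State trajectories come from FFBS. Because `Σ_δ = R Σ_δ̃ Rᵀ` is rank
deficient (rank C in a p-dimensional state), the backward pass samples the
C-dimensional slope innovations conditional on the next state,
`δ̃_{t+1} | θ_{t+1}, Y_{1:t}`, and reconstructs
`θ_t = G⁻¹(θ_{t+1} − R δ̃_{t+1})` deterministically. This is exact, never
inverts the singular p×p innovation covariance, and degrades gracefully:
at γ = 0 the innovations are exactly zero and every draw has exactly
constant slopes.

**DIC focus.** DIC is computed on the *marginal* deviance
`D(Σ) = −2 log p(Y | Σ_ε, Σ_δ)` (states integrated out), with the plug-in
at the posterior mean of the covariance matrices on the natural (Σ) scale.
Other focuses (conditional on states) give different numbers; the choice is
recorded in output metadata. Note that under the diffuse `N(0, κI)` initial
prior the marginal deviance contains a `p·log κ` term, so DIC comparisons
across models with different state dimensions include a substantial
dimension penalty from the prior itself; a seasonal model is preferred only
when the seasonal signal is strong enough to pay it.

## Numerical choices

- Joseph-form covariance updates and per-step symmetrization in the filter;
  innovations solved by Cholesky, never explicit inversion. A compiled
  (numba) path handles fully observed data; the pure-numpy path is the
  reference implementation and handles missing entries (skipped in the
  update, propagated through prediction). The two paths agree to ~1e-7.
- Diffuse initialization uses the proper prior `N(0, 10⁷ I)` exactly, not
  an exact-diffuse filter. At κ = 10⁷ double-precision cancellation limits
  absolute log-likelihood accuracy to about 1e-6 (verified against a
  60-digit reference); likelihood *differences* across parameter values —
  the only thing inference uses — are stable to far better than that, and
  doubling κ changes them by < 0.01. Oracle-equivalence tests therefore run
  at moderate κ where both sides are exact to 1e-10.
- Backward-pass solves use Cholesky with an eigenvalue-clipped fallback so
  degenerate limits (γ → 0, σ → 0) remain usable.
- One-sided 95% lower credible bounds are the ⌈0.05·K⌉-th order statistic
  of the pooled draws (all chains pooled; the pooled count is what the
  sign-probability estimator divides by). Count-scale smoothed bands
  exponentiate each draw before taking pointwise means and 2.5/97.5%
  quantiles — the mean of exponentials, deliberately not the exponential of
  the mean.
- The smoothed-series ambiguity (trend only vs. full fit including
  seasonality) is resolved by exposing both components; the CLI writes both.
- Energy test: residuals are centered and whitened by their sample
  covariance; `E‖a − Z‖` uses the closed hypergeometric form; the p-value
  is a parametric bootstrap from the standard normal (default 500
  resamples, each standardized the same way as the data).
- LKJ sampling uses the partial-correlation vine (layer-k partials are
  rescaled Beta(v + (d−1−k)/2, ·)); the normalized LKJ density constant is
  validated against the closed-form d = 2 integral.

## Synthetic data: what it emulates and what it does not

The generator runs the model's own equations forward and rounds
`exp(Y)` to integer counts (clipped below at 1). Rounded lognormal counts
keep generator and model consistent; Poisson sampling would introduce a
model mismatch that belongs to the DGLM extension, which is out of scope.
The `chicago_like_preset` emulates the scale of a large-city
reported-incident dataset: six series, 120 months, counts predominantly in
[500, 5000], declines of 0.3–1.2 log units per decade, strong annual
seasonality in half the series and weak in the rest, and a mix of positive,
negative, and zero evolution correlations. Initial slopes are kept at
|slope| ≤ 0.01/month and slope-innovation sds at ~5–9 × 10⁻⁴ so ten-year
trajectories stay in the realistic count band.

Because the generator satisfies the model's assumptions exactly, passing
tests demonstrate correctness of the *inference machinery* (filtering,
sampling, summarization) and achievable precision at realistic sample
sizes. They do not establish robustness to real-data features the generator
omits: integer rounding is the only non-Gaussian feature, and there are no
outliers, calendar effects, recording-practice discontinuities, or
non-annual cycles.

## Problem sizes used in the checks

Oracle comparisons use C = 2, T = 6–8 (the dense joint Gaussian is built
explicitly); FFBS moment checks use 20,000 vectorized draws. Parameter
recovery uses 10 replicates of C = 3, T = 120, q = 2 with a true evolution
correlation of 0.8 and reduced chains (3 × 500 + 1000); convergence gates
run the full default configuration on a C = 2, T = 120 dataset; the
end-to-end pipeline check fits the six-series preset with shortened chains.
These sizes make the whole suite run in a few minutes on one CPU while
keeping every check at full strength where exactness (rather than Monte
Carlo resolution) is what is being tested.

## Known limitations

- Gaussian observation model only; no Poisson/DGLM path.
- No exact-diffuse or square-root filtering; extremely large κ trades
  absolute log-likelihood accuracy for simplicity (differences are stable).
- The independence-MH sampler is tuned for the low-dimensional marginal
  posteriors of this model class (≤ ~42 parameters in practice); very high
  C would favor a gradient-based backend.
- Trading-day/calendar effects, time-varying F or G, and spatial structure
  are not modeled.
- No multiple-testing adjustment across correlation pairs is applied; the
  tables report per-pair posterior summaries.
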