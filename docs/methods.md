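# Methods

## Model

`nrffit` fits a two-stage generative model of a single voxel's (or ROI's)
BOLD time series `y` of length `T` at repetition time `TR`:

1. **Neural response function (NRF).** Stimulus events at onsets `t_j`
   contribute weighted deltas to a neuronal drive on a microtime grid of
   spacing `dt = TR/16`:

   - *categorical*: weight `beta_k` for an event of condition `k`;
   - *exponential repetition decay*: `beta_k * exp(-a_k * r_j)` with lag
     `r_j` counted in items (number of preceding same-condition stimuli in
     the train) or in seconds since the train's first same-condition
     stimulus; `a_k > 0` is suppression, `a_k < 0` facilitation;
   - *Gaussian pRF over tone frequency*: `beta * exp(-((f_j-mu)/sigma)^2/2)`;
   - *Ricker (Mexican-hat) pRF*: `beta * (1-u^2) exp(-u^2/2)`,
     `u = (f_j-mu)/sigma` — a Gaussian with surround suppression.

   A constant baseline `beta_0` adds to every microtime bin. Event deltas
   are discretized as one-bin pulses of height equal to their weight (the
   convention of the GLM/DCM software lineage). This makes amplitude
   estimates comparable only at a fixed `dt`; the package default is
   `TR/16` everywhere. A unit-area discretization was evaluated and
   rejected: it ties the physical impulse per event to `1/dt` and pushes
   the vasodilatory feedback loop below zero inflow for weights of a few
   units.

2. **Hemodynamics.** The drive enters the extended Balloon model
   (vasodilatory signal `s`, inflow `f_in`, volume `v`,
   deoxyhemoglobin `q`; `f_out = v^(1/alpha)`;
   `E(f,rho) = (1-(1-rho)^(1/f))/rho`) with fixed constants
   `gamma = alpha = rho = 0.32`, and the static BOLD observation
   `y = V0[k1(1-q) + k2(1-q/v) + k3(1-v)]` with `V0 = 4`, `r0 = 25`,
   `theta0 = 40.3`, `TE = 0.04 s`. Free hemodynamic parameters are
   `kappa = 0.64 e^{theta_kappa}` (signal decay, 1/s),
   `tau = 2 e^{theta_tau}` (transit time, s) and
   `epsilon = e^{theta_epsilon}` (intra/extravascular ratio), each latent
   having prior `N(0, 0.135)` (0.135 is a variance).

Bounded pRF parameters carry uniform priors implemented as standard-normal
latents pushed through the normal CDF:
`mu in (0, 20000) Hz`, `sigma in (1, 5000) Hz`, `beta in (0, 20)`.
Repetition parameters have Gaussian priors `beta_k ~ N(1, 10)`,
`a_k ~ N(0, 1)`, `beta_0 ~ N(0, 10)`.

## Integration

The drive is piecewise-constant per microtime bin, so the default
integrator takes one classical RK4 step per bin (numba-compiled; optional
`n_sub` substeps). Volumes are sampled at `t_n = n*TR` (end of volume,
configurable offset), starting from the zero-drive rest state
`(0, 1, 1, 1)` — a nonzero `beta_0` therefore produces an onset transient,
as no baseline-adjusted steady state is defined for this model.

Positivity: inflow is projected onto `[1e-6, inf)` after every step (no
backflow); steps that push `v` or `q` below `1e-6` are rejected and
retried with up to 256x finer substeps, then projected. Only numerically
non-finite states abort a trajectory (NaN output, which the optimizer
treats as an infeasible point). An adaptive stiff backend (`LSODA`,
rtol 1e-6 / atol 1e-8) is kept as an independent cross-check; the two
backends agree to better than 1e-5 RMS on test schedules, and quadrupling
the RK4 substeps moves predictions by < 1e-6 RMS, so integrator error is
negligible relative to the fMRI noise floor.

## Inference: variational Laplace

The observation model is `y = g(theta) + e`, `e ~ N(0, exp(-lambda) I_T)`,
with Gaussian prior `N(mu_theta, C_theta)` and hyperprior
`lambda ~ N(0, 1)`. The posterior is approximated by a factorized Gaussian
`q(theta) q(lambda)`, updated by coordinate ascent on the variational
energies:

- **theta step.** The gradient and curvature of theta's energy are built
  from a central-difference Jacobian `J` of the forward map (step
  `0.01 * prior SD` per parameter): `j = w J'r - C^-1 (m - mu)`,
  `H = -(w J'J + C^-1)` with `w = E_q[e^lambda]` — the regularized
  Gauss-Newton form, negative definite everywhere and exact for linear
  models. (A full central-difference Hessian of the energy is available as
  `curvature="energy"`; its residual-curvature terms make it indefinite
  far from the optimum, which in practice stalls the damped update — the
  reason it is not the default.) The update is
  `m <- m - (H - delta I)^-1 j` with Levenberg damping `delta` chosen to
  keep `H - delta I` negative definite.
- **lambda step.** With Gaussian factors the lambda energy is closed-form;
  a 1-D Newton iteration maximizes
  `T*lambda/2 - e^lambda <r'r>/2 - lambda^2/2`, where
  `<r'r> = r'r + tr(J S J')` is the posterior expectation of the squared
  residuals, and `S_lambda = -1/I''`.
- **Acceptance.** An iteration (theta step + lambda step) is accepted only
  if the free energy `F` does not decrease; otherwise `delta` escalates
  (x10, 8 retries). The accepted-iteration `F` trace is therefore
  non-decreasing by construction. Convergence: `dF < 0.01` on two
  successive accepted iterations, cap 64 iterations; a run that stalls
  (no improving step exists) is reported as converged-at-stall, a cap hit
  as non-converged.

The free energy is evaluated in the Laplace form
`F = E_q[log p(y, theta, lambda)] + H[q]`, using the same `<r'r>`
expectation; on exact linear-Gaussian problems it reproduces the
closed-form log marginal likelihood to machine precision, which is the
correctness surface the tests pin down. `F` differences give log Bayes
factors; `|log BF| > 3` (BF > 20) is labelled strong evidence. Nested
restrictions (e.g. `beta_0 = 0`) are tested by the Savage-Dickey density
ratio on the single-parameter Gaussian marginals of the fitted full
model. Per-session estimates combine by precision-weighted averaging;
when sessions must be pooled for model comparison, per-session free
energies are summed (sessions conditionally independent given the model —
an assumption, stated here because no pooling rule is canonical).

**Initialization.** Repetition models start at the prior mean. The pRF
free-energy surface is multimodal in the center-frequency latent (a pRF
centered away from all presented tones predicts nothing), so pRF fits are
seeded by a coarse grid scan — candidate centers at the distinct stimulus
frequencies crossed with three width levels (~115, ~790, ~2500 Hz),
ranked by correlation with the data — and the VL refinement runs once per
width level, keeping the best final `F`. This is the grid-then-refine
strategy standard in pRF estimation; a seeded random multistart is also
available (`multistart=k`).

**Joint vs two-step estimation.** The joint update couples neuronal and
hemodynamic parameters through the off-diagonal curvature; with the
complementary block at its conditional optimum, the neuronal block update
uses the Schur complement `Hnn - Hnh Hhh^-1 Hhn`, whereas a sequential
HRF-then-NRF procedure uses `Hnn` alone and attributes shared signal to
the neuronal cause. Both are exposed (`block_newton_steps`,
`scheme="two_step"`) as diagnostics; tests demonstrate the bias of the
sequential variant on confounded designs.

## Taylor-series GLM baseline

First-order expansion of `beta exp(-a r)` around `a0` yields stick
functions `z1` (weights `e^{-a0 r}`) and `z2` (weights `-r e^{-a0 r}`);
convolving with an assumed HRF kernel gives GLM regressors, and OLS yields
`a_hat = beta2/beta1 + a0`, accurate to `O((a-a0)^2)`. The default kernel
is the canonical double-gamma (peak 6 s, undershoot 16 s, ratio 1/6); any
kernel sampled on the microtime grid can be injected (tests also use the
Balloon impulse response at prior-mean parameters). An intercept column is
always appended — harmless when the data lie in the regressor span, and
protective otherwise. No standard errors are attached to `a_hat`: it is a
ratio of estimates, which is exactly the baseline's known weakness.

## Synthetic data: what it emulates and what it does not

No recordings ship with the package; every empirical claim is checked on
simulated voxels with known truth.

- **Repetition paradigm** (`make_repetition_schedule`): epochs containing
  one train per condition (4 conditions, train lengths uniform on 1-6,
  conditions shuffled per epoch), 2 s onset-to-onset within trains (1.5 s
  stimulus + 0.5 s gap), 4.5 s between trains, 10 s silence between
  epochs, 24 s tail, TR 1.8 s. Exact within-epoch timings are assumptions
  (the protocol's are not printed); they are configurable, and the
  item-vs-time discrimination suite jitters the ISI on U(1.5, 4.5) s so
  the two lag covariates decorrelate. Five epochs give T ~ 160-190 scans,
  the scale used by the recovery suites.
- **Tonotopy paradigm** (`make_tonotopy_schedule`): deterministic
  ascending sweep of 14 pure tones (88-8000 Hz), 2 s each (28 s block),
  12 s silence, 40 s cycle, 15 cycles (10 min) at TR 1.1 s. The
  family-selection suite runs 10 of the 15 cycles — enough data for the
  Gaussian/Ricker evidence to separate while keeping the 40-voxel suite
  within minutes (a Ricker with ~2.6x the width shares the Gaussian's
  central lobe, so the families are only weakly identifiable from short
  sessions).
- **Truths.** Repetition: `beta_k ~ N(1, 0.5^2)`, `a_k ~ N(0, 0.5^2)`
  truncated to [-0.6, 1.5] (stronger facilitation would amplify a fifth
  repetition more than e^3-fold — not physiological, and outside the
  Balloon model's valid domain), `beta_0 ~ N(0, 0.05^2)` (a sustained
  baseline feeds through the nonlinearity ~30x stronger per unit than a
  one-bin stick, so larger offsets would dominate the signal variance),
  hemodynamic latents from their prior. Tonotopy: `mu` log-uniform on
  300-4000 Hz, tuning value `W = mu/FWHM ~ U(0.8, 1.3)` (the W ~ 1 regime
  reported for auditory cortex) which fixes `sigma`, `beta ~ U(3, 8)`.
- **Noise.** White Gaussian, `SD = exp(-lambda/2)`; "SNR s" sets the
  noise SD to `SD(g)/s` over the session. SNR 1.0 is the default study
  condition.

Passing tests on these simulations show self-consistency of the
estimator under its own generative assumptions at realistic SNR. They do
not probe physiological noise, drift, motion residuals, HRF shapes
outside the Balloon family, interleaved-condition nonlinear interactions,
or spatial correlation across voxels — none of which the generator
emulates.

## Numerical choices and degenerate inputs

- Finite-difference steps `0.01 * prior SD`; exponent arguments in NRF
  weights clipped at +-500 to keep absurd optimizer probes finite.
- Posterior covariance is `-H^-1` when `H` is negative definite (always,
  for the Gauss-Newton curvature, up to damping at stall points);
  otherwise the base Levenberg shift is applied first.
- Natural-scale posterior summaries for bounded parameters are Monte
  Carlo (default 1e5 seeded latent draws through the CDF transform,
  median and central 95% interval) — the nonlinear transform of a
  Gaussian has no closed-form mean.
- The inverse CDF transform inverts through the smaller tail, keeping
  latent round trips accurate to ~1e-13 out to |latent| = 5.
- Degenerate inputs rejected with errors: non-positive `sigma`, variance
  or `dt`; events at/after the session end; non-finite series; rank
  deficient Taylor designs; `|beta1|` below 1e-10 flags `a_hat` unstable
  rather than returning an arbitrary ratio.
- Fits on a constant series (zero variance) are legal; the noise
  precision then runs into its hyperprior rather than diverging.

## Problem sizes

Default verification sizes, chosen to keep the full battery within
minutes on one CPU: 50 simulated repetition voxels (T ~ 180) for recovery
and calibration; 20 voxels per class at 10 tonotopy cycles for family
selection; 20 replicates for item-vs-time discrimination; 10 replicates
for the Taylor-vs-VL comparison. All are parameters of the corresponding
`nrffit.experiments` functions.

## Known limitations

- Amplitude units are tied to the microtime resolution (stick
  convention); compare `beta` across analyses only at equal `dt`.
- One scalar noise precision per fit; no AR noise, drift terms, or
  spatial priors.
- The exponential-facilitation branch (`a < 0`) grows without bound in
  train length; truths and fits are only meaningful in the moderate
  regime.
- Evidence values are Laplace approximations; their differences are
  trustworthy near well-behaved optima, less so at stalls on multimodal
  pRF surfaces (mitigated, not eliminated, by grid initialization).
- The two-step scheme is a diagnostic, not a recommended estimator.
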