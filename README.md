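# nrffit

Bayesian estimation of **neural response functions (NRFs)** from fMRI time
series.

Standard GLM analyses convolve stimulus sticks with a fixed hemodynamic
response function and estimate one amplitude per condition. Many questions
are not shaped like that: *how fast does the response decay when a sound is
repeated?* (repetition suppression), *what frequency is this voxel tuned
to, and how sharply?* (tonotopic population receptive fields). These are
**nonlinear** parametric relations between stimulus characteristics and
neuronal activity, entangled with hemodynamics that vary across voxels and
subjects.

`nrffit` fits a two-stage generative model to a single voxel or ROI series
`y` (length `T`, repetition time `TR`):

- an NRF maps events to a neuronal drive `z(t)`:
  - categorical: `z_k(t) = beta_k * sum_j delta(t - t_k(j))`
  - repetition decay: weights `beta_k * exp(-a_k * r)` with lag `r` in
    items or seconds (`a_k > 0` suppression, `a_k < 0` facilitation)
  - frequency tuning: Gaussian `beta * exp(-((f-mu)/sigma)^2 / 2)` or
    Ricker (Mexican-hat) `beta * (1-u^2) exp(-u^2/2)`, `u = (f-mu)/sigma`
  - plus a baseline offset `beta_0`
- the extended Balloon model + BOLD observation equation map `z(t)` to the
  predicted series `g(theta)`, with free parameters `kappa` (signal
  decay), `tau` (transit time) and `epsilon` (intra/extravascular ratio).

All parameters — neuronal and hemodynamic together — are estimated by
**variational Laplace**: a factorized Gaussian posterior
`q(theta) q(lambda)` (with `exp(lambda)` the noise precision) optimized by
regularized Newton ascent on the variational energies. The fit returns the
**free energy** `F ~ log p(y|m)`, so alternative NRFs are compared by log
Bayes factors (`|log BF| > 3`, i.e. BF > 20, is strong evidence), nested
restrictions are tested by Savage–Dickey ratios, and per-session estimates
pool by precision weighting. A first-order Taylor GLM baseline
(`a_hat = beta2/beta1 + a0`) is included for ballpark estimates at GLM
speed, and a synthetic-data module generates repetition and tonotopy
paradigms with known ground truth so the whole pipeline is verifiable
without recordings. Tuning summaries use `FWHM = 2 sqrt(2 ln 2) sigma` and
the tuning value `W = mu / FWHM`.

See `docs/methods.md` for model, priors, optimizer and simulator details.

## Worked example

Simulate one repetition-suppression voxel (4 auditory conditions in short
trains, T = 179 scans at TR 1.8 s, SNR 1) and fit the item-lag model:

```python
import numpy as np
from nrffit import NRFEstimator, TaylorGLM
from nrffit.simulate import (make_repetition_schedule, sample_rs_truth,
                             rs_truth_to_theta, simulate_series)
from nrffit.events import compute_lags
from nrffit.forward import ForwardModel

sched = make_repetition_schedule(n_epochs=5, seed=42)
rng = np.random.default_rng(42)
truth = sample_rs_truth(rng)
events = compute_lags(sched.events, mode="item")
model = ForwardModel(events, "exp_lag", sched.tr, sched.n_scans)
y, _, lam = simulate_series(model, rs_truth_to_theta(truth), snr=1.0, rng=rng)

est = NRFEstimator(sched.events, sched.tr, family="exp_lag").fit(y)
```

Output of the accompanying summary prints:

```
T = 179 scans, true noise log-precision = 1.60
free energy F = -114.2  (converged in 34 iterations)
a[0]: true +0.152  posterior +0.863 +/- 0.910
a[1]: true -0.520  posterior -0.530 +/- 0.078
a[2]: true +0.375  posterior +0.129 +/- 0.192
a[3]: true +0.470  posterior +0.570 +/- 0.387
offset log BF (no-offset vs full): +6.95
log BF item-lag vs time-lag: +0.85
Taylor baseline a_hat (pooled conditions): -0.340
```

Reading it: the well-identified facilitation effect `a[1]` is recovered
almost exactly with a tight posterior; conditions whose trains happened to
be short this session (`a[0]`) come back with honestly wide posteriors —
the 2 SD intervals cover the truth in every row. The Savage–Dickey log BF
of +6.95 favors *dropping* the offset for this voxel (its true `beta_0`
is near zero), the item-vs-time comparison leans the right way but is
inconclusive for a single session (|log BF| < 3), and the single-`a`
Taylor baseline illustrates why a ballpark linearized estimate is not a
substitute for the full fit. The same estimator fits tonotopy data with
`family="gaussian"` or `"mexican_hat"`, exposing `mu`, `sigma`, `beta`,
FWHM and the tuning value `W` in `est.params_`; `nrffit.fit_map` runs
several families over a voxel matrix and tabulates evidences and log
Bayes factors per voxel.

A CLI mirrors the library: `nrffit simulate | fit | taylor-fit | compare |
map`, exchanging plain-text events TSV, series CSV and JSON results.

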