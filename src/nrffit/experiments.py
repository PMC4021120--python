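"""End-to-end simulation studies: simulate -> fit -> tabulate.

These suites are the package's own verification instruments: because no
recordings ship with the method, every claim about estimator behavior
(parameter recovery and calibration, model selection, the value of joint
NRF+HRF estimation, VL vs the Taylor baseline) is checked on synthetic
voxels with known ground truth. The same functions back the test suite and
the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import vl
from .compare import log_bayes_factor
from .estimators import NRFEstimator, TaylorGLM
from .events import compute_lags
from .forward import ForwardModel, PriorSpec
from .simulate import (make_repetition_schedule, make_tonotopy_schedule,
                       prf_truth_to_theta, rs_truth_to_theta,
                       sample_prf_truth, sample_rs_truth, simulate_series)

__all__ = [
    "rs_recovery_suite", "prf_selection_suite", "item_time_suite",
    "taylor_vs_vl_suite", "linear_gaussian_problem",
    "conjugate_linear_solution",
]


def _child_rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]


def rs_recovery_suite(n_voxels: int = 50, snr: float = 1.0, seed: int = 11,
                      n_epochs: int = 5, tr: float = 1.8,
                      init: str = "prior", max_iter: int = 64
                      ) -> pd.DataFrame:
    """Repetition-paradigm parameter recovery.

    Simulates ``n_voxels`` voxels (fresh seeded schedule and truth each),
    fits the item-lag exponential model, and tabulates truth, posterior
    mean/SD and 2-SD coverage per parameter. ``init="truth"`` starts the
    optimizer at the generating parameters (used with ``snr=np.inf`` for
    the noiseless consistency check); ``init="prior"`` starts at the prior
    mean.
    """
    rows = []
    for vox, rng in enumerate(_child_rngs(seed, n_voxels)):
        sched = make_repetition_schedule(n_epochs=n_epochs, tr=tr, seed=rng)
        truth = sample_rs_truth(rng)
        theta_true = rs_truth_to_theta(truth)
        events = compute_lags(sched.events, mode="item")
        fm = ForwardModel(events, "exp_lag", sched.tr, sched.n_scans)
        y, _, lam = simulate_series(fm, theta_true, snr=snr, rng=rng)
        prior = fm.prior()
        start = theta_true if init == "truth" else prior.mean
        try:
            post = vl.fit(y, fm, prior, init=start, max_iter=max_iter)
            ok, status = True, post.status
        except Exception as exc:  # individual failures recorded, not fatal
            rows.append({"voxel": vox, "param": "", "ok": False,
                         "status": f"{type(exc).__name__}", "n_scans":
                         sched.n_scans})
            continue
        for i, name in enumerate(fm.param_names):
            m, sd = post.mean[i], post.sd[i]
            rows.append({
                "voxel": vox, "param": name, "truth": theta_true[i],
                "mean": m, "sd": sd, "error": m - theta_true[i],
                "covered": bool(abs(m - theta_true[i]) <= 2.0 * sd),
                "ok": ok, "status": status, "n_scans": sched.n_scans,
                "free_energy": post.free_energy,
            })
    return pd.DataFrame(rows)


def prf_selection_suite(n_per_class: int = 20, snr: float = 1.0,
                        seed: int = 21, n_cycles: int = 10,
                        max_iter: int = 64) -> pd.DataFrame:
    """Planted Gaussian-vs-Ricker tonotopy voxels, scored by the sign of
    the log Bayes factor between the two pRF families."""
    sched = make_tonotopy_schedule(n_cycles=n_cycles)
    rows = []
    rngs = _child_rngs(seed, 2 * n_per_class)
    for i, rng in enumerate(rngs):
        truth_family = "gaussian" if i < n_per_class else "mexican_hat"
        truth = sample_prf_truth(rng)
        theta_true = prf_truth_to_theta(truth)
        gen = ForwardModel(sched.events, truth_family, sched.tr,
                           sched.n_scans)
        y, _, _ = simulate_series(gen, theta_true, snr=snr, rng=rng)
        F = {}
        for fam in ("gaussian", "mexican_hat"):
            est = NRFEstimator(sched.events, sched.tr, family=fam,
                               max_iter=max_iter).fit(y)
            F[fam] = est.free_energy_
        log_bf = log_bayes_factor(F["gaussian"], F["mexican_hat"],
                                  "gaussian", "mexican_hat").log_bf
        winner = "gaussian" if log_bf > 0 else "mexican_hat"
        rows.append({"voxel": i, "truth_family": truth_family,
                     "log_bf_gauss_vs_mh": log_bf,
                     "correct": winner == truth_family,
                     "mu_true": truth["mu"], "n_scans": sched.n_scans})
    return pd.DataFrame(rows)


def item_time_suite(n_replicates: int = 20, snr: float = 1.0,
                    seed: int = 31, n_epochs: int = 5, tr: float = 1.8,
                    max_iter: int = 64) -> pd.DataFrame:
    """Item-lag vs time-lag discrimination on item-generated epochs.

    Inter-stimulus intervals are jittered (1.5-4.5 s) so the two lag
    covariates decorrelate; truths carry genuine suppression
    (a_k ~ U(0.3, 0.8)), since the two models coincide at a = 0.
    """
    rows = []
    for rep, rng in enumerate(_child_rngs(seed, n_replicates)):
        sched = make_repetition_schedule(n_epochs=n_epochs, tr=tr,
                                         isi=(1.5, 4.5), seed=rng)
        truth = {
            "beta": rng.normal(1.0, 0.3, 4),
            "a": rng.uniform(0.3, 0.8, 4),
            "beta_0": rng.normal(0.0, 0.05),
            "hemo": rng.normal(0.0, np.sqrt(0.135), 3),
        }
        theta_true = rs_truth_to_theta(truth)
        gen_events = compute_lags(sched.events, mode="item")
        gen = ForwardModel(gen_events, "exp_lag", sched.tr, sched.n_scans)
        y, _, _ = simulate_series(gen, theta_true, snr=snr, rng=rng)
        F = {}
        for mode in ("item", "time"):
            est = NRFEstimator(sched.events, sched.tr, family="exp_lag",
                               lag_mode=mode, max_iter=max_iter).fit(y)
            F[mode] = est.free_energy_
        rows.append({"replicate": rep, "log_bf_item_vs_time":
                     F["item"] - F["time"],
                     "item_wins": F["item"] > F["time"],
                     "n_scans": sched.n_scans})
    return pd.DataFrame(rows)


def taylor_vs_vl_suite(n_replicates: int = 10, snr: float = 2.0,
                       seed: int = 41, n_epochs: int = 6, tr: float = 1.8,
                       a0: float = 0.3, max_iter: int = 64) -> pd.DataFrame:
    """Taylor-GLM vs VL decay estimation on Balloon-generated data.

    A single-condition repetition design; data come from the full
    nonlinear generative model, so the Taylor baseline carries both its
    linearization error and its fixed-kernel assumption while VL fits the
    generating model class.
    """
    rows = []
    for rep, rng in enumerate(_child_rngs(seed, n_replicates)):
        sched = make_repetition_schedule(n_epochs=n_epochs, n_conditions=1,
                                         tr=tr, seed=rng)
        a_true = float(rng.uniform(0.2, 0.6))
        truth = {"beta": np.array([rng.normal(1.0, 0.2)]),
                 "a": np.array([a_true]),
                 "beta_0": 0.0,
                 "hemo": rng.normal(0.0, np.sqrt(0.135), 3)}
        events = compute_lags(sched.events, mode="item")
        fm = ForwardModel(events, "exp_lag", sched.tr, sched.n_scans)
        theta_true = rs_truth_to_theta(truth)
        y, _, _ = simulate_series(fm, theta_true, snr=snr, rng=rng)
        tay = TaylorGLM(sched.events, sched.tr, a0=a0).fit(y)
        est = NRFEstimator(sched.events, sched.tr, family="exp_lag",
                           max_iter=max_iter).fit(y)
        a_vl = est.theta_[est.forward_.param_names.index("a[0]")]
        rows.append({"replicate": rep, "a_true": a_true,
                     "taylor_error": abs(tay.a_hat_ - a_true),
                     "vl_error": abs(a_vl - a_true),
                     "vl_better": abs(a_vl - a_true)
                     < abs(tay.a_hat_ - a_true)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linear-Gaussian reference problems (closed-form oracle)

def linear_gaussian_problem(seed: int = 0, T: int = 40, p: int = 3,
                            lam: float = 0.0):
    """A random linear-Gaussian regression problem y = X theta + e.

    Returns ``(y, X, prior, theta_true)`` with a known noise log-precision
    ``lam``; the forward map is ``lambda th: X @ th``.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(T, p))
    prior = PriorSpec(mean=np.zeros(p), cov=np.diag(rng.uniform(0.5, 3.0, p)),
                      names=tuple(f"b{i}" for i in range(p)))
    theta_true = prior.mean + np.linalg.cholesky(prior.cov) @ rng.normal(
        size=p)
    y = X @ theta_true + rng.normal(0.0, np.exp(-lam / 2.0), T)
    return y, X, prior, theta_true


def conjugate_linear_solution(y, X, prior: PriorSpec, lam: float):
    """Exact conjugate posterior and log marginal likelihood for a
    linear-Gaussian model with known noise precision exp(lam).

    This closed form is the independent reference the VL fit is checked
    against on linear problems.
    """
    y = np.asarray(y, dtype=float)
    T = y.size
    w = np.exp(lam)
    cinv = np.linalg.inv(prior.cov)
    S = np.linalg.inv(w * X.T @ X + cinv)
    m = S @ (w * X.T @ y + cinv @ prior.mean)
    marg_cov = np.exp(-lam) * np.eye(T) + X @ prior.cov @ X.T
    d = y - X @ prior.mean
    sign, logdet = np.linalg.slogdet(marg_cov)
    log_ev = -0.5 * (T * np.log(2 * np.pi) + logdet
                     + d @ np.linalg.solve(marg_cov, d))
    return m, S, float(log_ev)
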