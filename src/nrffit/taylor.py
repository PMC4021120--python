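"""First-order Taylor GLM baseline for repetition-decay estimation.

Linearizing the exponential repetition model beta * exp(-a r) around an
assumed decay a0 yields two stick functions,

    z1(t) = sum_j delta[t - t_j] exp(-a0 r_j)
    z2(t) = -sum_j delta[t - t_j] r_j exp(-a0 r_j),

whose convolutions with an assumed (fixed) HRF kernel h form GLM regressors
x1, x2. Ordinary least squares then gives a_hat = beta2_hat / beta1_hat
+ a0. The estimate is accurate to O((a - a0)^2) and assumes linear
superposition and a known, voxel-invariant HRF — the trade-off for running
at GLM speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .events import EventStream

__all__ = ["TaylorDesign", "TaylorEstimate", "canonical_hrf",
           "taylor_regressors", "glm_estimate"]


def canonical_hrf(dt: float, duration: float = 32.0, peak_delay: float = 6.0,
                  undershoot_delay: float = 16.0, peak_disp: float = 1.0,
                  undershoot_disp: float = 1.0,
                  ratio: float = 6.0) -> np.ndarray:
    """Double-gamma HRF kernel sampled on the microtime grid, peak-normalized.

    Defaults: response peak at 6 s, undershoot at 16 s, undershoot ratio
    1/6 — the kernel conventionally assumed in GLM analyses.
    """
    t = np.arange(0.0, duration, dt)
    h = (_gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
         - _gamma_dist.pdf(t, undershoot_delay / undershoot_disp,
                           scale=undershoot_disp) / ratio)
    return h / h.max()


@dataclass(frozen=True)
class TaylorDesign:
    """Regressor pair for the linearized repetition model."""
    a0: float
    x1: np.ndarray
    x2: np.ndarray

    def matrix(self, intercept: bool = True) -> np.ndarray:
        cols = [self.x1, self.x2]
        if intercept:
            cols.append(np.ones_like(self.x1))
        return np.column_stack(cols)


@dataclass(frozen=True)
class TaylorEstimate:
    beta1: float
    beta2: float
    a_hat: float
    stable: bool


def _stick(onsets, weights, dt, n) -> np.ndarray:
    z = np.zeros(n)
    np.add.at(z, np.floor(onsets / dt).astype(int), weights)
    return z


def taylor_regressors(events: EventStream, a0: float, dt: float,
                      scan_times, h: np.ndarray | None = None,
                      duration: float | None = None) -> TaylorDesign:
    """Build the regressor pair x_i = z_i (x) h sampled at scan times.

    ``h`` is the HRF kernel on the microtime grid (defaults to
    :func:`canonical_hrf`); ``events`` must carry lag covariates.
    """
    if len(events) == 0:
        raise ValueError("need at least one event")
    if events.values is None:
        raise ValueError("events must carry lag covariates")
    scan_times = np.asarray(scan_times, dtype=float)
    if duration is None:
        duration = float(scan_times.max())
    n = int(round(duration / dt))
    if np.any(events.onsets >= duration):
        raise ValueError("event onset at or beyond duration")
    if h is None:
        h = canonical_hrf(dt)
    r = events.values
    w1 = np.exp(-a0 * r)
    z1 = _stick(events.onsets, w1, dt, n)
    z2 = _stick(events.onsets, -r * w1, dt, n)
    idx = np.clip(np.round(scan_times / dt).astype(int), 0, n - 1)
    x1 = np.convolve(z1, h)[:n][idx]
    x2 = np.convolve(z2, h)[:n][idx]
    return TaylorDesign(a0=float(a0), x1=x1, x2=x2)


def glm_estimate(y, design: TaylorDesign, intercept: bool = True,
                 beta1_tol: float = 1e-10) -> TaylorEstimate:
    """OLS fit of the Taylor design; a_hat = beta2 / beta1 + a0."""
    y = np.asarray(y, dtype=float)
    X = design.matrix(intercept)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("Taylor design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    b1, b2 = float(beta[0]), float(beta[1])
    stable = abs(b1) > beta1_tol
    a_hat = b2 / b1 + design.a0 if stable else np.nan
    return TaylorEstimate(beta1=b1, beta2=b2, a_hat=float(a_hat),
                          stable=stable)
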