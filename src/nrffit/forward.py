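"""Composed forward model: stimulus events -> neuronal drive -> BOLD.

:class:`ForwardModel` stacks an NRF family and the Balloon/BOLD model into a
single map ``theta -> g(theta)`` from a latent parameter vector to the
predicted fMRI series at scan times, together with the Gaussian prior over
``theta`` that instantiates the model's constraints (uniform priors over
bounded pRF parameters via the Phi transform; log-normal hemodynamic
parameters via the exponential transform).

Latent vector layout by family::

    categorical : [beta_1..beta_K, beta_0, th_kappa, th_tau, th_eps]
    exp_lag     : [beta_1..beta_K, a_1..a_K, beta_0, th_kappa, th_tau, th_eps]
    gaussian /
    mexican_hat : [th_mu, th_sigma, th_beta, beta_0, th_kappa, th_tau, th_eps]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import hemo
from .events import EventStream
from .nrf import (DEFAULT_PRF_BOUNDS, build_drive, latent_to_natural,
                  nrf_weights)

__all__ = ["PriorSpec", "ForwardModel", "scan_times_for"]

PRF_FAMILIES = ("gaussian", "mexican_hat")


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian prior over the stacked latent vector plus the noise
    log-precision hyperprior N(noise_mean, noise_var)."""
    mean: np.ndarray
    cov: np.ndarray
    names: tuple
    noise_mean: float = 0.0
    noise_var: float = 1.0

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if cov.shape != (mean.size, mean.size):
            raise ValueError("cov must be square and match mean")
        if not np.allclose(cov, cov.T):
            raise ValueError("prior covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("prior covariance must be positive definite")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def scan_times_for(n_scans: int, tr: float, offset: float = 0.0) -> np.ndarray:
    """Scan acquisition times t_n = n*TR + offset for n = 1..T (each volume
    stamped at its end)."""
    return (np.arange(1, n_scans + 1)) * tr + offset


# prior variances on the natural / latent scales
_VAR_BETA = 10.0      # condition efficacies and the baseline offset
_VAR_A = 1.0          # repetition decay coefficients
_VAR_HEMO = 0.135     # hemodynamic latents (variance, not SD)


class ForwardModel:
    """Generative map from latent parameters to a predicted BOLD series.

    Parameters
    ----------
    events : EventStream
        Stimulus events, with covariates filled where the family needs them
        (lags for ``exp_lag``, frequencies for the pRF families).
    family : str
        NRF family: ``categorical``, ``exp_lag``, ``gaussian`` or
        ``mexican_hat``.
    tr : float
        Repetition time in seconds.
    n_scans : int
        Number of fMRI volumes; the session spans ``n_scans * tr`` seconds.
    dt : float, optional
        Microtime resolution; defaults to ``tr / 16``.
    include_offset : bool
        Include the baseline neuronal activity parameter beta_0.
    bounds : dict, optional
        pRF bounds (``mu``/``sigma``/``beta`` -> :class:`~nrffit.nrf.Bounds`).
    """

    def __init__(self, events: EventStream, family: str, tr: float,
                 n_scans: int, dt: float | None = None,
                 include_offset: bool = True, bounds: dict | None = None,
                 constants: hemo.HemoConstants = hemo.DEFAULT_CONSTANTS,
                 backend: str = "rk4", scan_offset: float = 0.0):
        if family not in ("categorical", "exp_lag") + PRF_FAMILIES:
            raise ValueError(f"unknown NRF family {family!r}")
        self.events = events
        self.family = family
        self.tr = float(tr)
        self.n_scans = int(n_scans)
        self.dt = float(dt) if dt is not None else self.tr / 16.0
        self.include_offset = include_offset
        self.bounds = dict(DEFAULT_PRF_BOUNDS if bounds is None else bounds)
        self.constants = constants
        self.backend = backend
        self.duration = self.n_scans * self.tr
        self.scan_times = scan_times_for(self.n_scans, self.tr, scan_offset)
        self.n_conditions = events.n_conditions if family in (
            "categorical", "exp_lag") else 1
        self.param_names = self._layout()

    def _layout(self) -> tuple:
        K = self.n_conditions
        if self.family == "categorical":
            names = [f"beta[{k}]" for k in range(K)]
        elif self.family == "exp_lag":
            names = [f"beta[{k}]" for k in range(K)]
            names += [f"a[{k}]" for k in range(K)]
        else:
            names = ["theta_mu", "theta_sigma", "theta_beta"]
        if self.include_offset:
            names.append("beta_0")
        names += ["theta_kappa", "theta_tau", "theta_epsilon"]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def prior(self) -> PriorSpec:
        K = self.n_conditions
        mean, var = [], []
        if self.family == "categorical":
            mean += [1.0] * K
            var += [_VAR_BETA] * K
        elif self.family == "exp_lag":
            mean += [1.0] * K + [0.0] * K
            var += [_VAR_BETA] * K + [_VAR_A] * K
        else:
            mean += [0.0, 0.0, 0.0]
            var += [1.0, 1.0, 1.0]
        if self.include_offset:
            mean.append(0.0)
            var.append(_VAR_BETA)
        mean += [0.0, 0.0, 0.0]
        var += [_VAR_HEMO] * 3
        return PriorSpec(np.array(mean), np.diag(var), self.param_names)

    def split_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Indices of the neuronal vs hemodynamic blocks of theta."""
        n = self.n_params
        return np.arange(n - 3), np.arange(n - 3, n)

    def natural_params(self, theta) -> dict:
        """Natural-scale parameter dictionary for a latent vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError("theta has the wrong length")
        K = self.n_conditions
        out: dict = {}
        i = 0
        if self.family == "categorical":
            out["beta"] = theta[:K]
            i = K
        elif self.family == "exp_lag":
            out["beta"] = theta[:K]
            out["a"] = theta[K:2 * K]
            i = 2 * K
        else:
            out["mu"] = latent_to_natural(theta[0], self.bounds["mu"])
            out["sigma"] = latent_to_natural(theta[1], self.bounds["sigma"])
            out["beta"] = latent_to_natural(theta[2], self.bounds["beta"])
            i = 3
        out["beta_0"] = float(theta[i]) if self.include_offset else 0.0
        if self.include_offset:
            i += 1
        kappa, tau, eps = hemo.hemo_transform(*theta[i:i + 3])
        out.update(kappa=kappa, tau=tau, epsilon=eps)
        return out

    def drive(self, theta):
        p = self.natural_params(theta)
        w = nrf_weights(self.events, self.family, p)
        return build_drive(self.events, w, p["beta_0"], self.dt,
                           self.duration)

    def predict(self, theta, backend: str | None = None) -> np.ndarray:
        """Predicted BOLD series g(theta) at the scan times (length T);
        contains NaN if the hemodynamic trajectory left the valid domain."""
        p = self.natural_params(theta)
        d = self.drive(theta)
        return hemo.integrate_forward(
            d, p["kappa"], p["tau"], p["epsilon"], self.scan_times,
            self.constants, backend=backend or self.backend)

    def __call__(self, theta) -> np.ndarray:
        return self.predict(theta)
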