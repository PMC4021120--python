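"""Neural response functions.

A neural response function (NRF) maps stimulus characteristics to the drive
``z(t)`` of a neuronal population. Each stimulus event contributes a
weighted delta at its onset; the weight depends on the NRF family:

``categorical``
    weight = beta_k, the neuronal efficacy of the event's condition.
``exp_lag``
    weight = beta_k * exp(-a_k * r) with repetition lag r (items or
    seconds); a_k > 0 is repetition suppression, a_k < 0 facilitation.
``gaussian``
    weight = beta * exp(-((f - mu) / sigma)**2 / 2), a population receptive
    field over tone frequency f (Hz) with center mu and width sigma.
``mexican_hat``
    weight = beta * (1 - u**2) * exp(-u**2 / 2), u = (f - mu)/sigma — the
    Ricker wavelet, i.e. a Gaussian with surround suppression.

A constant baseline ``beta_0`` is added to the drive. Bounded pRF
parameters (mu, sigma, beta) are represented by unbounded Gaussian latents
and mapped through the standard normal CDF so a uniform prior over the
bounded range corresponds to a standard-normal prior over the latent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .events import EventStream

__all__ = [
    "Bounds", "DEFAULT_PRF_BOUNDS", "latent_to_natural", "natural_to_latent",
    "nrf_weights", "build_drive", "tuning_metrics", "NeuronalDrive",
]

# exp() argument clip; keeps degenerate optimizer probes finite
_EXP_CLIP = 500.0


@dataclass(frozen=True)
class Bounds:
    """Inclusive-exclusive bounds for one bounded natural parameter."""
    lo: float
    hi: float

    def __post_init__(self):
        if not self.hi > self.lo:
            raise ValueError("bound max must exceed min")


#: Uniform-prior ranges for the pRF parameters: center frequency mu (Hz),
#: width sigma (Hz) and amplitude beta (a.u.).
DEFAULT_PRF_BOUNDS = {
    "mu": Bounds(0.0, 20000.0),
    "sigma": Bounds(1.0, 5000.0),
    "beta": Bounds(0.0, 20.0),
}


def latent_to_natural(theta, bounds: Bounds):
    """Map an unbounded latent to its bounded natural value.

    natural = (hi - lo) * Phi(theta) + lo, with Phi the standard cumulative
    Gaussian; strictly increasing, with the bounds as open asymptotes.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("latent parameter must be finite")
    out = (bounds.hi - bounds.lo) * ndtr(theta) + bounds.lo
    return out if out.ndim else float(out)


def natural_to_latent(x, bounds: Bounds):
    """Inverse of :func:`latent_to_natural` (for values strictly inside).

    Inverts through whichever tail is smaller, so the round trip stays
    accurate (~1e-13) even for latents of magnitude 5 and beyond.
    """
    x = np.asarray(x, dtype=float)
    span = bounds.hi - bounds.lo
    p = (x - bounds.lo) / span
    q = (bounds.hi - x) / span
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("value must lie strictly inside the bounds")
    out = np.where(p <= 0.5, ndtri(np.minimum(p, 0.5)),
                   -ndtri(np.minimum(q, 0.5)))
    return out if out.ndim else float(out)


def _check_sigma(sigma):
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")


def nrf_weights(events: EventStream, family: str, params: dict) -> np.ndarray:
    """Per-event delta weights for an NRF family.

    ``params`` carries natural-scale parameters: ``beta`` (scalar or length-K
    per-condition array) and, per family, ``a`` (length-K decay coefficients,
    exp_lag), or ``mu``/``sigma`` (gaussian, mexican_hat).
    """
    k = events.conditions
    if family == "categorical":
        beta = np.atleast_1d(np.asarray(params["beta"], dtype=float))
        return beta[k].astype(float)
    if family == "exp_lag":
        if events.values is None:
            raise ValueError("exp_lag needs lag covariates (run compute_lags)")
        beta = np.atleast_1d(np.asarray(params["beta"], dtype=float))
        a = np.atleast_1d(np.asarray(params["a"], dtype=float))
        expo = np.clip(-a[k] * events.values, -_EXP_CLIP, _EXP_CLIP)
        return beta[k] * np.exp(expo)
    if family in ("gaussian", "mexican_hat"):
        if events.values is None:
            raise ValueError(f"{family} needs frequency covariates")
        mu, sigma = float(params["mu"]), float(params["sigma"])
        _check_sigma(sigma)
        beta = float(np.asarray(params["beta"], dtype=float))
        u = (events.values - mu) / sigma
        g = np.exp(np.clip(-0.5 * u * u, -_EXP_CLIP, 0.0))
        if family == "gaussian":
            return beta * g
        return beta * (1.0 - u * u) * g
    raise ValueError(f"unknown NRF family {family!r}")


@dataclass(frozen=True)
class NeuronalDrive:
    """Neuronal drive z(t) on a uniform microtime grid of spacing dt."""
    dt: float
    values: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def duration(self) -> float:
        return self.values.size * self.dt


def build_drive(events: EventStream, weights: np.ndarray, beta_0: float,
                dt: float, duration: float) -> NeuronalDrive:
    """Sum weighted event deltas plus baseline into a microtime drive.

    Each event contributes a rectangular pulse of height equal to its
    weight lasting exactly one microtime bin, starting at the bin containing
    its onset (the "stick" convention, so weights keep the drive's units;
    note this ties the effective impulse per event to dt, so amplitude
    estimates are comparable across analyses only at a fixed microtime
    resolution — the default is TR/16). Coincident events superpose
    linearly and the baseline ``beta_0`` is added to every bin.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(duration / dt))
    z = np.full(n, float(beta_0))
    if len(events):
        if np.any(events.onsets >= duration):
            raise ValueError("event onset at or beyond session duration")
        idx = np.floor(events.onsets / dt).astype(int)
        np.add.at(z, idx, np.asarray(weights, dtype=float))
    return NeuronalDrive(dt=dt, values=z)


_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def tuning_metrics(mu: float, sigma: float) -> tuple[float, float]:
    """Gaussian tuning-curve metrics: FWHM = 2*sqrt(2 ln 2)*sigma and the
    tuning value W = mu / FWHM (larger W = narrower tuning)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    fwhm = _FWHM_FACTOR * sigma
    return fwhm, mu / fwhm
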