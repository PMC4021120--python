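"""Synthetic stimulus schedules and BOLD simulation.

Two paradigms are emulated. The repetition paradigm presents short trains
(1-6 stimuli) of each of K = 4 auditory conditions within epochs separated
by silence; repetition lags within a train drive suppression/facilitation.
The tonotopy paradigm presents an ascending sweep of 14 pure tones
(88-8000 Hz, 2 s each, 28 s block + 12 s silence, 40 s cycle repeated 15
times, TR = 1.1 s).

Simulated series are y = g(theta_true) + e with e ~ N(0, exp(-lambda) I);
specifying a signal-to-noise ratio sets the noise SD to
SD(g) / SNR over the session. All randomness flows through a seeded
numpy Generator, so identical configuration + seed reproduces the series
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventStream
from .forward import ForwardModel
from .nrf import natural_to_latent, DEFAULT_PRF_BOUNDS

__all__ = [
    "TONOTOPY_FREQS_HZ", "Schedule", "make_tonotopy_schedule",
    "make_repetition_schedule", "simulate_series", "sample_rs_truth",
    "sample_prf_truth", "rs_truth_to_theta", "prf_truth_to_theta",
]

#: The 14 pure-tone frequencies of the tonotopy protocol (Hz).
TONOTOPY_FREQS_HZ = (88.0, 125.0, 177.0, 250.0, 354.0, 500.0, 707.0, 1000.0,
                     1414.0, 2000.0, 2828.0, 4000.0, 5657.0, 8000.0)


@dataclass(frozen=True)
class Schedule:
    """An event schedule plus its scan geometry."""
    events: EventStream
    tr: float
    n_scans: int

    @property
    def duration(self) -> float:
        return self.n_scans * self.tr


def make_tonotopy_schedule(tones=TONOTOPY_FREQS_HZ, tone_duration: float = 2.0,
                           silence: float = 12.0, n_cycles: int = 15,
                           tr: float = 1.1) -> Schedule:
    """Deterministic ascending tone sweep: tone i of cycle c starts at
    c*cycle + i*tone_duration; a cycle is the block of all tones plus the
    silent period (40 s by default), giving a 600 s session at defaults."""
    tones = np.asarray(tones, dtype=float)
    if np.any(np.diff(tones) <= 0):
        raise ValueError("tones must be strictly increasing")
    block = tones.size * tone_duration
    cycle = block + silence
    onsets, freqs = [], []
    for c in range(n_cycles):
        for i, f in enumerate(tones):
            onsets.append(c * cycle + i * tone_duration)
            freqs.append(f)
    n_scans = int(np.floor(n_cycles * cycle / tr))
    events = EventStream(np.array(onsets), np.zeros(len(onsets), dtype=int),
                         np.array(freqs))
    return Schedule(events=events, tr=tr, n_scans=n_scans)


def make_repetition_schedule(n_epochs: int = 6, n_conditions: int = 4,
                             train_lengths: tuple[int, int] = (1, 6),
                             isi: float | tuple[float, float] = 2.0,
                             inter_train_gap: float = 4.5,
                             epoch_silence: float = 10.0,
                             tail: float = 24.0, tr: float = 1.8,
                             seed: int | np.random.Generator = 0) -> Schedule:
    """Seeded repetition-suppression schedule.

    Each epoch presents one train per condition (conditions in shuffled
    order); train lengths are drawn uniformly from ``train_lengths``
    inclusive. Onset-to-onset intervals within a train are ``isi`` seconds
    (a (lo, hi) tuple draws jittered intervals — useful to decorrelate
    item- and time-lag covariates). ``tail`` seconds are appended so late
    hemodynamic responses are sampled; the session is rounded up to a whole
    number of TRs.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    lo, hi = train_lengths
    onsets, conds, trains = [], [], []
    t = 2.0
    tid = 0
    for _ in range(n_epochs):
        for k in rng.permutation(n_conditions):
            length = int(rng.integers(lo, hi + 1))
            for _j in range(length):
                onsets.append(t)
                conds.append(int(k))
                trains.append(tid)
                t += float(rng.uniform(*isi)) if isinstance(isi, tuple) \
                    else float(isi)
            t += inter_train_gap
            tid += 1
        t += epoch_silence
    n_scans = int(np.ceil((t + tail) / tr))
    events = EventStream(np.array(onsets), np.array(conds),
                         trains=np.array(trains))
    return Schedule(events=events, tr=tr, n_scans=n_scans)


def simulate_series(model: ForwardModel, theta_true, lam: float | None = None,
                    snr: float | None = None,
                    rng: np.random.Generator | int = 0):
    """Simulate a noisy BOLD series from known parameters.

    Exactly one of ``lam`` (noise log-precision; noise SD exp(-lam/2)) or
    ``snr`` (SD(g)/noise-SD) must be given; ``snr=np.inf`` or ``lam=np.inf``
    returns the noiseless prediction. Returns ``(y, g, lam)``.
    """
    if (lam is None) == (snr is None):
        raise ValueError("give exactly one of lam or snr")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    g = model.predict(theta_true)
    if not np.all(np.isfinite(g)):
        raise RuntimeError("forward simulation left the valid domain")
    if snr is not None:
        if np.isinf(snr):
            return g.copy(), g, np.inf
        sd = float(np.std(g)) / snr
        if sd <= 0:
            raise ValueError("zero-variance signal; SNR is undefined")
        lam = -2.0 * np.log(sd)
    if np.isinf(lam):
        return g.copy(), g, np.inf
    y = g + rng.normal(0.0, np.exp(-lam / 2.0), size=g.size)
    return y, g, float(lam)


# ---------------------------------------------------------------------------
# default ground-truth distributions (the simulated study conditions)

def sample_rs_truth(rng: np.random.Generator, n_conditions: int = 4) -> dict:
    """Repetition-paradigm truth: moderate efficacies around 1, decay
    coefficients around 0 (suppression and facilitation both occur), a
    small baseline offset, and hemodynamic latents from their prior.

    Decay draws are truncated to [-0.6, 1.5]: under the exponential lag
    model a facilitation coefficient of -0.6 already amplifies the fifth
    repetition e^3 ~ 20-fold, and stronger values are not physiological
    (and drive the Balloon state off its valid domain).
    """
    a = rng.normal(0.0, 0.5, n_conditions)
    while np.any((a < -0.6) | (a > 1.5)):
        bad = (a < -0.6) | (a > 1.5)
        a[bad] = rng.normal(0.0, 0.5, int(bad.sum()))
    return {
        "beta": rng.normal(1.0, 0.5, n_conditions),
        "a": a,
        "beta_0": rng.normal(0.0, 0.05),
        "hemo": rng.normal(0.0, np.sqrt(0.135), 3),
    }


def sample_prf_truth(rng: np.random.Generator) -> dict:
    """Tonotopy truth: center frequency log-uniform over 300-4000 Hz,
    tuning value W uniform over 0.8-1.3 (the reported W ~ 1 regime, which
    fixes sigma), amplitude 3-8 a.u."""
    mu = float(np.exp(rng.uniform(np.log(300.0), np.log(4000.0))))
    W = float(rng.uniform(0.8, 1.3))
    sigma = mu / (2.0 * np.sqrt(2.0 * np.log(2.0)) * W)
    return {
        "mu": mu, "sigma": sigma, "beta": float(rng.uniform(3.0, 8.0)),
        "beta_0": rng.normal(0.0, 0.05),
        "hemo": rng.normal(0.0, np.sqrt(0.135), 3),
    }


def rs_truth_to_theta(truth: dict) -> np.ndarray:
    return np.concatenate([truth["beta"], truth["a"],
                           [truth["beta_0"]], truth["hemo"]])


def prf_truth_to_theta(truth: dict, bounds=None) -> np.ndarray:
    b = DEFAULT_PRF_BOUNDS if bounds is None else bounds
    return np.concatenate([
        [natural_to_latent(truth["mu"], b["mu"]),
         natural_to_latent(truth["sigma"], b["sigma"]),
         natural_to_latent(truth["beta"], b["beta"]),
         truth["beta_0"]], truth["hemo"]])
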