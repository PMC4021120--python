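"""Bayesian model comparison and session pooling.

Free energies from VL fits approximate log model evidences, so the log
Bayes factor for models i vs j is F_i - F_j; |log BF| > 3 (BF > 20) is the
conventional threshold for strong evidence. Nested restrictions (is the
baseline offset beta_0 zero?) are tested without refitting via the
Savage-Dickey density ratio, and per-session parameter estimates are pooled
by precision-weighted averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ComparisonResult", "log_bayes_factor", "savage_dickey",
    "precision_weighted_average", "pool_free_energy",
]

STRONG_EVIDENCE_LOGBF = 3.0


@dataclass(frozen=True)
class ComparisonResult:
    """Pairwise evidence comparison between models i and j."""
    model_i: str
    model_j: str
    F_i: float
    F_j: float
    log_bf: float
    verdict: str  # 'strong_i' | 'strong_j' | 'inconclusive'

    @property
    def bayes_factor(self) -> float:
        return float(np.exp(self.log_bf))


def log_bayes_factor(F_i: float, F_j: float, model_i: str = "i",
                     model_j: str = "j",
                     threshold: float = STRONG_EVIDENCE_LOGBF
                     ) -> ComparisonResult:
    """Log Bayes factor log BF_ij = F_i - F_j with a strength verdict."""
    if not (np.isfinite(F_i) and np.isfinite(F_j)):
        raise ValueError("free energies must be finite")
    log_bf = float(F_i - F_j)
    if log_bf > threshold:
        verdict = "strong_i"
    elif log_bf < -threshold:
        verdict = "strong_j"
    else:
        verdict = "inconclusive"
    return ComparisonResult(model_i, model_j, float(F_i), float(F_j),
                            log_bf, verdict)


def _norm_logpdf(x: float, mean: float, var: float) -> float:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def savage_dickey(prior_mean: float, prior_var: float, post_mean: float,
                  post_var: float, point: float = 0.0) -> float:
    """Savage-Dickey log Bayes factor of the restricted vs full model.

    log BF = log N(point; post) - log N(point; prior), from the Gaussian
    marginals of the fitted full model; positive values favor the
    restricted (e.g. no-offset) model.
    """
    if prior_var <= 0 or post_var <= 0:
        raise ValueError("marginal variances must be positive")
    return float(_norm_logpdf(point, post_mean, post_var)
                 - _norm_logpdf(point, prior_mean, prior_var))


def precision_weighted_average(means, variances) -> tuple[float, float]:
    """Inverse-variance-weighted combination of per-session estimates.

    Returns the pooled mean sum(m_s / v_s) / sum(1 / v_s) and pooled
    variance 1 / sum(1 / v_s).
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    variances = np.atleast_1d(np.asarray(variances, dtype=float))
    if means.shape != variances.shape or means.size == 0:
        raise ValueError("need matching, non-empty means and variances")
    if np.any(variances <= 0):
        raise ValueError("session variances must be positive")
    prec = 1.0 / variances
    total = prec.sum()
    return float((means * prec).sum() / total), float(1.0 / total)


def pool_free_energy(F_sessions) -> float:
    """Session-pooled log evidence: the sum of per-session free energies
    (sessions treated as conditionally independent given the model)."""
    F_sessions = np.asarray(F_sessions, dtype=float)
    if not np.all(np.isfinite(F_sessions)):
        raise ValueError("free energies must be finite")
    return float(F_sessions.sum())
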