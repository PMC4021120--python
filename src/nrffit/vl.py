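"""Variational Laplace (VL) estimation.

Fits a nonlinear observation model y = g(theta) + e, with Gaussian noise of
precision exp(lambda), a Gaussian prior over the latent parameters theta and
a Gaussian hyperprior over lambda, by fixed-form variational Bayes with a
factorized Gaussian posterior q(theta) q(lambda). Each factor is updated by
a regularized Newton ascent on its variational energy (the expected log
joint under the other factor); gradients and curvatures of the theta energy
are obtained by central finite differences with scale-aware steps
(0.01 prior SD per parameter). The negative free energy F — expected log
joint plus posterior entropy — lower-bounds the log model evidence
log p(y | m) and is the quantity used for Bayesian model comparison.

An iteration (theta Newton step followed by the closed-form lambda update)
is accepted only if F does not decrease; otherwise the Levenberg damping of
the Newton step is escalated (x10, up to 8 retries), which makes the
accepted-iteration F trace non-decreasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import PriorSpec

__all__ = [
    "Posterior", "log_joint", "numeric_gradients", "newton_step",
    "block_newton_steps", "update_noise", "fit", "free_energy",
]

_LOG2PI = np.log(2.0 * np.pi)
_BAD_ENERGY = -1e12  # stands in for -inf so FD probing stays finite


@dataclass
class Posterior:
    """Gaussian approximate posterior and free-energy evidence estimate.

    Attributes
    ----------
    mean, cov : posterior mean and covariance of the latent vector.
    names : parameter names (layout of ``mean``).
    m_lam, s_lam : posterior mean/variance of the noise log-precision
        (``s_lam`` is 0 when the noise was fixed).
    free_energy : evidence lower bound F ~ log p(y | m).
    trace : F at each accepted iteration (non-decreasing).
    converged : True unless the iteration cap was hit.
    status : 'converged', 'stalled' (no F-increasing step found) or
        'max_iter'.
    """
    mean: np.ndarray
    cov: np.ndarray
    names: tuple
    m_lam: float
    s_lam: float
    free_energy: float
    trace: list = field(default_factory=list)
    converged: bool = True
    status: str = "converged"
    n_iter: int = 0

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def marginal(self, name: str) -> tuple[float, float]:
        """(mean, variance) of one parameter's Gaussian marginal."""
        i = self.names.index(name)
        return float(self.mean[i]), float(self.cov[i, i])


def _gauss_logpdf(x, mean, cov_inv, logdet, dim) -> float:
    d = np.atleast_1d(np.asarray(x, dtype=float) - mean)
    return float(-0.5 * (dim * _LOG2PI + logdet + d @ cov_inv @ d))


def log_joint(y, theta, lam, forward, prior: PriorSpec) -> float:
    """Joint log density log p(y, theta, lambda | m)."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(forward(theta), dtype=float)
    r = y - g
    T = y.size
    if not np.all(np.isfinite(r)):
        return -np.inf
    ll = -0.5 * T * _LOG2PI + 0.5 * T * lam - 0.5 * np.exp(lam) * (r @ r)
    cinv = np.linalg.inv(prior.cov)
    _, logdet = np.linalg.slogdet(prior.cov)
    lp = _gauss_logpdf(theta, prior.mean, cinv, logdet, prior.mean.size)
    lh = (-0.5 * (_LOG2PI + np.log(prior.noise_var))
          - 0.5 * (lam - prior.noise_mean) ** 2 / prior.noise_var)
    return float(ll + lp + lh)


def numeric_gradients(energy_fn, x, steps):
    """Central-difference gradient and curvature of a scalar energy.

    The diagonal of the Hessian uses the 3-point second difference on the
    same probes as the gradient; off-diagonals use the 4-point cross
    formula. The result is symmetrized as (H + H.T) / 2 (exact for the
    4-point formula, defensive otherwise).
    """
    x = np.asarray(x, dtype=float)
    h = np.asarray(steps, dtype=float)
    p = x.size
    f0 = energy_fn(x)
    if not np.isfinite(f0):
        raise FloatingPointError("energy non-finite at the expansion point")
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        for sign, dest in ((1.0, fp), (-1.0, fm)):
            xi = x.copy()
            xi[i] += sign * h[i]
            val = energy_fn(xi)
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"energy non-finite probing parameter {i}")
            dest[i] = val
    j = (fp - fm) / (2.0 * h)
    H = np.zeros((p, p))
    H[np.diag_indices(p)] = (fp - 2.0 * f0 + fm) / h ** 2
    for i in range(p):
        for k in range(i + 1, p):
            vals = np.empty(4)
            for n, (si, sk) in enumerate(((1, 1), (1, -1), (-1, 1), (-1, -1))):
                xi = x.copy()
                xi[i] += si * h[i]
                xi[k] += sk * h[k]
                v = energy_fn(xi)
                if not np.isfinite(v):
                    raise FloatingPointError(
                        f"energy non-finite probing parameters {i},{k}")
                vals[n] = v
            H[i, k] = H[k, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                4.0 * h[i] * h[k])
    return j, 0.5 * (H + H.T)


def _base_damping(H: np.ndarray) -> float:
    """Levenberg delta making (H - delta I) negative definite.

    Zero when H already is (so Newton is exact on quadratics); otherwise
    shifted past the largest eigenvalue by a fraction of the spectral
    spread so no direction is left near-singular.
    """
    eigs = np.linalg.eigvalsh(H)
    emin, emax = float(eigs[0]), float(eigs[-1])
    if emax < -1e-12:
        return 0.0
    return emax + max(1e-6, 0.05 * (emax - emin))


def _covariance_from(H: np.ndarray) -> np.ndarray:
    """Posterior covariance from an energy curvature.

    Exactly -H^-1 when H is negative definite (the Laplace form at an
    optimum); otherwise the base Levenberg shift is applied first, so the
    result stays PD with moderate variances while the optimizer is still
    far from a maximum."""
    delta = _base_damping(H)
    S = np.linalg.inv(-(H - delta * np.eye(H.shape[0])))
    return 0.5 * (S + S.T)


def _escalate(delta: float, H: np.ndarray) -> float:
    scale = max(1e-3, 1e-3 * float(np.max(np.abs(np.diag(H)))))
    return max(delta * 10.0, scale)


def newton_step(m_old, j, H, energy_fn=None, max_retries: int = 8):
    """Regularized Newton update m_new = m_old - (H - delta I)^-1 j.

    delta >= 0 is chosen so (H - delta I) is negative definite; when
    ``energy_fn`` is given the step is accepted only if it increases the
    energy, escalating delta (x10) otherwise. Returns
    ``(m_new, delta, accepted)``; ``accepted`` is False when no improving
    step was found within the retry budget (m_old is returned).
    """
    m_old = np.asarray(m_old, dtype=float)
    j = np.asarray(j, dtype=float)
    p = m_old.size
    delta = _base_damping(H)
    e0 = energy_fn(m_old) if energy_fn is not None else None
    for _ in range(max_retries + 1):
        m_new = m_old - np.linalg.solve(H - delta * np.eye(p), j)
        if energy_fn is None:
            return m_new, delta, True
        e1 = energy_fn(m_new)
        if np.isfinite(e1) and e1 >= e0:
            return m_new, delta, True
        delta = _escalate(delta, H)
    return m_old.copy(), delta, False


def block_newton_steps(m_old, j, H, idx_n):
    """Neuronal-block Newton updates with and without the hemodynamic
    cross-curvature.

    The joint update applies the Schur complement
    ``Hnn - Hnh Hhh^-1 Hhn`` (the neuronal sub-block of the full Newton
    step); the two-step update uses ``Hnn`` alone, as a sequential
    HRF-then-NRF procedure would. Returns ``(m_joint, m_twostep)`` for the
    neuronal block.
    """
    m_old = np.asarray(m_old, dtype=float)
    idx_n = np.asarray(idx_n, dtype=int)
    idx_h = np.setdiff1d(np.arange(m_old.size), idx_n)
    jn = j[idx_n]
    Hnn = H[np.ix_(idx_n, idx_n)]
    Hnh = H[np.ix_(idx_n, idx_h)]
    Hhh = H[np.ix_(idx_h, idx_h)]
    schur = Hnn - Hnh @ np.linalg.solve(Hhh, Hnh.T)
    m_joint = m_old[idx_n] - np.linalg.solve(schur, jn)
    m_two = m_old[idx_n] - np.linalg.solve(Hnn, jn)
    return m_joint, m_two


def update_noise(y, g, resid_extra: float = 0.0, prior_mean: float = 0.0,
                 prior_var: float = 1.0, lam_init: float = 0.0,
                 max_iter: int = 100) -> tuple[float, float]:
    """Newton maximization of the noise log-precision's variational energy.

    The energy I(lambda) = T lambda / 2 - exp(lambda) <r'r> / 2
    - (lambda - prior_mean)^2 / (2 prior_var) + const is strictly concave;
    ``resid_extra`` carries the trace correction tr(J S J') that completes
    the posterior expectation of the squared residuals. Returns the
    maximizer and the Laplace variance -1/I''.
    """
    r = np.asarray(y, dtype=float) - np.asarray(g, dtype=float)
    T = r.size
    R = float(r @ r) + float(resid_extra)
    if R <= 0:
        R = np.finfo(float).tiny
    lam = float(lam_init)
    for _ in range(max_iter):
        e = np.exp(np.clip(lam, -600, 600))
        g1 = 0.5 * T - 0.5 * e * R - (lam - prior_mean) / prior_var
        g2 = -0.5 * e * R - 1.0 / prior_var
        step = g1 / g2
        lam = lam - step
        if abs(step) < 1e-12:
            break
    g2 = -0.5 * np.exp(lam) * R - 1.0 / prior_var
    return float(lam), float(-1.0 / g2)


def _free_energy_terms(T, R, m_theta, S_theta, prior, cinv, logdet_c,
                       m_lam, s_lam, lam_fixed: bool) -> float:
    p = m_theta.size
    w = np.exp(m_lam + 0.5 * s_lam)
    sign, logdet_s = np.linalg.slogdet(S_theta)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior covariance is not PD")
    F = -0.5 * T * _LOG2PI + 0.5 * T * m_lam - 0.5 * w * R
    d = m_theta - prior.mean
    F += -0.5 * (p * _LOG2PI + logdet_c + d @ cinv @ d)
    F += -0.5 * float(np.sum(cinv * S_theta))       # tr(Cinv S)
    F += 0.5 * (p * (_LOG2PI + 1.0) + logdet_s)     # entropy of q(theta)
    if not lam_fixed:
        F += (-0.5 * (_LOG2PI + np.log(prior.noise_var))
              - 0.5 * ((m_lam - prior.noise_mean) ** 2 + s_lam)
              / prior.noise_var)
        F += 0.5 * (_LOG2PI + 1.0 + np.log(s_lam))  # entropy of q(lambda)
    return float(F)


def _forward_or_bad(forward, theta, T):
    g = np.asarray(forward(theta), dtype=float)
    if g.shape != (T,) or not np.all(np.isfinite(g)):
        return None
    return g


def fit(y, forward, prior: PriorSpec, lam: float | None = None,
        init=None, max_iter: int = 64, ftol: float = 0.01,
        step_scale: float = 0.01, max_retries: int = 8,
        scheme: str = "joint", blocks=None,
        curvature: str = "gauss_newton") -> Posterior:
    """Variational Laplace fit of ``y = forward(theta) + noise``.

    Parameters
    ----------
    y : array (T,)
        Observed series.
    forward : callable
        Map theta -> predicted series (length T).
    prior : PriorSpec
        Gaussian prior over theta and hyperprior over lambda.
    lam : float, optional
        Fix the noise log-precision at this value instead of estimating it.
    init : array, optional
        Initial posterior mean; defaults to the prior mean.
    scheme : 'joint' or 'two_step'
        'two_step' zeroes the neuronal-hemodynamic cross-curvature in the
        Newton step and posterior covariance (diagnostic only); ``blocks``
        must then give the two index arrays.
    curvature : 'gauss_newton' or 'energy'
        'gauss_newton' (default) builds the gradient and curvature of the
        theta energy from a central-difference Jacobian of the forward map
        (j = w J'r - Cinv d, H = -(w J'J + Cinv)); the curvature is then
        negative definite everywhere and exact for linear models.
        'energy' differences the energy itself (:func:`numeric_gradients`),
        which adds the second-order residual terms but is indefinite far
        from the optimum and quadratically more expensive.

    Returns
    -------
    Posterior
        With ``cov = -H^-1`` (Levenberg-damped when the raw curvature is
        not negative definite) and the free energy F.
    """
    y = np.asarray(y, dtype=float)
    T = y.size
    p = prior.mean.size
    if T <= p:
        raise ValueError("need more scans than parameters")
    cinv = np.linalg.inv(prior.cov)
    _, logdet_c = np.linalg.slogdet(prior.cov)
    steps = step_scale * prior.sd
    lam_fixed = lam is not None

    m = np.array(prior.mean if init is None else init, dtype=float)
    m_lam = float(lam) if lam_fixed else float(prior.noise_mean)
    s_lam = 0.0 if lam_fixed else float(prior.noise_var)

    def energy(theta, w):
        g = _forward_or_bad(forward, theta, T)
        if g is None:
            return _BAD_ENERGY
        r = y - g
        d = theta - prior.mean
        val = -0.5 * w * (r @ r) - 0.5 * (d @ cinv @ d)
        return float(val) if np.isfinite(val) else _BAD_ENERGY

    def jacobian(theta):
        J = np.zeros((T, p))
        for i in range(p):
            tp = theta.copy()
            tp[i] += steps[i]
            tm = theta.copy()
            tm[i] -= steps[i]
            gp = _forward_or_bad(forward, tp, T)
            gm = _forward_or_bad(forward, tm, T)
            if gp is not None and gm is not None:
                J[:, i] = (gp - gm) / (2.0 * steps[i])
        return J

    def lam_update(g, S):
        r = y - g
        J = jacobian_cache["J"]
        extra = float(np.sum((J @ S) * J))
        if lam_fixed:
            R = float(r @ r) + extra
            return m_lam, 0.0, R
        ml, sl = update_noise(y, g, extra, prior.noise_mean,
                              prior.noise_var, lam_init=m_lam)
        return ml, sl, float(r @ r) + extra

    def apply_scheme(H):
        if scheme == "joint":
            return H
        if scheme != "two_step":
            raise ValueError(f"unknown scheme {scheme!r}")
        if blocks is None:
            raise ValueError("two_step scheme needs block index arrays")
        Hb = np.zeros_like(H)
        for idx in blocks:
            Hb[np.ix_(idx, idx)] = H[np.ix_(idx, idx)]
        return Hb

    def grad_hess(theta, g, w):
        """Gradient and curvature of the theta energy at theta."""
        if curvature == "gauss_newton":
            J = jacobian_cache["J"]
            r = y - g
            jv = w * (J.T @ r) - cinv @ (theta - prior.mean)
            Hv = -(w * (J.T @ J)) - cinv
            return jv, Hv
        if curvature != "energy":
            raise ValueError(f"unknown curvature mode {curvature!r}")
        return numeric_gradients(lambda t: energy(t, w), theta, steps)

    w = float(np.exp(m_lam + 0.5 * s_lam))
    g0 = _forward_or_bad(forward, m, T)
    if g0 is None:
        raise ValueError("forward map not evaluable at the initial mean")
    jacobian_cache = {"J": jacobian(m)}

    j, H = grad_hess(m, g0, w)
    H = apply_scheme(H)
    S = _covariance_from(H)
    m_lam, s_lam, R = lam_update(g0, S)
    w = float(np.exp(m_lam + 0.5 * s_lam))
    F = _free_energy_terms(T, R, m, S, prior, cinv, logdet_c, m_lam, s_lam,
                           lam_fixed)
    trace = [F]
    status = "max_iter"
    small = 0
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        delta = _base_damping(H)
        accepted = False
        for _ in range(max_retries + 1):
            Hd = H - delta * np.eye(p)
            m_new = m - np.linalg.solve(Hd, j)
            g_new = _forward_or_bad(forward, m_new, T)
            if g_new is not None and energy(m_new, w) >= energy(m, w) - 1e-12:
                S_new = _covariance_from(H)
                jacobian_cache["J"] = jacobian(m_new)
                ml_new, sl_new, R_new = lam_update(g_new, S_new)
                try:
                    F_new = _free_energy_terms(
                        T, R_new, m_new, S_new, prior, cinv, logdet_c,
                        ml_new, sl_new, lam_fixed)
                except np.linalg.LinAlgError:
                    F_new = -np.inf
                if np.isfinite(F_new) and F_new >= F - 1e-9:
                    accepted = True
                    break
            delta = _escalate(delta, H)
        if not accepted:
            status = "stalled"
            break
        dF = F_new - F
        m, S, m_lam, s_lam, F = m_new, S_new, ml_new, sl_new, F_new
        w = float(np.exp(m_lam + 0.5 * s_lam))
        trace.append(F)
        small = small + 1 if dF < ftol else 0
        if small >= 2:
            status = "converged"
            break
        j, H = grad_hess(m, g_new, w)
        H = apply_scheme(H)
    return Posterior(mean=m, cov=S, names=tuple(getattr(prior, "names", ())),
                     m_lam=m_lam, s_lam=s_lam, free_energy=F, trace=trace,
                     converged=status != "max_iter", status=status,
                     n_iter=n_iter)


def free_energy(posterior: Posterior, y, forward, prior: PriorSpec,
                lam_fixed: bool = False) -> float:
    """Recompute the free energy of a fitted posterior on its problem."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(forward(posterior.mean), dtype=float)
    r = y - g
    cinv = np.linalg.inv(prior.cov)
    _, logdet_c = np.linalg.slogdet(prior.cov)
    # trace correction via a first-order expansion of the forward map
    steps = 0.01 * prior.sd
    p = prior.mean.size
    J = np.zeros((y.size, p))
    for i in range(p):
        tp = posterior.mean.copy()
        tp[i] += steps[i]
        tm = posterior.mean.copy()
        tm[i] -= steps[i]
        J[:, i] = (np.asarray(forward(tp)) - np.asarray(forward(tm))) / (
            2.0 * steps[i])
    R = float(r @ r) + float(np.sum((J @ posterior.cov) * J))
    return _free_energy_terms(y.size, R, posterior.mean, posterior.cov,
                              prior, cinv, logdet_c, posterior.m_lam,
                              posterior.s_lam, lam_fixed)
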