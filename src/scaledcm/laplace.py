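"""Variational Laplace for nonlinear-Gaussian regression.

Fits ``y = g(theta) + eps`` with ``eps ~ N(0, exp(-lam) I)`` and a Gaussian
prior ``theta ~ N(theta0, Sigma0)`` by Gauss-Newton ascent on the variational
free energy, with step halving so that accepted steps never decrease F.  The
noise log-precision ``lam`` is optimised by a fixed-point update (ML-II, flat
hyperprior) unless fixed by the caller.

For a linear ``g`` and fixed ``lam`` the scheme is exact: the returned moments
equal the conjugate Bayesian linear-regression posterior and F equals the log
model evidence.  That case is used as an oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LaplaceFit", "variational_laplace"]

_LAM_MAX = 32.0  # cap on log noise precision; keeps noiseless fits finite


@dataclass
class LaplaceFit:
    """Gaussian posterior ``N(theta, cov)`` plus fit diagnostics."""

    theta: np.ndarray
    cov: np.ndarray
    lam: float
    free_energy: float
    converged: bool
    n_iter: int
    free_energy_trace: np.ndarray


def _jacobian(g, theta, f0, rel_step=1e-6):
    """Forward-difference Jacobian of g at theta (columns = parameters)."""
    d = theta.size
    J = np.empty((f0.size, d))
    for i in range(d):
        h = rel_step * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        J[:, i] = (g(tp) - f0) / h
    return J


def _free_energy(r, J, Sigma, lam, dtheta0, P0, logdetP0, n):
    """Variational free energy for q = N(theta, Sigma) at residuals r."""
    d = dtheta0.size
    JS = J @ Sigma
    trJJS = float(np.einsum("ij,ij->", J, JS))
    accuracy = -0.5 * np.exp(lam) * (r @ r + trJJS) + 0.5 * n * (lam - np.log(2 * np.pi))
    sign, logdetS = np.linalg.slogdet(Sigma) if d else (1.0, 0.0)
    if sign <= 0:
        return -np.inf
    kl = 0.5 * (
        float(np.einsum("ij,ji->", P0, Sigma))
        + dtheta0 @ P0 @ dtheta0
        - d
        - (logdetP0 + logdetS)
    )
    return float(accuracy - kl)


def variational_laplace(
    g,
    y,
    theta0,
    prior_cov,
    *,
    lam=None,
    fix_lam=False,
    max_iter=128,
    tol=1e-6,
    init=None,
):
    """Fit ``y = g(theta) + noise`` and return the Laplace posterior.

    Parameters
    ----------
    g : callable
        Maps a parameter vector (d,) to a prediction vector (n,).
    y : array (n,)
        Observations.
    theta0 : array (d,)
        Prior mean.
    prior_cov : array (d, d) or (d,)
        Prior covariance (or its diagonal).  Must be positive definite;
        parameters with zero prior variance should be fixed by the caller.
    lam : float, optional
        Initial (or fixed) log noise precision.  Default: matched to the
        residual variance at the starting point.
    fix_lam : bool
        If True, ``lam`` is held at its given value (known noise precision).
    max_iter, tol : int, float
        Iteration cap and relative free-energy convergence threshold.
    init : array (d,), optional
        Starting point for the optimisation (default: the prior mean).
        The prior itself is unchanged.
    """
    y = np.asarray(y, dtype=float).ravel()
    theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
    d, n = theta0.size, y.size
    prior_cov = np.asarray(prior_cov, dtype=float)
    if prior_cov.ndim == 1:
        prior_cov = np.diag(prior_cov)
    if d and np.any(np.linalg.eigvalsh(prior_cov) <= 0):
        raise np.linalg.LinAlgError("prior covariance must be positive definite")
    P0 = np.linalg.inv(prior_cov) if d else np.zeros((0, 0))
    logdetP0 = float(np.linalg.slogdet(P0)[1]) if d else 0.0

    theta = theta0.copy() if init is None else np.asarray(init, dtype=float).copy()
    f = g(theta)
    r = y - f
    if lam is None:
        lam = float(-np.log(max(r @ r / n, 1e-12)))
    lam = min(lam, _LAM_MAX)

    J = _jacobian(g, theta, f)
    if not fix_lam:
        lam = _update_lam(r, J, P0, lam, n)
    Sigma = _posterior_cov(J, lam, P0)
    F = _free_energy(r, J, Sigma, lam, theta - theta0, P0, logdetP0, n)
    trace = [F]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = np.exp(lam) * (J.T @ r) - P0 @ (theta - theta0)
        step = Sigma @ grad
        accepted = False
        for _ in range(12):  # step halving
            cand = theta + step
            f_c = g(cand)
            r_c = y - f_c
            J_c = _jacobian(g, cand, f_c)
            lam_c = lam if fix_lam else _update_lam(r_c, J_c, P0, lam, n)
            Sig_c = _posterior_cov(J_c, lam_c, P0)
            F_c = _free_energy(r_c, J_c, Sig_c, lam_c, cand - theta0, P0, logdetP0, n)
            if F_c >= F:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # no ascent direction left at this resolution
            break
        rel = abs(F_c - F) / max(1.0, abs(F))
        theta, r, J, Sigma, lam, F = cand, r_c, J_c, Sig_c, lam_c, F_c
        trace.append(F)
        if rel < tol:
            converged = True
            break

    return LaplaceFit(
        theta=theta,
        cov=Sigma,
        lam=float(lam),
        free_energy=float(F),
        converged=converged,
        n_iter=it,
        free_energy_trace=np.asarray(trace),
    )


def _posterior_cov(J, lam, P0):
    d = P0.shape[0]
    if d == 0:
        return np.zeros((0, 0))
    H = np.exp(lam) * (J.T @ J) + P0
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError as err:  # singular curvature
        raise np.linalg.LinAlgError("singular curvature in Laplace fit") from err


def _update_lam(r, J, P0, lam, n, n_fix=4):
    """Fixed-point updates of the log noise precision (flat hyperprior).

    Alternates ``Sigma(lam)`` with ``exp(lam) = n / (r'r + tr(J'J Sigma))``,
    the stationary point of F in lam.
    """
    for _ in range(n_fix):
        Sigma = _posterior_cov(J, lam, P0)
        trJJS = float(np.einsum("ij,ij->", J, J @ Sigma))
        lam = min(float(np.log(n) - np.log(max(r @ r + trJJS, 1e-300))), _LAM_MAX)
    return lam
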