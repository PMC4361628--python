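"""Local-density random walk (LDRW) indicator-dilution model.

The LDRW model describes the passage of a contrast-agent bolus through a
voxel as a skewed unimodal concentration-time curve

    C(t) = A * exp(lam) * sqrt(lam / (2*pi*mu*(t - t0)))
             * exp(-(lam/2) * ((t - t0)/mu + mu/(t - t0)))      for t > t0

and C(t) = 0 for t <= t0.  The shape factor is a generalized inverse
Gaussian density (index 1/2), so the curve integrates to the area ``A``
(the cerebral-blood-volume surrogate), has first moment ``mu*(1 + 1/lam)``
about the arrival time ``t0`` (the mean transit time), and mode

    t0 + mu * (sqrt(1 + 1/(4*lam**2)) - 1/(2*lam)).

``lam`` controls skewness (large ``lam`` -> symmetric, nearly Gaussian).

This module owns the forward model, the moment-based initializer, a
single-curve bounded least-squares fit (via scipy) and a batched
Levenberg-Marquardt fitter used for voxelwise map computation, where one
scipy call per voxel would dominate the runtime of a cohort analysis.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ldrw_forward",
    "ldrw_first_moment",
    "ldrw_mode",
    "moment_initialization",
    "fit_ldrw_curve",
    "fit_ldrw_batch",
]

_TWO_PI = 2.0 * np.pi


def ldrw_forward(t, A, mu, lam, t0):
    """Evaluate the LDRW concentration curve on a time grid.

    Parameters
    ----------
    t : array_like
        Time points in seconds (absolute, same clock as ``t0``).
    A : float
        Area under the curve (concentration * s); must be > 0.
    mu : float
        Scale/transit parameter in seconds; must be > 0.
    lam : float
        Dimensionless skewness parameter; must be > 0.
    t0 : float
        Bolus arrival time in seconds.

    Returns
    -------
    ndarray
        Concentration values, zero for ``t <= t0``.
    """
    if not (A > 0 and mu > 0 and lam > 0):
        raise ValueError("A, mu and lam must all be positive")
    t = np.asarray(t, dtype=float)
    tau = t - t0
    out = np.zeros_like(tau)
    pos = tau > 0
    tp = tau[pos]
    out[pos] = (
        A
        * np.exp(lam)
        * np.sqrt(lam / (_TWO_PI * mu * tp))
        * np.exp(-(lam / 2.0) * (tp / mu + mu / tp))
    )
    return out


def ldrw_first_moment(mu, lam):
    """Mean transit time of the LDRW density: ``mu * (1 + 1/lam)``."""
    return mu * (1.0 + 1.0 / lam)


def ldrw_mode(mu, lam):
    """Offset of the curve maximum from ``t0`` (analytic mode of the density)."""
    return mu * (np.sqrt(1.0 + 1.0 / (4.0 * lam**2)) - 1.0 / (2.0 * lam))


def _batch_model_and_jac(theta, t, jac=True):
    """LDRW model values (and optionally Jacobian) for a parameter batch.

    theta : (n, 4) array of (A, mu, lam, t0); t : (n, nt) time grids.
    Returns m : (n, nt) and J : (n, nt, 4) or None.
    """
    A = theta[:, 0:1]
    mu = theta[:, 1:2]
    lam = theta[:, 2:3]
    t0 = theta[:, 3:4]
    tau = t - t0
    pos = tau > 0
    taus = np.where(pos, tau, 1.0)  # safe placeholder off-support
    logf = (
        lam
        + 0.5 * (np.log(lam) - np.log(_TWO_PI * mu * taus))
        - (lam / 2.0) * (taus / mu + mu / taus)
    )
    m = np.where(pos, A * np.exp(logf), 0.0)
    if not jac:
        return m, None
    # d m / d A = m / A ; others via d log f
    dmu = -0.5 / mu + (lam / 2.0) * (taus / mu**2 - 1.0 / taus)
    dlam = 1.0 + 0.5 / lam - 0.5 * (taus / mu + mu / taus)
    dt0 = 0.5 / taus + (lam / 2.0) * (1.0 / mu - mu / taus**2)
    J = np.empty(t.shape + (4,))
    J[..., 0] = np.where(pos, m / A, 0.0)
    J[..., 1] = np.where(pos, m * dmu, 0.0)
    J[..., 2] = np.where(pos, m * dlam, 0.0)
    J[..., 3] = np.where(pos, m * dt0, 0.0)
    return m, J


def moment_initialization(conc, t):
    """Moment-based starting values for LDRW fits (vectorized).

    Parameters
    ----------
    conc : (n, nt) array
        Concentration curves (may contain negative noise samples).
    t : (n, nt) array
        Time grids.

    Returns
    -------
    theta0 : (n, 4) array of (A0, mu0, lam0, t00)
    fit_ok : (n,) bool
        False where the curve carries no usable signal (e.g. all zero).

    Notes
    -----
    * ``A0``: trapezoidal area of the positive part of the curve.
    * ``t00``: time of the first sample exceeding 10% of the peak.
    * first moment m1 and variance computed from the positive part
      relative to ``t00``; ``lam0 = clip(m1^2/var, 0.5, 50)``,
      ``mu0 = m1 * lam0 / (lam0 + 1)``.
    """
    conc = np.atleast_2d(np.asarray(conc, dtype=float))
    t = np.broadcast_to(np.atleast_2d(np.asarray(t, dtype=float)), conc.shape)
    cpos = np.clip(conc, 0.0, None)
    A0 = np.trapezoid(cpos, t, axis=1)
    peak = conc.max(axis=1)
    fit_ok = (A0 > 0) & (peak > 0)
    # first sample above 10% of peak
    above = conc >= 0.1 * np.maximum(peak, 1e-300)[:, None]
    first = np.where(above.any(axis=1), above.argmax(axis=1), 0)
    t00 = t[np.arange(len(conc)), first]
    w = cpos / np.maximum(A0, 1e-300)[:, None]
    rel = t - t00[:, None]
    m1 = np.trapezoid(w * rel, t, axis=1)
    var = np.trapezoid(w * (rel - m1[:, None]) ** 2, t, axis=1)
    m1 = np.maximum(m1, 1e-3)
    var = np.maximum(var, 1e-6)
    lam0 = np.clip(m1**2 / var, 0.5, 50.0)
    mu0 = m1 * lam0 / (lam0 + 1.0)
    theta0 = np.stack(
        [np.maximum(A0, 1e-12), np.clip(mu0, 0.1, 100.0), lam0, np.maximum(t00, 0.0)],
        axis=1,
    )
    return theta0, fit_ok


def fit_ldrw_curve(conc, t, max_nfev=400):
    """Bounded nonlinear least-squares fit of one concentration curve.

    Returns a dict with keys A, mu, lam, t0, r_squared, converged.  This is
    the reference single-voxel path (scipy trust-region reflective); the
    batched fitter below must agree with it to within numerical tolerance.
    """
    conc = np.asarray(conc, dtype=float)
    t = np.asarray(t, dtype=float)
    if conc.size < 10:
        raise ValueError("need at least 10 samples to fit the LDRW model")
    theta0, ok = moment_initialization(conc[None, :], t[None, :])
    if not ok[0]:
        return dict(A=np.nan, mu=np.nan, lam=np.nan, t0=np.nan,
                    r_squared=0.0, converged=False)
    th = theta0[0]
    t_peak = t[int(np.argmax(conc))]
    lo = np.array([1e-12, 0.1, 0.1, 0.0])
    hi = np.array([100.0 * th[0], 100.0, 100.0, max(t_peak, 1e-6)])
    th = np.clip(th, lo + 1e-12, hi - 1e-12)

    def resid(p):
        m, _ = _batch_model_and_jac(p[None, :], t[None, :], jac=False)
        return m[0] - conc

    def jac(p):
        _, J = _batch_model_and_jac(p[None, :], t[None, :], jac=True)
        return J[0]

    sol = least_squares(resid, th, jac=jac, bounds=(lo, hi),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=max_nfev)
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((conc - conc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    A, mu, lam, t0 = sol.x
    converged = bool(sol.status > 0) and r2 > 0.0
    return dict(A=A, mu=mu, lam=lam, t0=t0, r_squared=max(r2, 0.0),
                converged=converged)


def fit_ldrw_batch(conc, t, max_iter=60, tol=1e-8, ftol=1e-10):
    """Batched Levenberg-Marquardt LDRW fit of many curves at once.

    Parameters
    ----------
    conc : (n, nt) array
        Concentration curves, one voxel per row.
    t : (nt,) or (n, nt) array
        Shared or per-voxel time grids (per-voxel grids carry slice-time
        offsets).
    max_iter : int
        Iteration cap per voxel.
    tol : float
        Relative parameter-step convergence threshold.
    ftol : float
        Relative cost-decrease convergence threshold.

    Returns
    -------
    dict of arrays
        A, mu, lam, t0, r_squared (each (n,)) and converged (bool (n,)).

    Each voxel is an independent 4-parameter problem; the normal equations
    (J^T J + damp*diag) dtheta = -J^T r are assembled and solved for all
    active voxels simultaneously, with per-voxel adaptive damping and
    projection onto the same bounds used by :func:`fit_ldrw_curve`.
    """
    conc = np.atleast_2d(np.asarray(conc, dtype=float))
    n, nt = conc.shape
    t = np.asarray(t, dtype=float)
    if t.ndim == 1:
        t = np.broadcast_to(t, (n, nt))
    theta, fit_ok = moment_initialization(conc, t)
    t_peak = t[np.arange(n), conc.argmax(axis=1)]
    lo = np.empty((n, 4))
    hi = np.empty((n, 4))
    lo[:] = [1e-12, 0.1, 0.1, 0.0]
    hi[:, 0] = 100.0 * theta[:, 0]
    hi[:, 1] = 100.0
    hi[:, 2] = 100.0
    hi[:, 3] = np.maximum(t_peak, 1e-6)
    theta = np.clip(theta, lo + 1e-12, hi - 1e-12)

    m, _ = _batch_model_and_jac(theta, t, jac=False)
    cost = np.einsum("ij,ij->i", m - conc, m - conc)
    damp = np.full(n, 1e-3)
    active = fit_ok.copy()
    eye = np.eye(4)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        th = theta[idx]
        ta = t[idx]
        ca = conc[idx]
        m, J = _batch_model_and_jac(th, ta)
        r = m - ca
        JtJ = np.einsum("vti,vtj->vij", J, J)
        Jtr = np.einsum("vti,vt->vi", J, r)
        diag = np.maximum(np.einsum("vii->vi", JtJ), 1e-12)
        Amat = JtJ + damp[idx, None, None] * diag[:, :, None] * eye
        try:
            step = -np.linalg.solve(Amat, Jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            Amat = Amat + 1e-8 * eye
            step = -np.linalg.solve(Amat, Jtr[..., None])[..., 0]
        trial = np.clip(th + step, lo[idx] + 1e-12, hi[idx])
        mt, _ = _batch_model_and_jac(trial, ta, jac=False)
        trial_cost = np.einsum("ij,ij->i", mt - ca, mt - ca)
        old_cost = cost[idx]
        better = trial_cost <= old_cost
        # accept improving steps, shrink damping there; grow elsewhere
        gi = idx[better]
        theta[gi] = trial[better]
        cost[gi] = trial_cost[better]
        damp[gi] = np.maximum(damp[gi] * 0.3, 1e-12)
        bi = idx[~better]
        damp[bi] = np.minimum(damp[bi] * 4.0, 1e10)
        # convergence: tiny relative step or stalled cost on an accepted step
        relstep = np.max(np.abs(step[better]) / np.maximum(np.abs(trial[better]), 1e-9),
                         axis=1)
        fdrop = ((old_cost[better] - trial_cost[better])
                 <= ftol * np.maximum(old_cost[better], 1e-300))
        done = gi[(relstep < tol) | fdrop]
        active[done] = False
        active[bi[damp[bi] >= 1e9]] = False

    m, _ = _batch_model_and_jac(theta, t, jac=False)
    ss_res = np.einsum("ij,ij->i", m - conc, m - conc)
    ss_tot = np.einsum("ij,ij->i", conc - conc.mean(axis=1, keepdims=True),
                       conc - conc.mean(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    converged = fit_ok & (r2 > 0)
    return dict(
        A=theta[:, 0], mu=theta[:, 1], lam=theta[:, 2], t0=theta[:, 3],
        r_squared=np.clip(r2, 0.0, 1.0), converged=converged,
    )
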