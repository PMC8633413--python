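"""Compiled numerical kernels.

The likelihood scan evaluates the coupled-growth ODE solution thousands of
times per marker (once per simplex move, per genotype class).  These kernels
keep that hot loop out of the Python interpreter: a fixed-step RK4 integrator
for the two-trait system and a self-contained Nelder-Mead simplex driving the
generalized-least-squares objective against a genotype-class mean curve.

Parameter vector layout used throughout (matches ``CRIParams.to_array``):

    theta = [alpha_h, k_h, beta_hd, alpha_d, k_d, beta_dh]
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BIG = 1e30


@njit(cache=True, inline="always")
def _cri_deriv(h, d, theta):
    ah, kh, bhd, ad, kd, bdh = theta[0], theta[1], theta[2], theta[3], theta[4], theta[5]
    dh = ah * (1.0 - h / kh) * h + ah * bhd * h * d
    dd = ad * (1.0 - d / kd) * d + ad * bdh * d * h
    return dh, dd


@njit(cache=True)
def cri_rk4(theta, h0, d0, times, step):
    """Integrate the coupled system with classic RK4.

    Returns an (m, 2) array of (H, D) at the requested ``times``; the first
    row is exactly (h0, d0).  Internal substeps never exceed ``step``.
    Non-finite blow-up is signalled by NaN rows from the offending time on.
    """
    m = times.shape[0]
    out = np.empty((m, 2))
    h = h0
    d = d0
    out[0, 0] = h
    out[0, 1] = d
    for k in range(m - 1):
        dt = times[k + 1] - times[k]
        nsub = int(np.ceil(dt / step))
        if nsub < 1:
            nsub = 1
        hh = dt / nsub
        ok = True
        for _ in range(nsub):
            k1h, k1d = _cri_deriv(h, d, theta)
            k2h, k2d = _cri_deriv(h + 0.5 * hh * k1h, d + 0.5 * hh * k1d, theta)
            k3h, k3d = _cri_deriv(h + 0.5 * hh * k2h, d + 0.5 * hh * k2d, theta)
            k4h, k4d = _cri_deriv(h + hh * k3h, d + hh * k3d, theta)
            h = h + hh * (k1h + 2.0 * k2h + 2.0 * k3h + k4h) / 6.0
            d = d + hh * (k1d + 2.0 * k2d + 2.0 * k3d + k4d) / 6.0
            if not (np.isfinite(h) and np.isfinite(d)) or abs(h) > 1e12 or abs(d) > 1e12:
                ok = False
                break
        if not ok:
            for kk in range(k + 1, m):
                out[kk, 0] = np.nan
                out[kk, 1] = np.nan
            return out
        out[k + 1, 0] = h
        out[k + 1, 1] = d
    return out


@njit(cache=True)
def gls_objective(theta, ybar, sinv, times, h0, d0, step):
    """(ybar - mu(theta))' Sinv (ybar - mu(theta)) with mu the stacked
    (height; diameter) RK4 solution.  Invalid or exploding parameter sets
    return a large penalty so the simplex backs away."""
    if theta[0] <= 0.0 or theta[1] <= 0.0 or theta[3] <= 0.0 or theta[4] <= 0.0:
        pen = 0.0
        for i in (0, 1, 3, 4):
            if theta[i] <= 0.0:
                pen += 1.0 - theta[i]
        return _BIG * (1.0 + pen)
    m = times.shape[0]
    traj = cri_rk4(theta, h0, d0, times, step)
    if not np.isfinite(traj[m - 1, 0]) or not np.isfinite(traj[m - 1, 1]):
        return _BIG
    r = np.empty(2 * m)
    for t in range(m):
        r[t] = ybar[t] - traj[t, 0]
        r[m + t] = ybar[m + t] - traj[t, 1]
    q = 0.0
    for i in range(2 * m):
        s = 0.0
        for j in range(2 * m):
            s += sinv[i, j] * r[j]
        q += s * r[i]
    return q


@njit(cache=True)
def nm_minimize_gls(x0, ybar, sinv, times, h0, d0, step, maxiter, ftol):
    """Nelder-Mead on ``gls_objective`` (standard reflect/expand/contract/
    shrink coefficients, scipy-style initial simplex).

    Returns (x_best, f_best, n_iter).
    """
    n = x0.shape[0]
    alpha = 1.0
    gamma = 2.0
    rho = 0.5
    sigma = 0.5

    sim = np.empty((n + 1, n))
    fv = np.empty(n + 1)
    sim[0] = x0
    for i in range(n):
        pt = x0.copy()
        if pt[i] != 0.0:
            pt[i] *= 1.05
        else:
            pt[i] = 0.00025
        sim[i + 1] = pt
    for i in range(n + 1):
        fv[i] = gls_objective(sim[i], ybar, sinv, times, h0, d0, step)

    it = 0
    while it < maxiter:
        order = np.argsort(fv)
        sim = sim[order]
        fv = fv[order]
        if fv[n] - fv[0] <= ftol * (abs(fv[0]) + ftol):
            break
        # centroid of all but worst
        cen = np.zeros(n)
        for i in range(n):
            for j in range(n):
                cen[j] += sim[i, j]
        cen /= n
        xr = cen + alpha * (cen - sim[n])
        fr = gls_objective(xr, ybar, sinv, times, h0, d0, step)
        if fr < fv[0]:
            xe = cen + gamma * (xr - cen)
            fe = gls_objective(xe, ybar, sinv, times, h0, d0, step)
            if fe < fr:
                sim[n] = xe
                fv[n] = fe
            else:
                sim[n] = xr
                fv[n] = fr
        elif fr < fv[n - 1]:
            sim[n] = xr
            fv[n] = fr
        else:
            if fr < fv[n]:
                xc = cen + rho * (xr - cen)
                fc = gls_objective(xc, ybar, sinv, times, h0, d0, step)
                shrink = fc >= fr
            else:
                xc = cen + rho * (sim[n] - cen)
                fc = gls_objective(xc, ybar, sinv, times, h0, d0, step)
                shrink = fc >= fv[n]
            if not shrink:
                sim[n] = xc
                fv[n] = fc
            else:
                for i in range(1, n + 1):
                    sim[i] = sim[0] + sigma * (sim[i] - sim[0])
                    fv[i] = gls_objective(sim[i], ybar, sinv, times, h0, d0, step)
        it += 1

    best = np.argmin(fv)
    return sim[best].copy(), fv[best], it


@njit(cache=True)
def sad1_paths(phi_h, phi_d, nu_h, nu_d, rho, n, T, z):
    """Turn standard-normal draws z of shape (n, T, 2) into SAD(1) residual
    paths stacked as (n, 2T): height block first, then diameter."""
    out = np.empty((n, 2 * T))
    c = np.sqrt(1.0 - rho * rho)
    for i in range(n):
        prev_h = 0.0
        prev_d = 0.0
        for t in range(T):
            eh = nu_h * z[i, t, 0]
            ed = nu_d * (rho * z[i, t, 0] + c * z[i, t, 1])
            prev_h = phi_h * prev_h + eh
            prev_d = phi_d * prev_d + ed
            out[i, t] = prev_h
            out[i, T + t] = prev_d
    return out
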