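"""Compiled Bogacki-Shampine (2,3) integrator core.

An adaptive explicit Runge-Kutta pair of orders 3(2) with FSAL, the same
pair scipy exposes as ``RK23``; the whole stepping loop is numba-compiled
so that thousands of long integrations (parameter sweeps) stay cheap.
Error control follows the standard embedded-pair recipe: RMS error norm
against ``atol + rtol * max(|y|, |y_new|)``, safety factor 0.9, step
factor clamped to [0.2, 10], exponent -1/3.  Dense output on the caller's
sample grid uses the cubic Hermite interpolant through the step endpoints
(third-order accurate, matching the pair).

Everything here is deterministic: identical inputs give bit-identical
trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Model identifiers for the compiled right-hand sides.
MODEL_FULL = 0   # four-compartment dormancy model
MODEL_RM = 1     # two-species Rosenzweig-MacArthur reduction, zero-padded

# Return status of the driver.
OK = 0
STEP_TOO_SMALL = 1
NONFINITE = 2

_EXP_CLAMP = 700.0


@njit(cache=True)
def _rhs(model_id, y, pv, out):
    """Evaluate the model RHS into ``out``; ``pv`` is PARAM_ORDER-packed."""
    r_p, r_y, K, d_z, alpha = pv[0], pv[1], pv[2], pv[3], pv[4]
    k_p, k_y1, k_y2 = pv[5], pv[6], pv[7]
    c_p, c_y1, c_y2 = pv[8], pv[9], pv[10]
    h_p, h_y1, h_y2 = pv[11], pv[12], pv[13]
    eta, sigma, chi, phi = pv[14], pv[15], pv[16], pv[17]

    p, y1, y2, z = y[0], y[1], y[2], y[3]
    pc = p if p > 0.0 else 0.0

    if model_id == MODEL_RM:
        # Independently coded two-species Rosenzweig-MacArthur system:
        # logistic prey with Holling type-II predation, linear predator
        # mortality.  y1/y2 slots stay identically zero.
        f_p = c_p * pc / (1.0 + c_p * h_p * pc)
        out[0] = r_p * (1.0 - pc / K) * p - f_p * z
        out[1] = 0.0
        out[2] = 0.0
        out[3] = k_p * f_p * z - d_z * z
        return

    y1c = y1 if y1 > 0.0 else 0.0
    y2c = y2 if y2 > 0.0 else 0.0

    f_p = c_p * pc / (1.0 + c_p * h_p * pc)
    f_y1 = c_y1 * y1c / (1.0 + c_y1 * h_y1 * y1c)
    f_y2 = c_y2 * y2c / (1.0 + c_y2 * h_y2 * y2c)

    x = (z - eta) / sigma
    if x > _EXP_CLAMP:
        x = _EXP_CLAMP
    elif x < -_EXP_CLAMP:
        x = -_EXP_CLAMP
    mu = chi + phi / (1.0 + np.exp(x))

    crowd = 1.0 - (pc + y1c) / K

    out[0] = r_p * crowd * p - f_p * z
    out[1] = r_y * crowd * mu * y1 + alpha * y2 - f_y1 * z
    out[2] = r_y * crowd * (1.0 - mu) * y1 - alpha * y2 - f_y2 * z
    out[3] = k_p * f_p * z + k_y1 * f_y1 * z + k_y2 * f_y2 * z - d_z * z


@njit(cache=True)
def _rms_scaled(e, y0, y1v, rtol, atol):
    s = 0.0
    for i in range(e.size):
        a0 = abs(y0[i])
        a1 = abs(y1v[i])
        sc = atol + rtol * (a0 if a0 > a1 else a1)
        s += (e[i] / sc) ** 2
    return np.sqrt(s / e.size)


@njit(cache=True)
def _initial_step(model_id, y0, f0, pv, t_bound, rtol, atol):
    """Hairer-style starting step size estimate (order-3 scaling)."""
    n = y0.size
    d0 = 0.0
    d1 = 0.0
    for i in range(n):
        sc = atol + rtol * abs(y0[i])
        d0 += (y0[i] / sc) ** 2
        d1 += (f0[i] / sc) ** 2
    d0 = np.sqrt(d0 / n)
    d1 = np.sqrt(d1 / n)
    if d0 < 1e-5 or d1 < 1e-5:
        h0 = 1e-6
    else:
        h0 = 0.01 * d0 / d1
    y1v = y0 + h0 * f0
    f1 = np.empty(n)
    _rhs(model_id, y1v, pv, f1)
    d2 = 0.0
    for i in range(n):
        sc = atol + rtol * abs(y0[i])
        d2 += ((f1[i] - f0[i]) / sc) ** 2
    d2 = np.sqrt(d2 / n) / h0
    dm = d1 if d1 > d2 else d2
    if d1 <= 1e-15 and d2 <= 1e-15:
        h1 = max(1e-6, h0 * 1e-3)
    else:
        h1 = (0.01 / dm) ** (1.0 / 3.0)
    h = min(100.0 * h0, h1)
    if h > t_bound:
        h = t_bound
    return h


@njit(cache=True)
def integrate_bs23(model_id, pv, y0, t0, t1, rtol, atol, t_out):
    """Integrate from ``t0`` to ``t1`` sampling at ``t_out``.

    Returns ``(status, t_fail, states)`` where ``states`` has one row per
    entry of ``t_out`` (rows past a failure are left as NaN).
    """
    n = y0.size
    n_out = t_out.size
    states = np.full((n_out, n), np.nan)

    t = t0
    y = y0.copy()
    f = np.empty(n)
    _rhs(model_id, y, pv, f)

    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    y_new = np.empty(n)
    err = np.empty(n)
    ytmp = np.empty(n)

    iout = 0
    # emit samples at or before t0
    while iout < n_out and t_out[iout] <= t0:
        for i in range(n):
            states[iout, i] = y[i]
        iout += 1

    h = _initial_step(model_id, y, f, pv, t1 - t0, rtol, atol)
    min_factor = 0.2
    max_factor = 10.0
    safety = 0.9

    while t < t1:
        hmin = 10.0 * np.abs(np.nextafter(t, np.inf) - t)
        if h < hmin:
            h = hmin
        if t + h > t1:
            h = t1 - t

        # BS23 stages (k1 = f, FSAL)
        for i in range(n):
            ytmp[i] = y[i] + 0.5 * h * f[i]
        _rhs(model_id, ytmp, pv, k2)
        for i in range(n):
            ytmp[i] = y[i] + 0.75 * h * k2[i]
        _rhs(model_id, ytmp, pv, k3)
        for i in range(n):
            y_new[i] = y[i] + h * (2.0 / 9.0 * f[i] + 1.0 / 3.0 * k2[i] + 4.0 / 9.0 * k3[i])
        _rhs(model_id, y_new, pv, k4)
        for i in range(n):
            err[i] = h * (
                5.0 / 72.0 * f[i]
                - 1.0 / 12.0 * k2[i]
                - 1.0 / 9.0 * k3[i]
                + 1.0 / 8.0 * k4[i]
            )

        ok = True
        for i in range(n):
            if not np.isfinite(y_new[i]):
                ok = False
        if not ok:
            return NONFINITE, t, states

        norm = _rms_scaled(err, y, y_new, rtol, atol)
        if norm < 1.0:
            # accepted: fill dense output on (t, t+h] by cubic Hermite
            t_new = t + h
            while iout < n_out and t_out[iout] <= t_new:
                s = (t_out[iout] - t) / h
                h00 = (1.0 + 2.0 * s) * (1.0 - s) ** 2
                h10 = s * (1.0 - s) ** 2
                h01 = s * s * (3.0 - 2.0 * s)
                h11 = s * s * (s - 1.0)
                for i in range(n):
                    states[iout, i] = (
                        h00 * y[i] + h10 * h * f[i] + h01 * y_new[i] + h11 * h * k4[i]
                    )
                iout += 1
            t = t_new
            for i in range(n):
                y[i] = y_new[i]
                f[i] = k4[i]  # FSAL
            if norm == 0.0:
                factor = max_factor
            else:
                factor = safety * norm ** (-1.0 / 3.0)
                if factor > max_factor:
                    factor = max_factor
                if factor < 1.0:
                    factor = 1.0
            h *= factor
        else:
            factor = safety * norm ** (-1.0 / 3.0)
            if factor < min_factor:
                factor = min_factor
            h *= factor
            if h < 1e-14 * max(1.0, abs(t)):
                return STEP_TOO_SMALL, t, states

    # exact endpoint samples (guard against floating slop at t1)
    while iout < n_out:
        for i in range(n):
            states[iout, i] = y[i]
        iout += 1
    return OK, t, states
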