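"""Compiled fixed-step RK4 kernels for the hemodynamic ODE systems.

Two families: scalar trajectory integration (one initial condition, full
trajectory returned) and in-place batch propagation (one RK4 pass applied to
every row of a sigma-point matrix, each row with its own parameter values).
The input u is piecewise constant per substep; block edges must fall on
substep boundaries for the nominal O(dt^4) accuracy to hold.

f, v, q are floored at ``STATE_FLOOR`` after every full step (and guarded
inside the right-hand side) so that degenerate sigma points cannot produce
NaNs; the number of floored components is returned for diagnostics.
"""

import numpy as np
from numba import njit

STATE_FLOOR = 1e-6


@njit(inline="always")
def _rhs(s, f, v, q, eps, ts, tf, t0, e0, ialpha, u):
    if f < STATE_FLOOR:
        f = STATE_FLOOR
    if v < STATE_FLOOR:
        v = STATE_FLOOR
    if q < STATE_FLOOR:
        q = STATE_FLOOR
    # exact at resting inflow: avoids the float cancellation in
    # 1 - (1 - E0)**(1/1) != E0 that would break the resting fixed point
    if f == 1.0:
        extraction = e0
    else:
        extraction = 1.0 - (1.0 - e0) ** (1.0 / f)
    outflow = v ** ialpha
    ds = eps * u - s / ts - (f - 1.0) / tf
    df = s
    dv = (f - outflow) / t0
    dq = (f * extraction / e0 - outflow * q / v) / t0
    return ds, df, dv, dq


@njit(inline="always")
def _rk4_step(s, f, v, q, eps, ts, tf, t0, e0, ialpha, u, dt):
    a1, b1, c1, d1 = _rhs(s, f, v, q, eps, ts, tf, t0, e0, ialpha, u)
    h = 0.5 * dt
    a2, b2, c2, d2 = _rhs(s + h * a1, f + h * b1, v + h * c1, q + h * d1,
                          eps, ts, tf, t0, e0, ialpha, u)
    a3, b3, c3, d3 = _rhs(s + h * a2, f + h * b2, v + h * c2, q + h * d2,
                          eps, ts, tf, t0, e0, ialpha, u)
    a4, b4, c4, d4 = _rhs(s + dt * a3, f + dt * b3, v + dt * c3, q + dt * d3,
                          eps, ts, tf, t0, e0, ialpha, u)
    w = dt / 6.0
    s += w * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
    f += w * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
    v += w * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
    q += w * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
    return s, f, v, q


@njit(inline="always")
def _floor3(f, v, q):
    n = 0
    if f < STATE_FLOOR:
        f = STATE_FLOOR
        n += 1
    if v < STATE_FLOOR:
        v = STATE_FLOOR
        n += 1
    if q < STATE_FLOOR:
        q = STATE_FLOOR
        n += 1
    return f, v, q, n


@njit
def integrate_balloon_traj(x0, eps, ts, tf, t0, e0, ialpha, u_seq, dt):
    """Integrate one Balloon trajectory; returns ((n+1, 4) array, floor count)."""
    n = u_seq.shape[0]
    out = np.empty((n + 1, 4))
    s, f, v, q = x0[0], x0[1], x0[2], x0[3]
    out[0, 0], out[0, 1], out[0, 2], out[0, 3] = s, f, v, q
    clamps = 0
    for k in range(n):
        s, f, v, q = _rk4_step(s, f, v, q, eps, ts, tf, t0, e0, ialpha,
                               u_seq[k], dt)
        f, v, q, c = _floor3(f, v, q)
        clamps += c
        out[k + 1, 0], out[k + 1, 1], out[k + 1, 2], out[k + 1, 3] = s, f, v, q
    return out, clamps


@njit
def propagate_balloon_batch(X, eps, ts, tf, t0, e0, ialpha, u_seq, dt):
    """Advance each row of X (m, 4) through len(u_seq) RK4 substeps, in place.

    eps..e0 are per-row parameter arrays of length m.
    """
    m = X.shape[0]
    clamps = 0
    for i in range(m):
        s, f, v, q = X[i, 0], X[i, 1], X[i, 2], X[i, 3]
        for k in range(u_seq.shape[0]):
            s, f, v, q = _rk4_step(s, f, v, q, eps[i], ts[i], tf[i], t0[i],
                                   e0[i], ialpha, u_seq[k], dt)
            f, v, q, c = _floor3(f, v, q)
            clamps += c
        X[i, 0], X[i, 1], X[i, 2], X[i, 3] = s, f, v, q
    return clamps


@njit(inline="always")
def _dcm_rk4_step(y, eps1, eps2, ts, tf, t0, e0, ialpha,
                  a11, a12, a21, a22, c1, c2, u1, u2, dt):
    """One RK4 step of the 10-state two-region system.

    State layout: [z1, z2, s1, f1, v1, q1, s2, f2, v2, q2].
    The neuronal state z_i takes the place of the extrinsic input in region
    i's flow-inducing-signal equation.
    """
    k1 = np.empty(10)
    k2 = np.empty(10)
    k3 = np.empty(10)
    k4 = np.empty(10)
    tmp = np.empty(10)

    for stage in range(4):
        if stage == 0:
            p = y
        elif stage == 1:
            for j in range(10):
                tmp[j] = y[j] + 0.5 * dt * k1[j]
            p = tmp
        elif stage == 2:
            for j in range(10):
                tmp[j] = y[j] + 0.5 * dt * k2[j]
            p = tmp
        else:
            for j in range(10):
                tmp[j] = y[j] + dt * k3[j]
            p = tmp
        z1, z2 = p[0], p[1]
        dz1 = a11 * z1 + a12 * z2 + c1 * u1
        dz2 = a21 * z1 + a22 * z2 + c2 * u2
        d1s, d1f, d1v, d1q = _rhs(p[2], p[3], p[4], p[5],
                                  eps1, ts, tf, t0, e0, ialpha, z1)
        d2s, d2f, d2v, d2q = _rhs(p[6], p[7], p[8], p[9],
                                  eps2, ts, tf, t0, e0, ialpha, z2)
        if stage == 0:
            k = k1
        elif stage == 1:
            k = k2
        elif stage == 2:
            k = k3
        else:
            k = k4
        k[0], k[1] = dz1, dz2
        k[2], k[3], k[4], k[5] = d1s, d1f, d1v, d1q
        k[6], k[7], k[8], k[9] = d2s, d2f, d2v, d2q

    out = np.empty(10)
    w = dt / 6.0
    for j in range(10):
        out[j] = y[j] + w * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
    return out


@njit(inline="always")
def _dcm_floor(y):
    n = 0
    for j in (3, 4, 5, 7, 8, 9):  # f1, v1, q1, f2, v2, q2
        if y[j] < STATE_FLOOR:
            y[j] = STATE_FLOOR
            n += 1
    return n


@njit
def integrate_dcm_traj(x0, eps1, eps2, ts, tf, t0, e0, ialpha,
                       a11, a12, a21, a22, c1, c2, u1_seq, u2_seq, dt):
    """Integrate one two-region trajectory; returns ((n+1, 10) array, floors)."""
    n = u1_seq.shape[0]
    out = np.empty((n + 1, 10))
    y = x0.copy()
    out[0] = y
    clamps = 0
    for k in range(n):
        y = _dcm_rk4_step(y, eps1, eps2, ts, tf, t0, e0, ialpha,
                          a11, a12, a21, a22, c1, c2,
                          u1_seq[k], u2_seq[k], dt)
        clamps += _dcm_floor(y)
        out[k + 1] = y
    return out, clamps


@njit
def propagate_dcm_batch(X, eps1, eps2, ts, tf, t0, e0, a12, a21, ialpha,
                        a11, a22, c1, c2, u1_seq, u2_seq, dt):
    """Advance each row of X (m, 10); per-row eps1, eps2, ts, tf, t0, e0, a12, a21."""
    m = X.shape[0]
    clamps = 0
    for i in range(m):
        y = X[i].copy()
        for k in range(u1_seq.shape[0]):
            y = _dcm_rk4_step(y, eps1[i], eps2[i], ts[i], tf[i], t0[i],
                              e0[i], ialpha, a11, a12[i], a21[i], a22,
                              c1, c2, u1_seq[k], u2_seq[k], dt)
            clamps += _dcm_floor(y)
        X[i] = y
    return clamps
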