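"""Fixed-step RK4 kernels (numba-compiled).

All kernels integrate on a uniform grid of ``n`` steps of size ``dt``.
Time-varying inputs are supplied pre-sampled on the half-step grid
(``2n + 1`` points at spacing ``dt/2``) so every RK4 stage sees the input
evaluated at exactly the right instant — no interpolation error enters the
integration itself.

Kernels fill caller-allocated state arrays and return the index of the first
step at which the state became non-finite, or -1 on success.
"""

import numpy as np
from numba import njit

__all__ = ["sim_coupled", "sim_msd", "sim_pendulum_driven"]


@njit(inline="always")
def _accel_coupled(x, xd, p, pd, u0, u0d, uff, mc, mp, l, g, K, B, nonlinear):
    # F = F_ff + B(x0d - xd) + K(x0 - x); then cart-pendulum accelerations
    # with the 2x2 mass matrix resolved algebraically.
    F = uff + B * (u0d - xd) + K * (u0 - x)
    if nonlinear:
        s = np.sin(p)
        c = np.cos(p)
        xdd = (mp * l * pd * pd * s + mp * g * s * c + F) / (mc + mp * s * s)
        pdd = -(xdd * c + g * s) / l
    else:
        xdd = (mp * g * p + F) / mc
        pdd = -(g * p + xdd) / l
    return xdd, pdd


@njit(cache=True)
def sim_coupled(mc, mp, l, g, K, B, x0h, x0dh, fffh, dt, n,
                x_init, xd_init, p_init, pd_init, nonlinear,
                xs, xds, ps, pds):
    """Integrate the coupled hand/cart-pendulum system.

    With K = B = 0 and ``fffh`` holding an applied-force profile this reduces
    to the bare object dynamics (nonlinear or linearized).
    """
    x = x_init
    xd = xd_init
    p = p_init
    pd = pd_init
    xs[0] = x
    xds[0] = xd
    ps[0] = p
    pds[0] = pd
    h = dt
    for i in range(n):
        j = 2 * i
        a1, b1 = _accel_coupled(x, xd, p, pd, x0h[j], x0dh[j], fffh[j],
                                mc, mp, l, g, K, B, nonlinear)
        x2 = x + 0.5 * h * xd
        xd2 = xd + 0.5 * h * a1
        p2 = p + 0.5 * h * pd
        pd2 = pd + 0.5 * h * b1
        a2, b2 = _accel_coupled(x2, xd2, p2, pd2, x0h[j + 1], x0dh[j + 1],
                                fffh[j + 1], mc, mp, l, g, K, B, nonlinear)
        x3 = x + 0.5 * h * xd2
        xd3 = xd + 0.5 * h * a2
        p3 = p + 0.5 * h * pd2
        pd3 = pd + 0.5 * h * b2
        a3, b3 = _accel_coupled(x3, xd3, p3, pd3, x0h[j + 1], x0dh[j + 1],
                                fffh[j + 1], mc, mp, l, g, K, B, nonlinear)
        x4 = x + h * xd3
        xd4 = xd + h * a3
        p4 = p + h * pd3
        pd4 = pd + h * b3
        a4, b4 = _accel_coupled(x4, xd4, p4, pd4, x0h[j + 2], x0dh[j + 2],
                                fffh[j + 2], mc, mp, l, g, K, B, nonlinear)
        x = x + (h / 6.0) * (xd + 2.0 * xd2 + 2.0 * xd3 + xd4)
        xd = xd + (h / 6.0) * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        p = p + (h / 6.0) * (pd + 2.0 * pd2 + 2.0 * pd3 + pd4)
        pd = pd + (h / 6.0) * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        if not (np.isfinite(x) and np.isfinite(xd)
                and np.isfinite(p) and np.isfinite(pd)):
            return i + 1
        xs[i + 1] = x
        xds[i + 1] = xd
        ps[i + 1] = p
        pds[i + 1] = pd
    return -1


@njit(cache=True)
def sim_msd(m, K, B, x0h, x0dh, dt, n, xs, xds):
    """Mass-spring-damper tracking a command: m*xdd = K(x0-x) + B(x0d-xd)."""
    x = 0.0
    xd = 0.0
    xs[0] = x
    xds[0] = xd
    h = dt
    for i in range(n):
        j = 2 * i
        a1 = (K * (x0h[j] - x) + B * (x0dh[j] - xd)) / m
        x2 = x + 0.5 * h * xd
        xd2 = xd + 0.5 * h * a1
        a2 = (K * (x0h[j + 1] - x2) + B * (x0dh[j + 1] - xd2)) / m
        x3 = x + 0.5 * h * xd2
        xd3 = xd + 0.5 * h * a2
        a3 = (K * (x0h[j + 1] - x3) + B * (x0dh[j + 1] - xd3)) / m
        x4 = x + h * xd3
        xd4 = xd + h * a3
        a4 = (K * (x0h[j + 2] - x4) + B * (x0dh[j + 2] - xd4)) / m
        x = x + (h / 6.0) * (xd + 2.0 * xd2 + 2.0 * xd3 + xd4)
        xd = xd + (h / 6.0) * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        if not (np.isfinite(x) and np.isfinite(xd)):
            return i + 1
        xs[i + 1] = x
        xds[i + 1] = xd
    return -1


@njit(cache=True)
def sim_pendulum_driven(g_over_l, inv_l, acch, dt, n, ps, pds):
    """Linearized pendulum driven by cart acceleration: pdd = -g/l*p - acc/l."""
    p = 0.0
    pd = 0.0
    ps[0] = p
    pds[0] = pd
    h = dt
    for i in range(n):
        j = 2 * i
        b1 = -g_over_l * p - inv_l * acch[j]
        p2 = p + 0.5 * h * pd
        pd2 = pd + 0.5 * h * b1
        b2 = -g_over_l * p2 - inv_l * acch[j + 1]
        p3 = p + 0.5 * h * pd2
        pd3 = pd + 0.5 * h * b2
        b3 = -g_over_l * p3 - inv_l * acch[j + 1]
        p4 = p + h * pd3
        pd4 = pd + h * b3
        b4 = -g_over_l * p4 - inv_l * acch[j + 2]
        p = p + (h / 6.0) * (pd + 2.0 * pd2 + 2.0 * pd3 + pd4)
        pd = pd + (h / 6.0) * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        if not (np.isfinite(p) and np.isfinite(pd)):
            return i + 1
        ps[i + 1] = p
        pds[i + 1] = pd
    return -1
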