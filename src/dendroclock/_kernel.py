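"""Packed-vector kinetics and fixed-step integration loops.

These functions mirror :mod:`dendroclock.kinetics` on flat float64 arrays
so the inner stepping loop can be JIT-compiled with numba.  When numba is
not importable the same source runs as plain Python (slower, identical
results).  The correspondence between the packed RHS and the reference
implementation is asserted in the test suite.

State vector layout (see :data:`dendroclock.state.SPECIES`):
``[x, y, AC, cAMP, PKA, PDE, RGS, z]``.

Stimulus onsets are passed as absolute times; ``NO_EVENT`` encodes "no
such stimulus yet".  All window indicators are evaluated at the end time
of the step, inside the implicit solve.
"""

from __future__ import annotations

import numpy as np

from .params import PARAM_INDEX

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


NO_EVENT = -1.0e30

# unpack parameter indices as module constants (frozen into compiled code)
_P = PARAM_INDEX
P_K1 = _P["k1"]; P_K2 = _P["k2"]; P_ALPHA = _P["alpha_store"]
P_BETA = _P["beta"]; P_GAMMA = _P["gamma"]; P_H = _P["h"]; P_N = _P["n"]
P_BCA = _P["B_Ca"]; P_PKAGAIN = _P["pka_gain"]; P_XINIT = _P["x_init_on_CS"]
P_CAWIN = _P["ca_window"]
P_GIA = _P["gi_a"]; P_GIB = _P["gi_b"]; P_GIRISE = _P["gi_rise_window"]
P_GIOFF = _P["gi_off_time"]
P_R1BL = _P["r1_bl"]; P_RCAG = _P["r_cag"]; P_KCAAC = _P["K_ca_AC"]
P_KGI = _P["K_Gi"]; P_R2BL = _P["r2_bl"]; P_RCA = _P["r_ca"]
P_K8 = _P["k8"]; P_K10 = _P["k10"]; P_KM = _P["km"]
P_KA7 = _P["ka7"]; P_K7 = _P["k7"]
P_K13 = _P["k13"]; P_K14 = _P["k14"]; P_KM2 = _P["km2"]; P_K15 = _P["k15"]
P_R5 = _P["r5"]; P_R6 = _P["r6"]; P_ZTHR = _P["z_threshold"]
P_R3BL = _P["r3_bl"]; P_KCARGS = _P["K_ca_RGS"]; P_R4 = _P["r4"]
P_KG = _P["K_g"]; P_GSAMP = _P["gs_amplitude"]; P_GSWIN = _P["gs_window"]
P_ACTOT = _P["AC_total"]; P_PKATOT = _P["PKA_total"]; P_PDETOT = _P["PDE_total"]

NSPECIES = 8
IX, IY, IAC, ICAMP, IPKA, IPDE, IRGS, IZ = range(NSPECIES)


@njit(cache=True)
def algebraic_inputs(t, s, p, cs_time, us_time):
    """Return (Ca, Gi, Gs) at absolute time t for state vector s."""
    # synaptic calcium read-out
    Ca = p[P_BCA]
    if cs_time > NO_EVENT / 2:
        tc = t - cs_time
        if 0.0 <= tc <= p[P_CAWIN]:
            y = s[IY]
            if y < 0.0:
                y = 0.0
            Ca = (1.0 + p[P_PKAGAIN] * s[IPKA]) * y
    # CS-driven Gi transient: exponential rise, hold, shut-off
    Gi = 0.0
    if cs_time > NO_EVENT / 2:
        tc = t - cs_time
        if 0.0 <= tc < p[P_GIOFF]:
            te = tc if tc < p[P_GIRISE] else p[P_GIRISE]
            Gi = p[P_GIA] * np.exp(p[P_GIB] * te)
    # US-driven Gs, suppressed by active RGS
    Gs = 0.0
    if us_time > NO_EVENT / 2:
        tu = t - us_time
        if 0.0 <= tu <= p[P_GSWIN]:
            kg3 = p[P_KG] ** 3
            rgs = s[IRGS]
            if rgs < 0.0:
                rgs = 0.0
            Gs = p[P_GSAMP] * kg3 / (kg3 + rgs ** 3)
    return Ca, Gi, Gs


@njit(cache=True)
def rhs(t, s, p, cs_time, us_time, out):
    """Full 8-species right-hand side at absolute time t."""
    Ca, Gi, Gs = algebraic_inputs(t, s, p, cs_time, us_time)

    # calcium store (clock)
    x = s[IX]
    y = s[IY]
    if y > 0.0:
        fy = 1.0 / (1.0 + (p[P_H] / y) ** p[P_N])
    else:
        fy = 0.0
    exchange = p[P_K1] * y - p[P_K2] * x - p[P_ALPHA] * fy * x
    out[IX] = exchange
    out[IY] = -exchange + p[P_GAMMA] - p[P_BETA] * y

    # adenylyl cyclase (coincidence detector)
    ca3 = Ca ** 3 if Ca > 0.0 else 0.0
    hill_ca = ca3 / (p[P_KCAAC] ** 3 + ca3)
    r1 = p[P_R1BL] + p[P_RCAG] * Gs * hill_ca * p[P_KGI] / (p[P_KGI] + Gi)
    r2 = p[P_R2BL] + p[P_RCA] * Ca
    ACi = p[P_ACTOT] - s[IAC]
    out[IAC] = r1 * ACi - r2 * s[IAC]

    # cAMP / PKA / PDE loop
    camp = s[ICAMP]
    out[ICAMP] = p[P_K8] * s[IAC] - p[P_K10] * s[IPDE] * camp / (p[P_KM] + camp)
    PKAi = p[P_PKATOT] - s[IPKA]
    out[IPKA] = p[P_KA7] * PKAi * camp - p[P_K7] * s[IPKA]
    PDEi = p[P_PDETOT] - s[IPDE]
    out[IPDE] = p[P_K13] + p[P_K14] * s[IPKA] * PDEi / (p[P_KM2] + PDEi) - p[P_K15] * s[IPDE]

    # RGS switch and gating variable
    alpha = 1.0 if s[IZ] > p[P_ZTHR] else 0.0
    out[IRGS] = (p[P_R5] + alpha) * (1.0 - s[IRGS]) - p[P_R6] * s[IRGS]
    if Ca > 0.0:
        r3 = p[P_R3BL] * Ca * Ca / (p[P_KCARGS] + Ca)
    else:
        r3 = 0.0
    out[IZ] = r3 * (1.0 - s[IZ]) - p[P_R4] * s[IZ]


@njit(cache=True)
def be_step(t_end, s, dt, p, cs_time, us_time, tol, max_iter):
    """One backward-Euler step to absolute time ``t_end``.

    Solves s' = s + dt·F(t_end, s') by Newton iteration with a
    finite-difference Jacobian; the explicit Euler value seeds the
    iteration.  Returns (s', n_iter) with n_iter = -1 on non-convergence.
    Window indicators and the z switch are evaluated at the end-of-step
    time/state; nothing is clamped.
    """
    f = np.empty(NSPECIES)
    rhs(t_end, s, p, cs_time, us_time, f)
    sp = s + dt * f  # predictor
    g = np.empty(NSPECIES)
    jac = np.empty((NSPECIES, NSPECIES))
    fpert = np.empty(NSPECIES)
    scale = 1.0 + np.max(np.abs(s))
    for it in range(max_iter):
        rhs(t_end, sp, p, cs_time, us_time, f)
        for i in range(NSPECIES):
            g[i] = sp[i] - s[i] - dt * f[i]
        res = 0.0
        for i in range(NSPECIES):
            a = abs(g[i])
            if a > res:
                res = a
        if res <= tol * scale:
            return sp, it
        # finite-difference Jacobian of G = s' - s - dt F(s')
        for j in range(NSPECIES):
            eps = 1e-7 * (1.0 + abs(sp[j]))
            tmp = sp[j]
            sp[j] = tmp + eps
            rhs(t_end, sp, p, cs_time, us_time, fpert)
            sp[j] = tmp
            for i in range(NSPECIES):
                jac[i, j] = (1.0 if i == j else 0.0) - dt * (fpert[i] - f[i]) / eps
        delta = np.linalg.solve(jac, g)
        sp = sp - delta
    # final residual check after the last update
    rhs(t_end, sp, p, cs_time, us_time, f)
    res = 0.0
    for i in range(NSPECIES):
        a = abs(sp[i] - s[i] - dt * f[i])
        if a > res:
            res = a
    if res <= tol * scale:
        return sp, max_iter
    return sp, -1


@njit(cache=True)
def integrate_be(s, t0, n_steps, dt, p, cs_time, us_time, tol, max_iter,
                 record_stride, step_offset, rec):
    """Run ``n_steps`` backward-Euler steps from t0, recording every state
    whose *global* step index (``step_offset + local step``) is a multiple
    of ``record_stride`` into ``rec`` (shape (n_rec, NSPECIES)).

    The caller sizes ``rec`` and records the t = 0 sample itself.  Returns
    (final_state, n_recorded, status, t_fail); status 0 = ok, 1 = Newton
    failed to converge at absolute time t_fail.
    """
    cur = s.copy()
    k = 0
    for step_i in range(n_steps):
        t_end = t0 + (step_i + 1) * dt
        cur, nit = be_step(t_end, cur, dt, p, cs_time, us_time, tol, max_iter)
        if nit < 0:
            return cur, k, 1, t_end
        if (step_offset + step_i + 1) % record_stride == 0:
            rec[k, :] = cur
            k += 1
    return cur, k, 0, 0.0


@njit(cache=True)
def integrate_rk4(s, t0, n_steps, dt, p, cs_time, us_time,
                  record_stride, step_offset, rec):
    """Classical explicit RK4 over the same grid (cross-validation oracle)."""
    cur = s.copy()
    k1v = np.empty(NSPECIES)
    k2v = np.empty(NSPECIES)
    k3v = np.empty(NSPECIES)
    k4v = np.empty(NSPECIES)
    k = 0
    for step_i in range(n_steps):
        t = t0 + step_i * dt
        rhs(t, cur, p, cs_time, us_time, k1v)
        rhs(t + 0.5 * dt, cur + 0.5 * dt * k1v, p, cs_time, us_time, k2v)
        rhs(t + 0.5 * dt, cur + 0.5 * dt * k2v, p, cs_time, us_time, k3v)
        rhs(t + dt, cur + dt * k3v, p, cs_time, us_time, k4v)
        cur = cur + (dt / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        if (step_offset + step_i + 1) % record_stride == 0:
            rec[k, :] = cur
            k += 1
    return cur, k, 0, 0.0
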