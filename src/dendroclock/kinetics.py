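"""Right-hand-side kinetics of every subsystem.

The cascade couples four blocks:

* a **calcium store** (Somogyi-Stucki-type oscillator) acting as the clock:
  pool calcium ``x`` leaks into the cytosol ``y`` and is amplified by
  calcium-induced calcium release (CICR) through the Hill gate ``f(y)``;
* a **synaptic calcium read-out** ``[Ca] = (1 + g·[PKA])·y`` that is only
  live for a fixed window after the CS, and sits at a basal level otherwise
  — the PKA factor is the positive feedback that speeds the clock up
  across pairings;
* an **adenylyl-cyclase coincidence detector**: the AC activation rate
  only rises above baseline when calcium (CS-driven) and stimulatory G
  protein Gs (US-driven) are present together, and is inhibited by the
  CS-driven Gi transient; AC feeds the cAMP→PKA→PDE loop;
* an **RGS negative feedback**: a calcium-gated variable ``z`` trips a
  hard switch that activates RGS, which in turn suppresses Gs production —
  the time at which this switch trips, relative to the CS, is the model's
  timed output.

All functions are pure and operate on floats; the integrator uses a packed
vector equivalent (see :mod:`dendroclock._kernel`) that is cross-checked
against these reference implementations in the test suite.
"""

from __future__ import annotations

from typing import Optional

from .params import ModelParameters
from .state import ModelState

__all__ = [
    "f_cicr",
    "calcium_store_rhs",
    "effective_calcium",
    "gi_input",
    "gs_input",
    "ac_rates",
    "pka_pathway_rhs",
    "rgs_switch",
    "rgs_rhs",
    "full_rhs",
]


def f_cicr(y: float, h: float, n: float) -> float:
    """CICR activation fraction ``y^n / (y^n + h^n)``.

    Monotone non-decreasing in ``y``, in ``[0, 1)``.
    """
    if y < 0:
        raise ValueError(f"cytosolic calcium must be >= 0, got {y}")
    if h <= 0:
        raise ValueError(f"half-activation h must be > 0, got {h}")
    if y == 0.0:
        return 0.0
    # ratio form in log space: safe for y far above or below h
    import math

    ln_r = n * (math.log(h) - math.log(y))
    if ln_r > 700.0:
        return 0.0
    if ln_r < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(ln_r))


def calcium_store_rhs(state: ModelState, params: ModelParameters) -> tuple[float, float]:
    """Time derivatives (dx/dt, dy/dt) of the store oscillator.

    dx/dt = k1·y − k2·x − α·f(y)·x
    dy/dt = k2·x − k1·y + α·f(y)·x + γ − β·y

    The exchange terms cancel pairwise, so d(x+y)/dt = γ − β·y exactly:
    total calcium changes only through influx and removal.
    """
    x, y = state.x, state.y
    exchange = params.k1 * y - params.k2 * x - params.alpha_store * f_cicr(y, params.h, params.n) * x
    dx = exchange
    dy = -exchange + params.gamma - params.beta * y
    return dx, dy


def effective_calcium(state: ModelState, params: ModelParameters) -> float:
    """Synaptic calcium read-out.

    Basal (``B_Ca``) outside the post-CS window; ``(1 + g·[PKA])·y`` while
    the window is live.  The PKA factor is how learning feeds back on the
    clock: a trained (high-PKA) dendrite sees an amplified calcium signal
    from the identical store trajectory.
    """
    t = state.t_since_CS
    if t is None or t > params.ca_window or t < 0:
        return params.B_Ca
    return (1.0 + params.pka_gain * state.PKA) * state.y


def gi_input(t_since_CS: Optional[float], params: ModelParameters) -> float:
    """CS-driven inhibitory G-alpha transient.

    Grows exponentially (``a·e^{b·t}``) for ``gi_rise_window`` seconds,
    holds its end value until ``gi_off_time``, then is deactivated.
    """
    if t_since_CS is None:
        return 0.0
    t = t_since_CS
    if t < 0:
        raise ValueError(f"time since CS must be >= 0, got {t}")
    if t >= params.gi_off_time:
        return 0.0
    import math
    t_eff = min(t, params.gi_rise_window)
    return params.gi_a * math.exp(params.gi_b * t_eff)


def gs_input(t_since_US: Optional[float], RGS: float, params: ModelParameters) -> float:
    """US-driven stimulatory G-alpha level, suppressed by active RGS.

    ``gs_amplitude · K_g³ / (K_g³ + RGS³)`` during the ``gs_window`` after
    the US, zero otherwise.  Strictly decreasing in RGS: once the negative
    feedback anticipates the US, the teaching signal is attenuated.
    """
    if t_since_US is None or t_since_US > params.gs_window or t_since_US < 0:
        return 0.0
    kg3 = params.K_g ** 3
    return params.gs_amplitude * kg3 / (kg3 + RGS ** 3)


def ac_rates(Ca: float, Gs: float, Gi: float, params: ModelParameters) -> tuple[float, float]:
    """Activation and deactivation rates (r1, r2) of adenylyl cyclase.

    r1 = r1_bl + r_cag·Gs·Ca³/(K_ca_AC³ + Ca³)·K_Gi/(K_Gi + Gi)
    r2 = r2_bl + r_ca·Ca

    The synergy term vanishes whenever Gs = 0: calcium alone never raises
    the activation rate above baseline.  This is the coincidence-detector
    property — AC only responds to the *joint* presence of the CS-driven
    calcium signal and the US-driven Gs.
    """
    ca3 = Ca ** 3
    hill_ca = ca3 / (params.K_ca_AC ** 3 + ca3) if ca3 > 0 else 0.0
    inhib = params.K_Gi / (params.K_Gi + Gi)
    r1 = params.r1_bl + params.r_cag * Gs * hill_ca * inhib
    r2 = params.r2_bl + params.r_ca * Ca
    return r1, r2


def pka_pathway_rhs(state: ModelState, params: ModelParameters) -> tuple[float, float, float, float]:
    """Derivatives (dAC/dt, dcAMP/dt, dPKA/dt, dPDE/dt).

    Inactive pools are closed by strict conservation:
    [ACi] = AC_total − [AC], [PKAi] = PKA_total − [PKA],
    [PDEi] = PDE_total − [PDE].

    dAC/dt   = r1·[ACi] − r2·[AC]
    dcAMP/dt = k8·[AC] − k10·[PDE]·[cAMP]/(km + [cAMP])
    dPKA/dt  = ka7·[PKAi]·[cAMP] − k7·[PKA]
    dPDE/dt  = k13 + k14·[PKA]·[PDEi]/(km2 + [PDEi]) − k15·[PDE]
    """
    tol = 1e-9
    for name, active, total in (
        ("AC", state.AC, params.AC_total),
        ("PKA", state.PKA, params.PKA_total),
        ("PDE", state.PDE, params.PDE_total),
    ):
        if active > total + tol:
            raise ValueError(f"active {name} = {active} exceeds total {total}")
    Ca = effective_calcium(state, params)
    Gi = gi_input(state.t_since_CS, params)
    Gs = gs_input(state.t_since_US, state.RGS, params)
    r1, r2 = ac_rates(Ca, Gs, Gi, params)
    ACi = params.AC_total - state.AC
    PKAi = params.PKA_total - state.PKA
    PDEi = params.PDE_total - state.PDE
    dAC = r1 * ACi - r2 * state.AC
    dcAMP = params.k8 * state.AC - params.k10 * state.PDE * state.cAMP / (params.km + state.cAMP)
    dPKA = params.ka7 * PKAi * state.cAMP - params.k7 * state.PKA
    dPDE = params.k13 + params.k14 * state.PKA * PDEi / (params.km2 + PDEi) - params.k15 * state.PDE
    return dAC, dcAMP, dPKA, dPDE


def rgs_switch(z: float, params: ModelParameters) -> int:
    """Hard switch gating RGS activation: 1 if ``z`` strictly exceeds the
    threshold, else 0."""
    return 1 if z > params.z_threshold else 0


def rgs_rhs(state: ModelState, Ca: float, params: ModelParameters) -> tuple[float, float]:
    """Derivatives (dRGS/dt, dz/dt) of the negative-feedback arm.

    dRGS/dt = (r5 + α(z))·(1 − RGS) − r6·RGS
    dz/dt   = r3·(1 − z) − r4·z,   r3 = r3_bl·Ca²/(K_ca_RGS + Ca)

    The r3 drive is quadratic in calcium against a linear Michaelis
    denominator (implemented exactly in that form), so the ratio of trained
    to naive drive approaches the square of the PKA amplification factor
    while calcium stays below K_ca_RGS.
    """
    alpha = float(rgs_switch(state.z, params))
    dRGS = (params.r5 + alpha) * (1.0 - state.RGS) - params.r6 * state.RGS
    r3 = params.r3_bl * Ca * Ca / (params.K_ca_RGS + Ca)
    dz = r3 * (1.0 - state.z) - params.r4 * state.z
    return dRGS, dz


def full_rhs(state: ModelState, params: ModelParameters) -> ModelState:
    """All eight species derivatives, returned as a ModelState whose fields
    hold d/dt values (timers and algebraic fields copied through as-is).

    Provided for inspection and cross-checks; the integrator uses the
    packed-vector kernel.
    """
    dx, dy = calcium_store_rhs(state, params)
    dAC, dcAMP, dPKA, dPDE = pka_pathway_rhs(state, params)
    Ca = effective_calcium(state, params)
    dRGS, dz = rgs_rhs(state, Ca, params)
    out = state.copy()
    out.x, out.y = dx, dy
    out.AC, out.cAMP, out.PKA, out.PDE = dAC, dcAMP, dPKA, dPDE
    out.RGS, out.z = dRGS, dz
    out.Ca = Ca
    out.Gi = gi_input(state.t_since_CS, params)
    out.Gs = gs_input(state.t_since_US, state.RGS, params)
    return out
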