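"""Instantaneous model state.

The dynamical state of the cascade is eight concentrations:

====== =================================================================
symbol meaning
====== =================================================================
x      calcium inside the local store (pool), µM
y      cytosolic calcium of the store oscillator, µM
AC     active adenylyl cyclase, µM
cAMP   cyclic AMP, µM
PKA    active protein kinase A, µM
PDE    active phosphodiesterase, µM
RGS    active RGS fraction (dimensionless, in [0, 1])
z      calcium-gated auxiliary variable driving the RGS switch, in [0, 1]
====== =================================================================

The synaptic calcium read-out ``Ca``, the inhibitory G protein ``Gi`` and
the stimulatory G protein ``Gs`` are algebraic functions of this state and
of the time since the most recent CS/US onset; they are stored on
:class:`ModelState` for inspection but are recomputed, never integrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .params import ModelParameters

__all__ = ["ModelState", "SPECIES", "resting_state"]

#: order of the dynamical species in packed state vectors
SPECIES: tuple[str, ...] = ("x", "y", "AC", "cAMP", "PKA", "PDE", "RGS", "z")

#: algebraic (driven) quantities recorded alongside the dynamical species
ALGEBRAIC: tuple[str, ...] = ("Ca", "Gi", "Gs")


@dataclass
class ModelState:
    """Concentrations of every dynamical species plus stimulus timers.

    ``t_since_CS`` / ``t_since_US`` are ``None`` before the first CS/US of
    the current trial.
    """

    x: float = 0.0
    y: float = 0.0
    Ca: float = 0.0
    Gi: float = 0.0
    Gs: float = 0.0
    AC: float = 0.0
    cAMP: float = 0.0
    PKA: float = 0.0
    PDE: float = 0.0
    RGS: float = 0.0
    z: float = 0.0
    t_since_CS: Optional[float] = None
    t_since_US: Optional[float] = None

    def validate(self, params: ModelParameters) -> None:
        """Raise if conservation or sign invariants are violated."""
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            raise ValueError("non-finite concentration in state")
        if min(self.x, self.y, self.Ca, self.cAMP) < 0:
            raise ValueError("negative concentration in state")
        tol = 1e-9
        if not -tol <= self.RGS <= 1 + tol or not -tol <= self.z <= 1 + tol:
            raise ValueError("RGS and z must lie in [0, 1]")
        for name, active, total in (
            ("AC", self.AC, params.AC_total),
            ("PKA", self.PKA, params.PKA_total),
            ("PDE", self.PDE, params.PDE_total),
        ):
            if active < -tol or active > total + tol:
                raise ValueError(
                    f"active {name} = {active} outside [0, {name}_total = {total}]"
                )

    # -- vector packing ------------------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=np.float64)

    def with_vector(self, vec: np.ndarray) -> "ModelState":
        kw = {s: float(vec[i]) for i, s in enumerate(SPECIES)}
        return replace(self, **kw)

    def copy(self) -> "ModelState":
        return replace(self)


def resting_state(params: ModelParameters) -> ModelState:
    """Unstimulated initial state before the first trial.

    The store oscillator sits at its unstimulated fixed point (``y`` at the
    influx/removal balance gamma/beta, ``x`` balancing the exchange fluxes),
    the synaptic read-out at the basal level, and the enzymes at the printed
    initial concentrations with inactive pools given by total − active.
    RGS and z start at zero.
    """
    y0 = params.gamma / params.beta if params.beta > 0 else 0.0
    fy = y0 ** params.n / (y0 ** params.n + params.h ** params.n) if y0 > 0 else 0.0
    denom = params.k2 + params.alpha_store * fy
    x0 = params.k1 * y0 / denom if denom > 0 else 0.0
    if not math.isfinite(x0):
        x0 = 0.0
    return ModelState(
        x=x0,
        y=y0,
        Ca=params.B_Ca,
        Gi=0.0,
        Gs=0.0,
        AC=params.AC_total - params.init_ACi,
        cAMP=params.init_cAMP,
        PKA=params.PKA_total - params.init_PKAi,
        PDE=params.init_PDE,
        RGS=0.0,
        z=0.0,
        t_since_CS=None,
        t_since_US=None,
    )
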