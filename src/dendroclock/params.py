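"""Model parameters for the dendritic interval-learning cascade.

All concentrations are in µM and all times in seconds.  A single
:class:`ModelParameters` instance carries every rate constant, threshold,
Hill constant, conserved total and stimulus-window duration used by the
kinetics.  The shipped defaults (``data/default_params.yaml``) are a
re-calibrated, non-authoritative set obtained with the constraint suite in
:mod:`dendroclock.calibration`; they are not transcribed from any published
table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "PARAM_FIELDS",
]


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, thresholds and totals of the signalling cascade.

    Units: concentrations µM, time s; rate constants carry the inverse
    units implied by their mass-action or Michaelis-Menten role.
    """

    # -- calcium store (Somogyi-Stucki oscillator) --------------------------
    k1: float = 0.05          # cytosol -> pool uptake rate (1/s)
    k2: float = 1.7         # pool -> cytosol leak rate (1/s)
    alpha_store: float = 0.15  # CICR flux coefficient (1/s), multiplies f(y)*x
    beta: float = 45.0        # cytosolic removal rate (1/s)
    gamma: float = 2.25     # constant cytosolic influx (µM/s)
    h: float = 0.45           # CICR half-activation of f(y) (µM)
    n: float = 4.0           # CICR Hill exponent (dimensionless)

    # -- synaptic calcium read-out ------------------------------------------
    B_Ca: float = 0.05       # basal synaptic calcium (µM)
    pka_gain: float = 10.0   # PKA multiplier in the release factor (1/µM)
    x_init_on_CS: float = 25.0  # pool calcium set-point at CS arrival (µM)
    ca_window: float = 2.0   # duration of the amplified read-out after CS (s)

    # -- CS-driven inhibitory G protein -------------------------------------
    gi_a: float = 1.0        # Gi transient amplitude (µM)
    gi_b: float = 1.9        # Gi exponential growth rate (1/s)
    gi_rise_window: float = 1.2  # duration of Gi growth after CS (s)
    gi_off_time: float = 2.0     # time after CS at which Gi is zeroed (s)

    # -- adenylyl cyclase activation / deactivation -------------------------
    r1_bl: float = 1e-5      # baseline AC activation rate (1/s)
    r_cag: float = 13.0       # Ca/Gs synergy gain (1/(µM·s))
    K_ca_AC: float = 0.9     # calcium half-activation of AC, cubed Hill (µM)
    K_Gi: float = 0.2        # Gi half-inhibition of AC activation (µM)
    r2_bl: float = 0.6       # baseline AC deactivation rate (1/s)
    r_ca: float = 0.05       # calcium-dependent AC deactivation (1/(µM·s))

    # -- cAMP / PKA / PDE loop ----------------------------------------------
    k8: float = 300.0         # cAMP synthesis rate per active AC (1/s)
    k10: float = 400.0         # PDE-mediated hydrolysis Vmax factor (1/s)
    km: float = 20.0          # cAMP hydrolysis Michaelis constant (µM)
    ka7: float = 0.0125        # PKA activation per cAMP (1/(µM·s))
    k7: float = 2e-4         # PKA deactivation rate (1/s)
    k13: float = 5e-3        # PDE basal activation (µM/s)
    k14: float = 0.2        # PKA-dependent PDE activation Vmax factor (1/s)
    km2: float = 2.0         # Michaelis constant of PDE activation (µM)
    k15: float = 0.05        # PDE deactivation rate (1/s)

    # -- RGS switch ----------------------------------------------------------
    r5: float = 1e-3         # RGS baseline activation rate (1/s)
    r6: float = 0.3          # RGS deactivation rate (1/s)
    z_threshold: float = 0.1  # switch level of the gating variable z
    r3_bl: float = 0.19       # z activation scale (1/(µM·s))
    K_ca_RGS: float = 0.2   # calcium constant of the z drive (µM)
    r4: float = 0.5          # z decay rate (1/s)

    # -- US-driven stimulatory G protein ------------------------------------
    K_g: float = 0.5         # RGS half-suppression constant for Gs (µM)
    gs_amplitude: float = 5.0  # Gs scale (µM)
    gs_window: float = 0.2   # Gs generation window after US (s)

    # -- conserved totals and initial concentrations ------------------------
    AC_total: float = 0.1    # active + inactive adenylyl cyclase (µM)
    PKA_total: float = 1.0   # active + inactive PKA (µM)
    PDE_total: float = 5.1   # active + inactive PDE (µM)
    init_ACi: float = 0.1    # initial inactive AC (µM)
    init_cAMP: float = 1.9   # initial cAMP (µM)
    init_PKAi: float = 1.0   # initial inactive PKA (µM)
    init_PDE: float = 0.1    # initial active PDE (µM)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        """Check sign constraints, Hill exponents and window orderings."""
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v!r}")
            if f.name == "gi_b":
                continue  # the exponential rate may have either sign
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        if self.n < 1:
            raise ValueError(f"Hill exponent n must be >= 1, got {self.n}")
        if not 0 < self.z_threshold < 1:
            raise ValueError("z_threshold must lie in (0, 1)")
        if self.h <= 0:
            raise ValueError("CICR half-activation h must be positive")
        if self.ca_window < self.gi_rise_window:
            raise ValueError("ca_window must be >= gi_rise_window")
        if self.gi_off_time < self.gi_rise_window:
            raise ValueError("gi_off_time must be >= gi_rise_window")
        for name, total, inact in (
            ("AC", self.AC_total, self.init_ACi),
            ("PKA", self.PKA_total, self.init_PKAi),
        ):
            if inact > total * (1 + 1e-12):
                raise ValueError(f"init_{name}i exceeds {name}_total")
        if self.init_PDE > self.PDE_total * (1 + 1e-12):
            raise ValueError("init_PDE exceeds PDE_total")

    # -- conversion helpers --------------------------------------------------
    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(
                f"unknown parameter keys: {sorted(unknown)}; "
                f"expected a subset of {sorted(known)}"
            )
        return cls(**{k: float(v) for k, v in d.items()})

    def to_array(self) -> np.ndarray:
        """Pack into a flat float64 vector (order :data:`PARAM_FIELDS`)."""
        return np.array([getattr(self, name) for name in PARAM_FIELDS], dtype=np.float64)

    def hash(self) -> str:
        """Stable short hash identifying the parameter set."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())


PARAM_FIELDS: tuple[str, ...] = tuple(f.name for f in fields(ModelParameters))

#: index of each parameter in the packed array used by the compiled kernels
PARAM_INDEX: dict[str, int] = {name: i for i, name in enumerate(PARAM_FIELDS)}


def initial_condition_preset(reading: str = "pde_pool") -> dict[str, float]:
    """Return total/initial concentration fields for the two printed readings.

    The printed initial-condition list assigns 0.1 and 5 µM to what is
    literally the same symbol (inactive adenylyl cyclase), which cannot both
    hold.  Two self-consistent readings are exposed:

    ``"pde_pool"``
        0.1 µM is the inactive AC pool and 5 µM the inactive PDE pool
        (consistent with the Michaelis dependence of PDE activation on a
        sizeable inactive-PDE reservoir).  This is the default.
    ``"ac_pool"``
        0.1 µM is the *active* AC and 5 µM the inactive AC pool; the
        inactive PDE pool is then unspecified and set equal to the PDE
        total minus the printed active PDE.
    """
    if reading == "pde_pool":
        return {
            "AC_total": 0.1, "init_ACi": 0.1,
            "PKA_total": 1.0, "init_PKAi": 1.0,
            "PDE_total": 5.1, "init_PDE": 0.1,
            "init_cAMP": 1.9,
        }
    if reading == "ac_pool":
        return {
            "AC_total": 5.1, "init_ACi": 5.0,
            "PKA_total": 1.0, "init_PKAi": 1.0,
            "PDE_total": 0.1, "init_PDE": 0.1,
            "init_cAMP": 1.9,
        }
    raise ValueError(f"unknown initial-condition reading: {reading!r}")


def default_parameters() -> ModelParameters:
    """The shipped re-calibrated default parameter set."""
    with resources.files("dendroclock").joinpath("data/default_params.yaml").open() as fh:
        d = yaml.safe_load(fh)
    d.pop("_meta", None)
    return ModelParameters.from_dict(d)


def load_parameters(path: str | Path) -> ModelParameters:
    """Load parameters from a flat YAML/JSON key-value file.

    Unknown keys are an error; omitted keys fall back to the dataclass
    defaults (which equal the shipped set).
    """
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, Mapping):
        raise ValueError(f"parameter file {path} must contain a mapping")
    d = dict(d)
    d.pop("_meta", None)
    return ModelParameters.from_dict(d)


def save_parameters(params: ModelParameters, path: str | Path, meta: Mapping[str, Any] | None = None) -> None:
    d: dict[str, Any] = params.to_dict()
    if meta:
        d["_meta"] = dict(meta)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
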