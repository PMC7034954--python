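"""CS-US conditioning protocols.

A :class:`Trial` is one pairing: a CS (parallel-fibre) onset and,
optionally, a US (climbing-fibre) onset inside a simulated trial window.
The inter-stimulus interval (ISI) is their onset-to-onset difference —
the quantity the cascade learns.  ``cs_duration`` and ``cs_strength`` are
descriptors of the parallel-fibre drive retained purely to *test* the
decoupling property: the cascade reads only the CS onset, so they must
never affect the dynamics.

Between trials the slow species (AC, cAMP, PKA, PDE, RGS, z) persist and
relax without stimulation for the inter-trial interval; the fast
stimulus-driven quantities (pool and cytosolic calcium, Gi, Gs and the
stimulus clocks) are re-initialised at each CS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .integrator import IntegratorConfig, integrate
from .params import ModelParameters
from .state import ModelState, resting_state
from .trace import SimulationTrace

__all__ = ["Trial", "StimulusProtocol", "run_trial", "run_training"]

#: species that persist across trials; everything else is stimulus-driven
CARRY_OVER_SPECIES: tuple[str, ...] = ("AC", "cAMP", "PKA", "PDE", "RGS", "z")

#: padding after the last onset so that all 2 s stimulus windows complete
TRIAL_TAIL = 2.5


@dataclass(frozen=True)
class Trial:
    """One conditioning trial.

    ``us_onset=None`` denotes a CS-alone probe.  ``trial_duration=None``
    defaults to the last onset plus :data:`TRIAL_TAIL` seconds so every
    stimulus window closes before carry-over.
    """

    cs_onset: float = 0.1
    us_onset: Optional[float] = None
    cs_duration: float = 0.025
    cs_strength: float = 1.0
    trial_duration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cs_onset < 0:
            raise ValueError("cs_onset must be >= 0")
        if self.us_onset is not None and self.us_onset <= self.cs_onset:
            raise ValueError("us_onset must come strictly after cs_onset")
        if self.trial_duration is not None and self.trial_duration <= self.last_onset + 2.0:
            raise ValueError("trial_duration must exceed the last onset by > 2 s")

    @property
    def last_onset(self) -> float:
        return self.cs_onset if self.us_onset is None else self.us_onset

    @property
    def isi(self) -> Optional[float]:
        """Inter-stimulus interval (onset-to-onset), None for CS-alone."""
        if self.us_onset is None:
            return None
        return self.us_onset - self.cs_onset

    @property
    def duration(self) -> float:
        if self.trial_duration is not None:
            return self.trial_duration
        return self.last_onset + TRIAL_TAIL


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered trials plus inter-trial relaxation time."""

    trials: tuple[Trial, ...]
    inter_trial_interval: float = 10.0

    def __post_init__(self) -> None:
        if len(self.trials) < 1:
            raise ValueError("a protocol needs at least one trial")
        if self.inter_trial_interval < 0:
            raise ValueError("inter_trial_interval must be >= 0")
        object.__setattr__(self, "trials", tuple(self.trials))

    @property
    def carry_over_rule(self) -> tuple[str, ...]:
        """Species persisting across trials (fixed by the model design)."""
        return CARRY_OVER_SPECIES

    # -- constructors --------------------------------------------------------
    @classmethod
    def pairing_series(cls, n_pairings: int, isi: float,
                       inter_trial_interval: float = 10.0,
                       cs_onset: float = 0.1) -> "StimulusProtocol":
        """n identical CS-US pairings at a fixed ISI (seconds)."""
        if n_pairings < 1:
            raise ValueError("n_pairings must be >= 1")
        if isi <= 0:
            raise ValueError("isi must be positive")
        trial = Trial(cs_onset=cs_onset, us_onset=cs_onset + isi)
        return cls(trials=(trial,) * n_pairings,
                   inter_trial_interval=inter_trial_interval)

    @classmethod
    def from_file(cls, path: str | Path) -> "StimulusProtocol":
        """Load a protocol from a YAML file.

        Either a generator spec (``n_pairings``, ``isi_ms``, optional
        ``iti_s``, ``cs_onset_s``) or an explicit ``trials`` list with
        per-trial ``cs_onset_s`` / ``us_onset_s`` entries.
        """
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"protocol file {path} must contain a mapping")
        iti = float(d.get("iti_s", 10.0))
        if "trials" in d:
            trials = []
            for td in d["trials"]:
                us = td.get("us_onset_s")
                trials.append(Trial(
                    cs_onset=float(td.get("cs_onset_s", 0.1)),
                    us_onset=None if us is None else float(us),
                    trial_duration=(float(td["duration_s"]) if "duration_s" in td else None),
                ))
            return cls(trials=tuple(trials), inter_trial_interval=iti)
        return cls.pairing_series(
            n_pairings=int(d["n_pairings"]),
            isi=float(d["isi_ms"]) / 1000.0,
            inter_trial_interval=iti,
            cs_onset=float(d.get("cs_onset_s", 0.1)),
        )


def _reset_fast_species(state: ModelState, params: ModelParameters) -> ModelState:
    """Re-initialise stimulus-driven quantities before a new trial."""
    rest = resting_state(params)
    new = state.copy()
    new.x = rest.x
    new.y = rest.y
    new.Ca = params.B_Ca
    new.Gi = 0.0
    new.Gs = 0.0
    new.t_since_CS = None
    new.t_since_US = None
    return new


def run_trial(state: ModelState, trial: Trial, params: ModelParameters,
              config: IntegratorConfig) -> tuple[ModelState, SimulationTrace]:
    """Simulate one trial from the given state.

    At the CS onset the pool calcium is set to its release set-point and
    the calcium/Gi windows start; at the US onset the Gs window starts,
    with amplitude gated by the instantaneous RGS level.  The returned
    trace is identical for any ``cs_duration`` / ``cs_strength``: the CS
    acts only through its onset.
    """
    if trial.us_onset is not None and trial.us_onset - trial.cs_onset < config.dt:
        raise ValueError(
            f"degenerate ISI: us_onset - cs_onset = {trial.us_onset - trial.cs_onset}"
            f" is inside one integration step (dt={config.dt})"
        )
    start = _reset_fast_species(state, params)
    schedule: list[tuple[float, str]] = [(trial.cs_onset, "CS")]
    if trial.us_onset is not None:
        schedule.append((trial.us_onset, "US"))
    duration = round(trial.duration / config.dt) * config.dt
    return integrate(start, schedule, params, config, duration)


def run_training(protocol: StimulusProtocol, params: ModelParameters,
                 config: IntegratorConfig, keep_traces: bool = False):
    """Run a training series with slow-species carry-over.

    Returns a :class:`dendroclock.analysis.TrainingResult` with one
    summary record per trial (and the full traces when requested).
    """
    from .analysis import TrainingResult, summarize_trial

    state = resting_state(params)
    records = []
    traces: list[SimulationTrace] = []
    relax_cfg = config.for_relaxation()
    for i, trial in enumerate(protocol.trials):
        state, trace = run_trial(state, trial, params, config)
        records.append(summarize_trial(trace, trial, params, index=i + 1, end_state=state))
        if keep_traces:
            traces.append(trace)
        if protocol.inter_trial_interval > 0 and i + 1 < len(protocol.trials):
            iti = round(protocol.inter_trial_interval / relax_cfg.dt) * relax_cfg.dt
            state = _reset_fast_species(state, params)
            state, _ = integrate(state, [], params, relax_cfg, iti)
    return TrainingResult(
        records=records,
        protocol=protocol,
        params_hash=params.hash(),
        traces=traces if keep_traces else None,
    )
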