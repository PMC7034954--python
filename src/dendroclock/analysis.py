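"""Learning read-outs: anticipation latency, pairings-to-learn, calcium
amplification.

The model's timed output is the activation of the RGS negative feedback.
Its latency is operationalised through the model's own hard switch — the
first post-CS time at which the calcium-gated variable ``z`` exceeds the
switch threshold — because that is the quantity the feedback actually
uses.  A trace-based alternative (RGS crossing a fixed fraction of its
trial maximum) is provided for figure-style comparison.

A trial has *anticipated* the US when its RGS activation latency precedes
the inter-stimulus interval.  ``pairings_to_learn`` counts the pairings
until the first anticipating trial; repeated across ISIs it yields the
learning-curve table (number of pairings versus interval).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .integrator import IntegratorConfig
from .params import ModelParameters
from .protocol import StimulusProtocol, Trial, run_trial, run_training
from .state import ModelState, resting_state
from .trace import SimulationTrace

__all__ = [
    "TrialRecord",
    "TrainingResult",
    "rgs_activation_time",
    "calcium_amplification",
    "pairings_to_learn",
    "isi_sweep",
]


@dataclass(frozen=True)
class TrialRecord:
    """Per-pairing summary."""

    index: int                       # 1-based trial number
    isi: Optional[float]             # s, None for CS-alone probes
    rgs_activation_time: Optional[float]  # s after CS onset, None if no switch
    anticipated: bool                # activation precedes the US onset
    peak_Ca: float                   # µM, within the post-CS window
    Ca_integral: float               # µM·s over the post-CS window
    end_AC: float
    end_cAMP: float
    end_PKA: float
    end_PDE: float
    end_RGS: float

    def __post_init__(self) -> None:
        if self.anticipated:
            if self.rgs_activation_time is None or self.isi is None:
                raise ValueError("anticipated requires an activation time and an ISI")
            if self.rgs_activation_time >= self.isi:
                raise ValueError("anticipated requires activation before the US")


@dataclass
class TrainingResult:
    """Summaries of a training series, one record per pairing."""

    records: list[TrialRecord]
    protocol: StimulusProtocol
    params_hash: str = ""
    traces: Optional[list[SimulationTrace]] = None

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    @property
    def first_anticipating_trial(self) -> Optional[int]:
        for r in self.records:
            if r.anticipated:
                return r.index
        return None


def rgs_activation_time(trace: SimulationTrace, params: ModelParameters,
                        criterion: str = "z_switch",
                        fraction: float = 0.5) -> Optional[float]:
    """First post-CS activation time of the RGS feedback, relative to CS.

    ``criterion="z_switch"`` (default): first time the gating variable z
    strictly exceeds the switch threshold — the event the model's own
    feedback responds to.  ``criterion="rgs_fraction"``: first time the
    RGS trace crosses ``fraction`` of its post-CS maximum.  Crossing times
    are linearly interpolated between recorded samples.  Returns None when
    the criterion is never met.
    """
    t_cs = trace.event_time("CS")
    if t_cs is None:
        raise ValueError("trace has no CS event")
    t = trace.time
    post = t >= t_cs - 1e-12
    if criterion == "z_switch":
        series = trace["z"][post]
        level = params.z_threshold
    elif criterion == "rgs_fraction":
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        series = trace["RGS"][post]
        level = fraction * float(series.max())
        if level <= 0:
            return None
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    tt = t[post]
    above = series > level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(tt[0] - t_cs)
    # linear interpolation of the crossing inside the recording stride
    y0, y1 = series[i - 1], series[i]
    frac = (level - y0) / (y1 - y0) if y1 != y0 else 1.0
    t_star = tt[i - 1] + frac * (tt[i] - tt[i - 1])
    return float(t_star - t_cs)


def _window_metrics(trace: SimulationTrace, params: ModelParameters) -> tuple[float, float]:
    """(peak, integral) of synaptic calcium over the post-CS window."""
    t_cs = trace.event_time("CS")
    if t_cs is None:
        return float(trace["Ca"].max()), 0.0
    mask = (trace.time >= t_cs - 1e-12) & (trace.time <= t_cs + params.ca_window + 1e-12)
    ca = trace["Ca"][mask]
    tt = trace.time[mask]
    if ca.size < 2:
        return float(ca.max(initial=0.0)), 0.0
    return float(ca.max()), float(np.trapezoid(ca, tt))


def summarize_trial(trace: SimulationTrace, trial: Trial, params: ModelParameters,
                    index: int, end_state: ModelState) -> TrialRecord:
    t_act = rgs_activation_time(trace, params)
    isi = trial.isi
    peak, integral = _window_metrics(trace, params)
    anticipated = t_act is not None and isi is not None and t_act < isi
    return TrialRecord(
        index=index,
        isi=isi,
        rgs_activation_time=t_act,
        anticipated=anticipated,
        peak_Ca=peak,
        Ca_integral=integral,
        end_AC=end_state.AC,
        end_cAMP=end_state.cAMP,
        end_PKA=end_state.PKA,
        end_PDE=end_state.PDE,
        end_RGS=end_state.RGS,
    )


def calcium_amplification(result: TrainingResult) -> float:
    """Percent increase of released calcium from the first to the second
    pairing, measured as the integral of synaptic calcium over the post-CS
    window (the peak is available on the records as a secondary metric)."""
    if len(result.records) < 2:
        raise ValueError("calcium_amplification needs at least two trials")
    m1 = result.records[0].Ca_integral
    m2 = result.records[1].Ca_integral
    if m1 == 0:
        raise ZeroDivisionError("first-trial calcium integral is zero")
    return 100.0 * (m2 - m1) / m1


def pairings_to_learn(isi: float, params: ModelParameters,
                      config: IntegratorConfig, max_pairings: int = 70,
                      inter_trial_interval: float = 10.0,
                      cs_onset: float = 0.1,
                      return_result: bool = False):
    """Smallest number of pairings after which RGS activation anticipates
    the US at the given ISI (seconds); None if never within the budget.

    Trials are run incrementally from the naive resting state with the
    standard carry-over rule, stopping at the first anticipating trial.
    """
    if isi <= 0:
        raise ValueError("isi must be positive")
    if max_pairings < 1:
        raise ValueError("max_pairings must be >= 1")
    from .integrator import integrate
    from .protocol import _reset_fast_species

    trial = Trial(cs_onset=cs_onset, us_onset=cs_onset + isi)
    state = resting_state(params)
    relax_cfg = config.for_relaxation()
    records: list[TrialRecord] = []
    learned: Optional[int] = None

    for i in range(1, max_pairings + 1):
        state, trace = run_trial(state, trial, params, config)
        rec = summarize_trial(trace, trial, params, index=i, end_state=state)
        records.append(rec)
        if rec.anticipated:
            learned = i
            break
        if inter_trial_interval > 0 and i < max_pairings:
            iti = round(inter_trial_interval / relax_cfg.dt) * relax_cfg.dt
            state = _reset_fast_species(state, params)
            state, _ = integrate(state, [], params, relax_cfg, iti)
    if return_result:
        proto = StimulusProtocol(trials=(trial,) * len(records),
                                 inter_trial_interval=inter_trial_interval)
        return learned, TrainingResult(records=records, protocol=proto,
                                       params_hash=params.hash())
    return learned


def isi_sweep(isis: Sequence[float], params: ModelParameters,
              config: IntegratorConfig, max_pairings: int = 70,
              inter_trial_interval: float = 10.0) -> pd.DataFrame:
    """Learning-curve table over a grid of ISIs (seconds).

    Each ISI is trained independently from the naive resting state.
    Columns: ``isi_s``, ``pairings_to_learn`` (NaN when not learned within
    ``max_pairings``) and ``final_rgs_activation_time_s`` (latency on the
    last trial run, i.e. the first anticipating trial when learning
    succeeded).
    """
    if len(isis) == 0:
        raise ValueError("isi list must be non-empty")
    rows = []
    for isi in isis:
        learned, result = pairings_to_learn(
            isi, params, config, max_pairings=max_pairings,
            inter_trial_interval=inter_trial_interval, return_result=True)
        final_t = result.records[-1].rgs_activation_time
        rows.append({
            "isi_s": float(isi),
            "pairings_to_learn": (np.nan if learned is None else learned),
            "final_rgs_activation_time_s": (np.nan if final_t is None else final_t),
        })
    return pd.DataFrame(rows)
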