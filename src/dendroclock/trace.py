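"""Recorded simulation traces.

A :class:`SimulationTrace` holds the time series of all eight dynamical
species at the recording stride, the recomputed algebraic inputs (synaptic
calcium, Gi, Gs) and the stimulus-event annotations.  Traces are written
as tidy CSV with a JSON metadata sidecar (parameter hash, integrator
config, package version) so any run can be re-read and reproduced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .state import ALGEBRAIC, SPECIES

__all__ = ["SimulationTrace"]


@dataclass
class SimulationTrace:
    """Time series of every species plus event annotations.

    ``data`` has one row per recorded sample and one column per entry of
    :data:`dendroclock.state.SPECIES`; ``algebraic`` likewise for
    (Ca, Gi, Gs).  ``events`` is an ordered list of ``(time, label)`` with
    labels ``"CS"`` / ``"US"``.
    """

    time: np.ndarray
    data: np.ndarray
    algebraic: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        self.algebraic = np.asarray(self.algebraic, dtype=float)
        if self.data.shape != (self.time.size, len(SPECIES)):
            raise ValueError("trace data shape does not match time axis / species")
        if self.algebraic.shape != (self.time.size, len(ALGEBRAIC)):
            raise ValueError("algebraic shape does not match time axis")

    def __len__(self) -> int:
        return self.time.size

    def __getitem__(self, name: str) -> np.ndarray:
        """Series for a species or algebraic quantity by name."""
        if name == "time":
            return self.time
        if name in SPECIES:
            return self.data[:, SPECIES.index(name)]
        if name in ALGEBRAIC:
            return self.algebraic[:, ALGEBRAIC.index(name)]
        raise KeyError(name)

    @property
    def dt_record(self) -> float:
        if self.time.size < 2:
            return 0.0
        return float(self.time[1] - self.time[0])

    def event_time(self, label: str, which: int = 0) -> Optional[float]:
        """Time of the ``which``-th event with the given label, or None."""
        times = [t for t, lab in self.events if lab == label]
        if which < len(times):
            return times[which]
        return None

    def event_index(self, label: str, which: int = 0) -> Optional[int]:
        """Index of the recorded sample closest to the event time."""
        t = self.event_time(label, which)
        if t is None:
            return None
        return int(np.argmin(np.abs(self.time - t)))

    # -- conversions ---------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time})
        for i, s in enumerate(SPECIES):
            df[s] = self.data[:, i]
        for i, s in enumerate(ALGEBRAIC):
            df[s] = self.algebraic[:, i]
        ev = np.full(self.time.size, "", dtype=object)
        for t, lab in self.events:
            idx = int(np.argmin(np.abs(self.time - t)))
            ev[idx] = (ev[idx] + "+" + lab).lstrip("+")
        df["event"] = ev
        return df

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the tidy CSV trace and (optionally) a JSON metadata sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = dict(self.metadata)
            meta["events"] = [[float(t), lab] for t, lab in self.events]
            path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimulationTrace":
        path = Path(path)
        df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
        time = df["time_s"].to_numpy()
        data = df[list(SPECIES)].to_numpy()
        algebraic = df[list(ALGEBRAIC)].to_numpy()
        events: list[tuple[float, str]] = []
        meta: dict = {}
        side = path.with_suffix(".meta.json")
        if side.exists():
            meta = json.loads(side.read_text())
            events = [(float(t), lab) for t, lab in meta.pop("events", [])]
        else:
            for t, labs in zip(time, df["event"].astype(str)):
                for lab in labs.split("+"):
                    if lab:
                        events.append((float(t), lab))
        return cls(time=time, data=data, algebraic=algebraic, events=events, metadata=meta)

    def concat(self, other: "SimulationTrace") -> "SimulationTrace":
        """Append a later trace segment (times must continue monotonically)."""
        if len(other) and len(self) and other.time[0] <= self.time[-1]:
            raise ValueError("trace segments overlap in time")
        return SimulationTrace(
            time=np.concatenate([self.time, other.time]),
            data=np.vstack([self.data, other.data]),
            algebraic=np.vstack([self.algebraic, other.algebraic]),
            events=self.events + other.events,
            metadata=self.metadata or other.metadata,
        )
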