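"""Core containers passed between pipeline stages.

All signal containers hold a plain ``numpy`` array plus the metadata the
downstream stage needs (sampling rate, labels, provenance keys). Events
and responses are kept in ``pandas`` DataFrames with fixed column
conventions so they round-trip through delimited text files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import Band

#: column order for event tables
EVENT_COLUMNS = ("onset_ms", "kind", "stream")
#: recognised event kinds
EVENT_KINDS = ("target_numeral", "nontarget_numeral", "syntactic_violation", "button_press")


@dataclass
class RegionRecording:
    """One continuous region-by-time signal block.

    ``signals`` has shape (n_regions, n_samples), units microvolt.
    """

    signals: np.ndarray
    sampling_rate: float
    region_labels: Sequence[str]
    participant: int | str | None = None
    condition: str | None = None
    block: int | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (regions x samples)")
        if len(self.region_labels) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} labels for {self.signals.shape[0]} regions"
            )

    @property
    def n_regions(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sampling_rate


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame({"onset_ms": pd.Series(dtype=float),
                         "kind": pd.Series(dtype=object),
                         "stream": pd.Series(dtype=object)})


@dataclass
class EventList:
    """Annotated events for one recording block.

    ``events`` columns: onset_ms (float, non-decreasing), kind (one of
    :data:`EVENT_KINDS`), stream ('target' or 'distractor').
    """

    events: pd.DataFrame
    block_duration_ms: float | None = None

    def __post_init__(self) -> None:
        ev = self.events
        missing = set(EVENT_COLUMNS) - set(ev.columns)
        if missing:
            raise ValueError(f"event table missing columns {sorted(missing)}")
        bad = set(ev["kind"]) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds {sorted(bad)}")
        ev = ev.sort_values("onset_ms", kind="stable").reset_index(drop=True)
        if len(ev) and ev["onset_ms"].iloc[0] < 0:
            raise ValueError("event onsets must be non-negative")
        if self.block_duration_ms is not None and len(ev):
            if ev["onset_ms"].iloc[-1] > self.block_duration_ms:
                raise ValueError("event onset beyond block duration")
        self.events = ev

    def onsets(self, kind: str | None = None, stream: str | None = None) -> np.ndarray:
        ev = self.events
        if kind is not None:
            ev = ev[ev["kind"] == kind]
        if stream is not None:
            ev = ev[ev["stream"] == stream]
        return ev["onset_ms"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.events)

    def merged_with(self, other: "EventList") -> "EventList":
        ev = pd.concat([self.events, other.events], ignore_index=True)
        return EventList(ev, block_duration_ms=self.block_duration_ms)


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one recording.

    ``epochs`` has shape (n_epochs, n_regions, epoch_length). For
    event-free epochs ``intervals`` stores the half-open [start, stop)
    sample interval of each retained epoch in the source recording; for
    event-locked epochs ``event_onsets_ms`` stores the locking onsets.
    """

    epochs: np.ndarray
    sampling_rate: float
    region_labels: Sequence[str]
    kind: str = "event_free"  # or "event_locked"
    participant: int | str | None = None
    condition: str | None = None
    intervals: np.ndarray | None = None
    event_onsets_ms: np.ndarray | None = None
    baseline_window_ms: tuple[float, float] | None = None
    window_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch x region x sample)")
        if self.kind not in ("event_free", "event_locked"):
            raise ValueError(f"unknown epoch kind {self.kind!r}")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_length(self) -> int:
        return self.epochs.shape[2]

    def take(self, index: np.ndarray) -> "EpochSet":
        """Subset epochs (boolean mask or integer index), keeping metadata aligned."""
        return EpochSet(
            epochs=self.epochs[index],
            sampling_rate=self.sampling_rate,
            region_labels=self.region_labels,
            kind=self.kind,
            participant=self.participant,
            condition=self.condition,
            intervals=None if self.intervals is None else self.intervals[index],
            event_onsets_ms=(None if self.event_onsets_ms is None
                             else self.event_onsets_ms[index]),
            baseline_window_ms=self.baseline_window_ms,
            window_ms=self.window_ms,
        )


@dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region phase-lag-index matrix.

    Values lie in [0, 1]; the diagonal is stored as 0 by convention.
    """

    values: np.ndarray
    band: Band
    region_labels: Sequence[str]
    participant: int | str | None = None
    condition: str | None = None
    n_epochs_averaged: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=0.0):
            raise ValueError("connectivity matrix must be exactly symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("PLI values must lie in [0, 1]")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be 0")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle values in row-major (i < j) order."""
        iu = np.triu_indices(self.n_regions, 1)
        return self.values[iu]


@dataclass
class ResponseLog:
    """Button presses plus the event onsets they are scored against (ms)."""

    presses: np.ndarray
    targets: np.ndarray
    nontargets: np.ndarray
    participant: int | str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        for name in ("presses", "targets", "nontargets"):
            arr = np.sort(np.asarray(getattr(self, name), dtype=float))
            if len(arr) and arr[0] < 0:
                raise ValueError(f"{name} must be non-negative times")
            setattr(self, name, arr)


@dataclass
class BehavioralSummary:
    """Detection scores for one participant x condition cell."""

    participant: int | str
    condition: str
    window_ms: tuple[float, float]
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    d_prime: float
    hit_rts_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    recognition_index: float | None = None

    def __post_init__(self) -> None:
        if self.hits + self.misses < 0 or self.false_alarms + self.correct_rejections < 0:
            raise ValueError("negative trial counts")

    @property
    def n_targets(self) -> int:
        return self.hits + self.misses

    @property
    def n_nontargets(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def log_rt(self) -> np.ndarray:
        """Natural log of hit latencies in ms."""
        return np.log(self.hit_rts_ms)
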