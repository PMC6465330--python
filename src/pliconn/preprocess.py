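"""Filtering, epoching and artifact rejection.

Filtering uses linear-phase Kaiser-window FIR filters applied by centred
convolution, which is inherently zero-phase — essential here because the
downstream connectivity measure is a pure phase statistic and any phase
distortion would bias it.

Epoching conventions: epochs are consecutive, non-overlapping, half-open
sample intervals [start, stop), 0-based. An epoch "contains" an event if
the event onset sample falls inside the interval (optionally widened by
a margin); such epochs are dropped so that stimulus- and response-locked
activity cannot leak into the connectivity estimates.
"""

from __future__ import annotations

import logging
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datatypes import EpochSet, EventList, RegionRecording

logger = logging.getLogger(__name__)

#: Kaiser window shape used for all FIR designs (~60 dB stopband)
KAISER_BETA = 5.65


@lru_cache(maxsize=64)
def design_bandpass(
    low: float, high: float, fs: float, numtaps: int | None = None
) -> np.ndarray:
    """Linear-phase Kaiser bandpass. Tap count scales with the low edge
    (the hardest transition) unless given explicitly."""
    if numtaps is None:
        numtaps = int(6.5 * fs / low)
    numtaps |= 1  # odd => exactly symmetric, integer group delay
    return sps.firwin(
        numtaps, [low, high], pass_zero=False, window=("kaiser", KAISER_BETA), fs=fs
    )


@lru_cache(maxsize=16)
def design_bandstop(
    low: float, high: float, fs: float, numtaps: int | None = None
) -> np.ndarray:
    if numtaps is None:
        numtaps = int(6.5 * fs / 1.0)  # ~1 Hz transition
    numtaps |= 1
    return sps.firwin(
        numtaps, [low, high], pass_zero=True, window=("kaiser", KAISER_BETA), fs=fs
    )


def _zero_phase(signals: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Centred FIR convolution: zero phase, output length = input length."""
    n = signals.shape[-1]
    if len(taps) > n:
        raise ValueError(
            f"filter of {len(taps)} taps longer than signal of {n} samples"
        )
    return sps.oaconvolve(signals, taps[None, :], mode="same", axes=-1)


def bandpass_filter(
    recording: RegionRecording,
    low: float = 0.5,
    high: float = 80.0,
    notch: tuple[float, float] | None = (47.0, 53.0),
    numtaps: int | None = None,
) -> RegionRecording:
    """Zero-phase bandpass (default 0.5–80 Hz) with optional bandstop
    (default 47–53 Hz, for line noise)."""
    nyq = recording.sampling_rate / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) must satisfy 0 < low < high < {nyq}")
    taps = design_bandpass(low, high, recording.sampling_rate, numtaps)
    out = _zero_phase(recording.signals, taps)
    if notch is not None:
        nlo, nhi = notch
        if not 0.0 < nlo < nhi < nyq:
            raise ValueError(f"notch ({nlo}, {nhi}) outside (0, {nyq})")
        out = _zero_phase(out, design_bandstop(nlo, nhi, recording.sampling_rate))
    return RegionRecording(
        out, recording.sampling_rate, recording.region_labels,
        participant=recording.participant, condition=recording.condition,
        block=recording.block,
    )


def event_free_intervals(
    n_samples: int,
    onsets_ms: np.ndarray,
    sampling_rate: float,
    epoch_length: int,
    margin_ms: float = 0.0,
) -> np.ndarray:
    """Half-open [start, stop) intervals of consecutive epochs containing
    no event onset within +- margin."""
    n_windows = n_samples // epoch_length
    starts = np.arange(n_windows) * epoch_length
    if len(onsets_ms) == 0:
        return np.column_stack([starts, starts + epoch_length])
    onset_samples = np.asarray(onsets_ms) * sampling_rate / 1000.0
    margin = margin_ms * sampling_rate / 1000.0
    keep = []
    for s in starts:
        lo, hi = s - margin, s + epoch_length + margin
        if not np.any((onset_samples >= lo) & (onset_samples < hi)):
            keep.append((s, s + epoch_length))
    return np.array(keep, dtype=int).reshape(-1, 2)


def extract_event_free_epochs(
    recording: RegionRecording,
    events: EventList,
    epoch_length: int = 2048,
    margin_ms: float = 0.0,
) -> EpochSet:
    """Cut consecutive epochs and drop any containing an event onset."""
    if epoch_length > recording.n_samples:
        raise ValueError(
            f"epoch_length {epoch_length} exceeds recording of {recording.n_samples}"
        )
    if recording.n_samples == 0:
        warnings.warn("empty recording: no epochs extracted")
    intervals = event_free_intervals(
        recording.n_samples, events.onsets(), recording.sampling_rate,
        epoch_length, margin_ms,
    )
    if len(intervals):
        epochs = np.stack([recording.signals[:, s:e] for s, e in intervals])
    else:
        epochs = np.empty((0, recording.n_regions, epoch_length))
    return EpochSet(
        epochs=epochs, sampling_rate=recording.sampling_rate,
        region_labels=recording.region_labels, kind="event_free",
        participant=recording.participant, condition=recording.condition,
        intervals=intervals,
    )


def reject_artifact_epochs(epochs: EpochSet, threshold: float = 100.0) -> EpochSet:
    """Drop epochs whose peak-to-peak range exceeds ``threshold`` (uV) on
    any region."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if epochs.n_epochs == 0:
        return epochs
    ptp = epochs.epochs.max(axis=2) - epochs.epochs.min(axis=2)  # (epoch, region)
    keep = np.all(ptp <= threshold, axis=1)
    return epochs.take(keep)


def concat_epoch_sets(sets: list[EpochSet]) -> EpochSet:
    """Concatenate epoch sets from multiple blocks of one cell."""
    sets = [s for s in sets if s.n_epochs > 0]
    if not sets:
        raise ValueError("no epochs to concatenate")
    first = sets[0]
    return EpochSet(
        epochs=np.concatenate([s.epochs for s in sets]),
        sampling_rate=first.sampling_rate, region_labels=first.region_labels,
        kind=first.kind, participant=first.participant, condition=first.condition,
    )


def enforce_min_epochs(
    epoch_counts: "pd.DataFrame | dict[tuple, int]", minimum: int = 90
) -> pd.DataFrame:
    """Participant inclusion report from clean-epoch counts.

    ``epoch_counts`` maps (participant, condition) -> count, or is a
    DataFrame with columns participant, condition, n_epochs. A
    participant falling below ``minimum`` in any condition is excluded.
    """
    if isinstance(epoch_counts, dict):
        df = pd.DataFrame(
            [(p, c, n) for (p, c), n in epoch_counts.items()],
            columns=["participant", "condition", "n_epochs"],
        )
    else:
        df = epoch_counts.copy()
    df["meets_criterion"] = df["n_epochs"] >= minimum
    excluded = set(df.loc[~df["meets_criterion"], "participant"])
    df["participant_excluded"] = df["participant"].isin(excluded)
    return df.sort_values(["participant", "condition"]).reset_index(drop=True)


def extract_erp_epochs(
    recording: RegionRecording,
    events: EventList,
    kind: str | None = None,
    stream: str | None = None,
    window_ms: tuple[float, float] = (-200.0, 2200.0),
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    threshold: float | None = 100.0,
) -> EpochSet:
    """Event-locked, baseline-corrected, amplitude-rejected epochs.

    The baseline mean (over ``baseline_ms``) is subtracted per region;
    epochs whose corrected amplitude leaves +-``threshold`` uV on any
    region are dropped. Events too close to the recording edge are
    skipped with a log entry.
    """
    w_lo, w_hi = window_ms
    b_lo, b_hi = baseline_ms
    if not (w_lo <= b_lo < b_hi <= w_hi):
        raise ValueError("baseline window must lie inside the epoch window")
    fs = recording.sampling_rate
    start_off = int(round(w_lo * fs / 1000.0))
    stop_off = int(round(w_hi * fs / 1000.0))
    b_start = int(round(b_lo * fs / 1000.0)) - start_off
    b_stop = int(round(b_hi * fs / 1000.0)) - start_off

    onsets = events.onsets(kind=kind, stream=stream)
    chunks, kept_onsets = [], []
    for onset in onsets:
        s0 = int(round(onset * fs / 1000.0))
        lo, hi = s0 + start_off, s0 + stop_off
        if lo < 0 or hi > recording.n_samples:
            logger.info("ERP epoch at %.0f ms skipped: outside recording", onset)
            continue
        ep = recording.signals[:, lo:hi].copy()
        ep -= ep[:, b_start:b_stop].mean(axis=1, keepdims=True)
        chunks.append(ep)
        kept_onsets.append(onset)
    if chunks:
        epochs = np.stack(chunks)
        if threshold is not None:
            keep = np.all(np.abs(epochs).max(axis=2) <= threshold, axis=1)
            epochs = epochs[keep]
            kept_onsets = list(np.asarray(kept_onsets)[keep])
    else:
        epochs = np.empty((0, recording.n_regions, stop_off - start_off))
    return EpochSet(
        epochs=epochs, sampling_rate=fs, region_labels=recording.region_labels,
        kind="event_locked", participant=recording.participant,
        condition=recording.condition,
        event_onsets_ms=np.asarray(kept_onsets, dtype=float),
        baseline_window_ms=baseline_ms, window_ms=window_ms,
    )
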