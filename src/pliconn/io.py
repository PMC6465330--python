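"""Plain-text readers and writers for every pipeline artifact.

Signals are tab-delimited region-by-sample matrices with a JSON sidecar
header (sampling rate, labels, provenance); events, responses, edge
tables and reports are TSV; run summaries are JSON. Everything
round-trips losslessly enough for the statistics downstream (floats at
repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import get_band
from .datatypes import ConnectivityMatrix, EventList, RegionRecording, ResponseLog


def write_recording(recording: RegionRecording, path: "str | Path") -> Path:
    path = Path(path)
    np.savetxt(path, recording.signals, delimiter="\t", fmt="%.6f")
    header = {
        "sampling_rate": recording.sampling_rate,
        "region_labels": list(recording.region_labels),
        "participant": recording.participant,
        "condition": recording.condition,
        "block": recording.block,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))
    return path


def read_recording(path: "str | Path") -> RegionRecording:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    signals = np.loadtxt(path, delimiter="\t", ndmin=2)
    return RegionRecording(
        signals=signals,
        sampling_rate=header["sampling_rate"],
        region_labels=header["region_labels"],
        participant=header.get("participant"),
        condition=header.get("condition"),
        block=header.get("block"),
    )


def write_events(events: EventList, path: "str | Path") -> Path:
    path = Path(path)
    events.events.to_csv(path, sep="\t", index=False)
    return path


def read_events(path: "str | Path", block_duration_ms: float | None = None) -> EventList:
    return EventList(pd.read_csv(path, sep="\t"), block_duration_ms=block_duration_ms)


def write_responses(log: ResponseLog, path: "str | Path") -> Path:
    rows = (
        [("press", t) for t in log.presses]
        + [("target", t) for t in log.targets]
        + [("nontarget", t) for t in log.nontargets]
    )
    df = pd.DataFrame(rows, columns=["kind", "time_ms"]).sort_values("time_ms")
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_responses(
    path: "str | Path", participant=None, condition=None
) -> ResponseLog:
    df = pd.read_csv(path, sep="\t")
    pick = lambda kind: df.loc[df["kind"] == kind, "time_ms"].to_numpy(float)
    return ResponseLog(
        presses=pick("press"), targets=pick("target"), nontargets=pick("nontarget"),
        participant=participant, condition=condition,
    )


def write_connectivity_matrix(matrix: ConnectivityMatrix, path: "str | Path") -> Path:
    path = Path(path)
    df = pd.DataFrame(
        matrix.values, index=matrix.region_labels, columns=matrix.region_labels
    )
    df.to_csv(path, sep="\t")
    meta = {
        "band": matrix.band.name, "low": matrix.band.low, "high": matrix.band.high,
        "participant": matrix.participant, "condition": matrix.condition,
        "n_epochs_averaged": matrix.n_epochs_averaged,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_connectivity_matrix(path: "str | Path") -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    vals = df.to_numpy(float)
    vals = (vals + vals.T) / 2  # text round-trip can nick symmetry in the last digit
    np.fill_diagonal(vals, 0.0)
    from .bands import BAND_BY_NAME

    band = (BAND_BY_NAME[meta["band"]] if meta.get("band") in BAND_BY_NAME
            else get_band((meta["low"], meta["high"])))
    return ConnectivityMatrix(
        values=vals, band=band,
        region_labels=list(df.columns),
        participant=meta.get("participant"), condition=meta.get("condition"),
        n_epochs_averaged=meta.get("n_epochs_averaged", 1),
    )


def edge_long_table(matrices: "list[ConnectivityMatrix]") -> pd.DataFrame:
    """Long-format edge table over many matrices: one row per edge."""
    rows = []
    for m in matrices:
        labels = list(m.region_labels)
        iu, ju = np.triu_indices(m.n_regions, 1)
        for i, j in zip(iu, ju):
            rows.append(
                {
                    "region_i": labels[i], "region_j": labels[j],
                    "band": m.band.name, "condition": m.condition,
                    "participant": m.participant, "pli": m.values[i, j],
                }
            )
    return pd.DataFrame(rows)


def write_json(obj, path: "str | Path") -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, default=_jsonify))
    return path


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, set):
        return sorted(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
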