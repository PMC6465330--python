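"""Broadband-filter the simulated recordings, cut event-free epochs,
reject artifacts, and apply the minimum-epoch inclusion criterion.

Reads ``scratch/study`` (run 01 first); writes the per-cell clean-epoch
counts and the participant inclusion report to ``results/``.
"""

from pathlib import Path

import pandas as pd

from pliconn.io import read_events, read_recording
from pliconn.preprocess import (
    bandpass_filter,
    enforce_min_epochs,
    extract_event_free_epochs,
    reject_artifact_epochs,
)

ROOT = Path(__file__).resolve().parents[1]
EPOCH_LENGTH = 400
MIN_EPOCHS = 10


def main() -> None:
    study = ROOT / "scratch" / "study"
    if not study.exists():
        raise SystemExit("run analysis/01_simulate_study.py first")

    counts: dict[tuple, int] = {}
    for sig_path in sorted((study / "signals").glob("*.tsv")):
        rec = read_recording(sig_path)
        events = read_events(study / "events" / sig_path.name)
        filtered = bandpass_filter(
            rec, 0.5, 80.0, notch=None,
            numtaps=min(int(6.5 * rec.sampling_rate / 0.5), rec.n_samples - 1) | 1,
        )
        ep = extract_event_free_epochs(filtered, events, EPOCH_LENGTH)
        clean = reject_artifact_epochs(ep, 100.0)
        key = (rec.participant, rec.condition)
        counts[key] = counts.get(key, 0) + clean.n_epochs

    report = enforce_min_epochs(counts, minimum=MIN_EPOCHS)
    out = ROOT / "results" / "02_inclusion_report.tsv"
    report.to_csv(out, sep="\t", index=False)
    n_excl = report.loc[report["participant_excluded"], "participant"].nunique()
    print(report.to_string(index=False))
    print(f"\n{n_excl} participant(s) below the {MIN_EPOCHS}-epoch criterion -> {out}")


if __name__ == "__main__":
    main()
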