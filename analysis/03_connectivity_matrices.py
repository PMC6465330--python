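"""Phase-lag-index matrices per participant, condition and band.

Reads ``scratch/study`` (run 01 first), repeats the epoching of 02, and
writes every matrix as a labeled table under ``scratch/fc/`` plus one
long-format edge table to ``results/`` for downstream statistics.
"""

from pathlib import Path

from pliconn.bands import LOW_ALPHA, THETA
from pliconn.connectivity import fc_matrices
from pliconn.io import edge_long_table, read_events, read_recording, write_connectivity_matrix
from pliconn.preprocess import bandpass_filter, extract_event_free_epochs, reject_artifact_epochs

ROOT = Path(__file__).resolve().parents[1]
BANDS = (THETA, LOW_ALPHA)
EPOCH_LENGTH = 400


def main() -> None:
    study = ROOT / "scratch" / "study"
    if not study.exists():
        raise SystemExit("run analysis/01_simulate_study.py first")
    fc_dir = ROOT / "scratch" / "fc"
    fc_dir.mkdir(parents=True, exist_ok=True)

    matrices = []
    for sig_path in sorted((study / "signals").glob("*.tsv")):
        rec = read_recording(sig_path)
        events = read_events(study / "events" / sig_path.name)
        filtered = bandpass_filter(
            rec, 0.5, 80.0, notch=None,
            numtaps=min(int(6.5 * rec.sampling_rate / 0.5), rec.n_samples - 1) | 1,
        )
        ep = reject_artifact_epochs(
            extract_event_free_epochs(filtered, events, EPOCH_LENGTH), 100.0
        )
        for m in fc_matrices(ep, BANDS):
            matrices.append(m)
            write_connectivity_matrix(
                m, fc_dir / f"p{m.participant:02d}_{m.condition}_{m.band.name}.tsv"
            )

    table = edge_long_table(matrices)
    out = ROOT / "results" / "03_fc_edges.tsv"
    table.to_csv(out, sep="\t", index=False)
    by_band = table.groupby(["band", "condition"])["pli"].mean().round(4)
    print("mean PLI by band and condition:")
    print(by_band.to_string())
    print(f"\n{len(matrices)} matrices -> {fc_dir}; long table -> {out}")


if __name__ == "__main__":
    main()
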