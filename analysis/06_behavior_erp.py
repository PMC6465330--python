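"""Behavioral scoring and ERP window amplitudes for the simulated study.

Reads ``scratch/study`` (run 01 first). Pools response latencies over
all participants and conditions, trims to the empirical 5-95% window,
scores hits / misses / false alarms / correct rejections and d' per
cell, and measures N2b / N400 / P3b window amplitudes of event-locked
epochs at the first region. Writes ``results/06_behavior.tsv`` and
``results/06_erp.tsv``.
"""

from pathlib import Path

from pliconn.behavior import score_logs
from pliconn.erp import DEFAULT_COMPONENTS, amplitude_table
from pliconn.io import read_events, read_recording, read_responses
from pliconn.preprocess import extract_erp_epochs

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = ROOT / "scratch" / "study"
    if not study.exists():
        raise SystemExit("run analysis/01_simulate_study.py first")

    logs = []
    for path in sorted((study / "responses").glob("*.tsv")):
        participant, condition, _ = path.stem.split("_")
        logs.append(read_responses(path, participant=participant,
                                   condition=condition))
    behavior = score_logs(logs)
    out_b = ROOT / "results" / "06_behavior.tsv"
    behavior.to_csv(out_b, sep="\t", index=False)
    window = (behavior["window_low_ms"].iloc[0], behavior["window_high_ms"].iloc[0])
    print(f"response window after 5-95% trimming: "
          f"{window[0]:.0f}-{window[1]:.0f} ms")
    print(behavior.groupby("condition")[["hit_rate", "fa_rate", "d_prime"]]
          .mean().round(3).to_string())

    cells = {}
    for sig_path in sorted((study / "signals").glob("*.tsv")):
        rec = read_recording(sig_path)
        events = read_events(study / "events" / sig_path.name)
        ep = extract_erp_epochs(rec, events, kind="target_numeral")
        cells[(rec.participant, rec.condition, "target_numeral")] = ep
    erp = amplitude_table(cells, DEFAULT_COMPONENTS, site=0)
    out_e = ROOT / "results" / "06_erp.tsv"
    erp.to_csv(out_e, sep="\t", index=False)
    print("\nmean window amplitude (uV) by component "
          "(oscillatory background only, no evoked response planted):")
    print(erp.groupby("component")["amplitude_uv"].mean().round(3).to_string())
    print(f"\n-> {out_b}\n-> {out_e}")


if __name__ == "__main__":
    main()
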