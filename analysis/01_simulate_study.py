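"""Simulate a scaled-down selective-listening study with a planted
low-alpha connectivity effect.

Writes region signals, event streams and button-press logs for every
participant x condition x block as delimited text under
``scratch/study/`` (bulky; regenerated on demand) and a design summary
under ``results/``.

The planted effect mirrors an energetic-masking hypothesis: a 4-node
low-alpha subnetwork is phase-coupled in the equal-loudness condition
and decoupled when the distractor is louder, so the downstream
equal-vs-louder contrast has a genuine network to find.
"""

import json
from pathlib import Path

from pliconn.io import write_events, write_recording, write_responses
from pliconn.pipeline import RunConfig
from pliconn.synthetic_data import simulate_study

ROOT = Path(__file__).resolve().parents[1]

CONFIG = RunConfig(
    n_participants=6,
    conditions=("0", "+5", "+10"),
    n_blocks_per_condition=1,
    block_duration=150.0,
    sampling_rate=200.0,
    n_regions=8,
    bands=("theta", "low_alpha"),
    epoch_length=400,
    min_epochs=10,
    n_perm=500,
    f_step=0.5,
    effects=(
        {
            "band": "low_alpha",
            "edges": [[0, 1], [1, 2], [2, 3]],
            "coupling_strength": 0.9,
            "condition_profile": {"+5": 0.3, "+10": 0.0},
        },
    ),
    seed=7,
)


def main() -> None:
    out = ROOT / "scratch" / "study"
    for sub in ("signals", "events", "responses"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    dataset = simulate_study(
        CONFIG.design(), CONFIG.coupling_specs(), noise_sd=CONFIG.noise_sd,
        seed=CONFIG.seed, rate_spec=CONFIG.rate_spec(),
        min_epochs=CONFIG.min_epochs, epoch_length=CONFIG.epoch_length,
        bands=CONFIG.band_objects(),
    )
    n_events = 0
    for key, rec in dataset.recordings.items():
        p, c, b = key
        stem = f"p{p:02d}_{c}_{b}"
        write_recording(rec, out / "signals" / f"{stem}.tsv")
        ev = dataset.events_with_presses(key)
        write_events(ev, out / "events" / f"{stem}.tsv")
        write_responses(dataset.responses[key], out / "responses" / f"{stem}.tsv")
        n_events += len(ev)

    summary = {
        "config_hash": CONFIG.config_hash(),
        "n_blocks": len(dataset.recordings),
        "n_events_total": n_events,
        "block_samples": CONFIG.design().block_samples,
        "planted_effect": CONFIG.effects,
    }
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "01_study_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"simulated {summary['n_blocks']} blocks, {n_events} events -> {out}")
    print(f"summary -> results/01_study_summary.json (config {summary['config_hash']})")


if __name__ == "__main__":
    main()
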