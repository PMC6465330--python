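"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
network statistics -> behavior / ERP, from one configuration.

A single master seed is fanned out per stage (and per cell) through
``numpy.random.SeedSequence`` derivations, so each stage reproduces
bit-identically on its own. Every run writes into a directory named
after the config hash, so outputs carry their provenance.

The default configuration is a deliberately scaled-down study (fewer
participants, regions, shorter blocks, lower sampling rate) so that a
full pipeline run stays interactive; the full-scale study shape is a
config file away.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bands import BAND_BY_NAME, Band, get_band
from .behavior import score_logs
from .connectivity import fc_matrices
from .datatypes import ResponseLog
from .edgeops import to_vector
from .erp import DEFAULT_COMPONENTS, amplitude_table
from .io import edge_long_table, write_json
from .network_stats import (
    NetworkResult,
    average_conditions,
    monotonic_trend,
    select_top_edges,
    threshold_search,
)
from .preprocess import (
    bandpass_filter,
    concat_epoch_sets,
    enforce_min_epochs,
    extract_erp_epochs,
    extract_event_free_epochs,
    reject_artifact_epochs,
)
from .synthetic_data import (
    BehaviorSpec,
    CouplingSpec,
    NumeralRateSpec,
    StudyDesign,
    StudyDataset,
    simulate_study,
)

logger = logging.getLogger(__name__)

#: canonical per-stream numeral density (events per second of block)
NUMERAL_DENSITY = 50.7 / 352.0
VIOLATION_DENSITY = 20.0 / 352.0


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run."""

    # design
    n_participants: int = 8
    conditions: tuple[str, ...] = ("-10", "-5", "0", "+5", "+10")
    n_blocks_per_condition: int = 1
    block_duration: float = 120.0
    sampling_rate: float = 256.0
    n_regions: int = 12
    # preprocessing
    bandpass: tuple[float, float] = (0.5, 80.0)
    notch: tuple[float, float] | None = None
    epoch_length: int = 512
    artifact_threshold: float = 100.0
    min_epochs: int = 20
    margin_ms: float = 0.0
    # connectivity
    bands: tuple[str, ...] = ("theta", "low_alpha")
    edge_trim: float = 0.1
    # network statistics
    f_range: tuple[float, float] = (3.0, 10.0)
    f_step: float = 0.5
    n_perm: int = 500
    alpha: float = 0.05
    k_top_edges: int = 32
    run_trend: bool = False
    # generator
    noise_sd: float = 1.0
    effects: tuple[dict, ...] = ()
    # misc
    seed: int = 0
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        nyq = self.sampling_rate / 2
        lo, hi = self.bandpass
        if not 0 < lo < hi < nyq:
            raise ValueError(f"bandpass {self.bandpass} invalid for fs={self.sampling_rate}")
        for name in self.bands:
            band = get_band(name)
            if band.high >= nyq:
                raise ValueError(f"band {name} exceeds Nyquist {nyq}")
        if self.epoch_length <= 0 or self.min_epochs < 0:
            raise ValueError("epoch parameters must be positive")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    # -- construction -------------------------------------------------
    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("conditions", "bands", "effects"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        for key in ("bandpass", "notch", "f_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def design(self) -> StudyDesign:
        return StudyDesign(
            n_participants=self.n_participants,
            conditions=tuple(self.conditions),
            n_blocks_per_condition=self.n_blocks_per_condition,
            block_duration=self.block_duration,
            sampling_rate=self.sampling_rate,
            n_regions=self.n_regions,
        )

    def band_objects(self) -> tuple[Band, ...]:
        return tuple(BAND_BY_NAME[b] for b in self.bands)

    def coupling_specs(self) -> tuple[CouplingSpec, ...]:
        specs = []
        for eff in self.effects:
            specs.append(
                CouplingSpec(
                    band=eff["band"],
                    edges=tuple(tuple(e) for e in eff["edges"]),
                    phase_lag=eff.get("phase_lag", np.pi / 4),
                    coupling_strength=eff.get("coupling_strength", 0.8),
                    condition_profile=eff.get("condition_profile", {}),
                )
            )
        return tuple(specs)

    def rate_spec(self) -> NumeralRateSpec:
        """Numeral counts scaled to block duration at canonical density."""
        scale = self.block_duration / 352.0
        return NumeralRateSpec(
            mean=50.7 * scale,
            sd=2.7 * np.sqrt(scale),
            bounds=(max(0, int(45 * scale)), max(1, int(np.ceil(57 * scale)))),
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:10]


def merged_cell_log(dataset: StudyDataset, participant, condition) -> ResponseLog:
    """Collapse a participant x condition cell's blocks into one response
    log, offsetting each block by its position so times stay ordered."""
    block_ms = dataset.design.block_duration * 1000.0
    presses, targets, nontargets = [], [], []
    for blk in range(dataset.design.n_blocks_per_condition):
        log = dataset.responses[(participant, condition, blk)]
        off = blk * block_ms
        presses.append(log.presses + off)
        targets.append(log.targets + off)
        nontargets.append(log.nontargets + off)
    return ResponseLog(
        presses=np.concatenate(presses), targets=np.concatenate(targets),
        nontargets=np.concatenate(nontargets),
        participant=participant, condition=condition,
    )


def contrast_groups(conditions: tuple[str, ...]) -> dict[str, dict[str, list[str]]]:
    """Energetic (louder vs equal) and informational (softer vs equal)
    contrast groupings available in the given conditions."""
    out = {}
    if {"0", "+5", "+10"} <= set(conditions):
        out["energetic"] = {"A": ["0"], "B": ["+5", "+10"]}
    if {"0", "-5", "-10"} <= set(conditions):
        out["informational"] = {"A": ["0"], "B": ["-5", "-10"]}
    return out


def network_summary(res: NetworkResult, labels: list[str]) -> dict:
    return {
        "threshold": res.threshold,
        "n_permutations": res.n_permutations,
        "components": [
            {
                "size": c.size,
                "p_fwe": p,
                "significant": s,
                "edges": [[labels[i], labels[j]] for i, j in c.edges],
            }
            for c, p, s in zip(res.components, res.p_fwe, res.significant)
        ],
        "top_edges": [
            {
                "edge": [labels[e.edge[0]], labels[e.edge[1]]],
                "mean_diff": e.mean_diff, "t": e.t, "p": e.p,
                "direction": e.direction,
            }
            for e in res.top_edges
        ],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artifacts; returns the run report."""
    out_dir = Path(config.output_dir) / f"run_{config.config_hash()}"
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    design = config.design()
    bands = config.band_objects()

    logger.info("simulating study into %s", out_dir)
    dataset = simulate_study(
        design, config.coupling_specs(),
        noise_sd=config.noise_sd, seed=root,
        rate_spec=config.rate_spec(),
        min_epochs=config.min_epochs, epoch_length=config.epoch_length,
        bands=bands,
    )

    # ---- preprocessing & connectivity -------------------------------
    counts: dict[tuple, int] = {}
    cell_epochs: dict[tuple, object] = {}
    for p in range(design.n_participants):
        for c in design.conditions:
            sets = []
            for blk in range(design.n_blocks_per_condition):
                key = (p, c, blk)
                rec = bandpass_filter(
                    dataset.recordings[key], *config.bandpass, notch=config.notch,
                    numtaps=min(
                        int(6.5 * design.sampling_rate / config.bandpass[0]),
                        dataset.recordings[key].n_samples - 1,
                    ) | 1,
                )
                ep = extract_event_free_epochs(
                    rec, dataset.events_with_presses(key),
                    epoch_length=config.epoch_length, margin_ms=config.margin_ms,
                )
                sets.append(reject_artifact_epochs(ep, config.artifact_threshold))
            merged = concat_epoch_sets(sets)
            counts[(p, c)] = merged.n_epochs
            cell_epochs[(p, c)] = merged
    report_df = enforce_min_epochs(counts, minimum=config.min_epochs)
    report_df.to_csv(out_dir / "inclusion_report.tsv", sep="\t", index=False)
    included = sorted(
        set(report_df.loc[~report_df["participant_excluded"], "participant"])
    )
    logger.info("%d/%d participants included", len(included), design.n_participants)

    matrices = []
    for p in included:
        for c in design.conditions:
            matrices.extend(
                fc_matrices(cell_epochs[(p, c)], bands, edge_trim=config.edge_trim)
            )
    edge_long_table(matrices).to_csv(out_dir / "fc_edges.tsv", sep="\t", index=False)

    # ---- network statistics -----------------------------------------
    labels = design.labels
    networks: dict[str, dict] = {}
    trends: dict[str, dict] = {}
    by_band_cond: dict[tuple, dict[str, np.ndarray]] = {}
    for band in bands:
        data = {
            c: np.stack(
                [
                    to_vector(m.values)
                    for m in matrices
                    if m.band.name == band.name and m.condition == c
                ]
            )
            for c in design.conditions
        }
        by_band_cond[band.name] = data
        for contrast, groups in contrast_groups(design.conditions).items():
            grouped = average_conditions(
                data, {"A": groups["A"], "B": groups["B"]}
            )
            res = threshold_search(
                grouped["A"], grouped["B"],
                f_range=config.f_range, step=config.f_step,
                n_perm=config.n_perm,
                seed=np.random.default_rng(config.seed + 1),
                alpha=config.alpha,
            )
            if res.any_significant:
                select_top_edges(
                    res, grouped["A"], grouped["B"],
                    k=config.k_top_edges, alpha=config.alpha,
                )
            networks[f"{contrast}_{band.name}"] = network_summary(res, labels)
            if config.run_trend and res.any_significant:
                ordered = (
                    ("+10", "+5", "0") if contrast == "energetic" else ("-10", "-5", "0")
                )
                tr = monotonic_trend(
                    data, ordered, f_range=config.f_range, step=config.f_step,
                    n_perm=config.n_perm,
                    seed=np.random.default_rng(config.seed + 2),
                    alpha=config.alpha,
                )
                trends[f"{contrast}_{band.name}"] = {
                    "threshold": tr.network.threshold,
                    "edges": [
                        {
                            "edge": [labels[e.edge[0]], labels[e.edge[1]]],
                            "means": list(e.means), "monotonic": e.monotonic,
                        }
                        for e in tr.edges
                    ],
                }

    # ---- behavior & ERP ---------------------------------------------
    logs = [
        merged_cell_log(dataset, p, c)
        for p in range(design.n_participants)
        for c in design.conditions
    ]
    behavior_df = score_logs(logs)
    behavior_df.to_csv(out_dir / "behavior.tsv", sep="\t", index=False)

    erp_cells = {}
    for p in range(design.n_participants):
        for c in design.conditions:
            key = (p, c, 0)  # first block is representative for the demo table
            ep = extract_erp_epochs(
                dataset.recordings[key], dataset.events[key],
                kind="target_numeral",
            )
            erp_cells[(p, c, "target_numeral")] = ep
    erp_df = amplitude_table(erp_cells, DEFAULT_COMPONENTS, site=0)
    erp_df.to_csv(out_dir / "erp.tsv", sep="\t", index=False)

    report = {
        "config_hash": config.config_hash(),
        "output_dir": str(out_dir),
        "included_participants": included,
        "n_excluded": design.n_participants - len(included),
        "networks": networks,
        "trends": trends,
        "n_behavior_rows": len(behavior_df),
        "n_erp_rows": len(erp_df),
    }
    write_json(report, out_dir / "report.json")
    return report
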