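"""Study-shaped synthetic data with planted, band-specific connectivity.

Two generators live here, operating at two levels of the measurement
hierarchy:

* :func:`simulate_region_signals` / :func:`simulate_study` produce raw
  region-by-time signals: per band, each region carries a narrow-band
  oscillator; region pairs listed in a :class:`CouplingSpec` share a
  carrier phase up to a fixed lag plus von-Mises phase jitter whose
  concentration maps the ``coupling_strength`` knob monotonically onto
  the downstream phase lag index (PLI). A 1/f background is added so the
  spectrum is EEG-like. Events (numerals in both streams, syntactic
  violations in the distractor stream, button presses) and behavioral
  responses are generated alongside.

* :func:`simulate_pli_dataset` skips the signal level and draws
  per-epoch PLI values directly from the null sampling law of the PLI
  (|mean of N random signs|), adding participant effects and planted
  condition differences on chosen edges. This is the right level for
  calibration studies of the network statistics (false-positive rate,
  power), where thousands of studies must be generated.

The jitter model: for effective coupling strength c in [0, 1], the
phase of a coupled region is the carrier phase plus the accumulated edge
lag plus piecewise-constant jitter resampled once per carrier cycle from
a von Mises distribution with concentration kappa = 4c/(1-c) (zero
jitter at c = 1, uniform at c = 0). Because the jitter is constant
within a cycle and independent across cycles, the sign of the pairwise
phase difference behaves like one independent random sign per cycle at
c = 0, which is what makes the null PLI law analytically checkable.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bands import Band, DEFAULT_BANDS, get_band
from .datatypes import EventList, RegionRecording, ResponseLog, empty_event_table
from .edgeops import edge_index, n_edges
from .regions import region_labels

#: distractor-minus-target loudness steps in dB, softest first
DEFAULT_CONDITIONS: tuple[str, ...] = ("-10", "-5", "0", "+5", "+10")

#: per-band oscillator amplitude in microvolt
OSCILLATOR_AMPLITUDE_UV = 4.0

#: slow phase diffusion of free-running oscillators, rad per sample
PHASE_DRIFT_SD = 0.003


@dataclass(frozen=True)
class StudyDesign:
    """Shape of a selective-listening study.

    Defaults mirror a 27-participant, five-condition design with four
    ~6-minute blocks per condition, 36 cortical regions sampled at
    1 kHz. Scaled-down variants (fewer participants, shorter blocks,
    lower rate) are obtained with :func:`dataclasses.replace`.
    """

    n_participants: int = 27
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_blocks_per_condition: int = 4
    block_duration: float = 352.0  # seconds
    sampling_rate: float = 1000.0  # Hz
    n_regions: int = 36
    region_labels_: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_regions < 2:
            raise ValueError("need at least 1 participant and 2 regions")
        if len(self.conditions) < 1:
            raise ValueError("need at least one condition")
        if self.block_duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("durations and rates must be positive")
        if self.region_labels_ is not None and len(self.region_labels_) != self.n_regions:
            raise ValueError("region label count mismatch")

    @property
    def labels(self) -> list[str]:
        if self.region_labels_ is not None:
            return list(self.region_labels_)
        return region_labels(self.n_regions)

    @property
    def block_samples(self) -> int:
        return int(round(self.block_duration * self.sampling_rate))

    def validate_bands(self, bands: Iterable[Band]) -> None:
        for b in bands:
            if b.high * 2 >= self.sampling_rate:
                raise ValueError(
                    f"sampling rate {self.sampling_rate} Hz too low for band {b}"
                )


@dataclass(frozen=True)
class CouplingSpec:
    """Planted phase coupling for one band.

    ``edges`` are unordered pairs of distinct region indices.
    ``phase_lag`` is either one lag (radians) for every edge or a
    mapping edge -> lag. ``condition_profile`` multiplies
    ``coupling_strength`` per condition (missing conditions default to
    1), which is how condition contrasts are planted.
    """

    band: Band | str | tuple[float, float]
    edges: tuple[tuple[int, int], ...]
    phase_lag: float | Mapping[tuple[int, int], float] = math.pi / 4
    coupling_strength: float = 0.8
    condition_profile: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "band", get_band(self.band))
        norm = []
        seen = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-coupling ({i},{j}) is not allowed")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate edge {key} in coupling spec")
            seen.add(key)
            norm.append(key)
        object.__setattr__(self, "edges", tuple(norm))
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        for v in dict(self.condition_profile).values():
            if v < 0:
                raise ValueError("condition_profile multipliers must be >= 0")

    def lag_of(self, edge: tuple[int, int]) -> float:
        if isinstance(self.phase_lag, Mapping):
            key = (min(edge), max(edge))
            return float(self.phase_lag[key])
        return float(self.phase_lag)

    def strength_in(self, condition: str) -> float:
        mult = dict(self.condition_profile).get(condition, 1.0)
        return float(np.clip(self.coupling_strength * mult, 0.0, 1.0))


@dataclass(frozen=True)
class NumeralRateSpec:
    """Per-block numeral counts: rounded normal draw, resampled into bounds."""

    mean: float = 50.7
    sd: float = 2.7
    bounds: tuple[int, int] = (45, 57)

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("numeral rate mean must be non-negative")
        if self.sd < 0:
            raise ValueError("numeral rate sd must be non-negative")

    def draw(self, rng: np.random.Generator) -> int:
        if self.sd == 0:
            return int(round(self.mean))
        lo, hi = self.bounds
        for _ in range(1000):
            k = int(round(rng.normal(self.mean, self.sd)))
            if lo <= k <= hi:
                return k
        return int(np.clip(round(self.mean), lo, hi))


@dataclass(frozen=True)
class BehaviorSpec:
    """Response model per condition: detection probabilities and RT scale.

    Defaults emulate the qualitative study pattern — detection best at
    equal loudness, degraded for the extreme loudness differences, with
    false alarms rising in the moderately softer and louder conditions.
    """

    p_hit: Mapping[str, float] = field(
        default_factory=lambda: {"-10": 0.72, "-5": 0.88, "0": 0.93, "+5": 0.90, "+10": 0.84}
    )
    p_fa: Mapping[str, float] = field(
        default_factory=lambda: {"-10": 0.10, "-5": 0.05, "0": 0.02, "+5": 0.04, "+10": 0.08}
    )
    rt_mean_ms: float = 800.0
    rt_sd_ms: float = 250.0

    def probs(self, condition: str) -> tuple[float, float]:
        return (dict(self.p_hit).get(condition, 0.9), dict(self.p_fa).get(condition, 0.05))


@dataclass
class StudyDataset:
    """Bundle of everything one simulated study produces."""

    design: StudyDesign
    coupling: tuple[CouplingSpec, ...]
    recordings: dict[tuple, RegionRecording]
    events: dict[tuple, EventList]
    responses: dict[tuple, ResponseLog]

    def keys(self) -> list[tuple]:
        return sorted(self.recordings)

    def events_with_presses(self, key: tuple) -> EventList:
        """Block events including the participant's button presses."""
        ev = self.events[key]
        presses = self.responses[key].presses
        if len(presses) == 0:
            return ev
        add = pd.DataFrame(
            {"onset_ms": presses, "kind": "button_press", "stream": "target"}
        )
        # no duration bound: a late response can outlast the block itself
        return EventList(pd.concat([ev.events, add], ignore_index=True))


# ---------------------------------------------------------------------------
# oscillator machinery


def jitter_kappa(strength: float) -> float:
    """Von Mises concentration for coupling strength c: kappa = c/(1-c).

    Maps [0, 1] onto [0, inf] so downstream PLI runs from the null level
    to 1 without saturating at intermediate strengths (band filtering
    already tightens the realized phase locking above the raw jitter).
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    if strength >= 1.0:
        return math.inf
    return strength / (1.0 - strength)


def expected_pair_sign_mean(strength: float, lag: float) -> float:
    """E[sign(lag + jitter)] under the piecewise-constant jitter model.

    The large-sample PLI of a coupled pair converges to the absolute
    value of this quantity; it is 1 at c = 1 (for lag not a multiple of
    pi) and 0 at c = 0.
    """
    lag = math.remainder(lag, 2 * math.pi)
    if lag < 0:  # jitter is symmetric, so the mean sign is odd in the lag
        return -expected_pair_sign_mean(strength, -lag)
    kappa = jitter_kappa(strength)
    if math.isinf(kappa):
        return float(np.sign(lag))
    vm = stats.vonmises(kappa)
    # wrapped (lag + j) is positive when j falls in (-lag, pi - lag)
    p_pos = vm.cdf(math.pi - lag) - vm.cdf(-lag)
    return 2.0 * p_pos - 1.0


def expected_null_pli(n_signs: int) -> float:
    """Exact E|mean of N independent fair signs| (binomial closed form)."""
    k = np.arange(n_signs + 1)
    pmf = stats.binom.pmf(k, n_signs, 0.5)
    return float(np.sum(pmf * np.abs(2 * k - n_signs) / n_signs))


def _piecewise_constant_jitter(
    rng: np.random.Generator, n_samples: int, knot_len: int, kappa: float
) -> np.ndarray:
    """Jitter held constant over knots of ``knot_len`` samples."""
    n_knots = -(-n_samples // knot_len)
    if math.isinf(kappa):
        return np.zeros(n_samples)
    if kappa == 0.0:
        draws = rng.uniform(-math.pi, math.pi, n_knots)
    else:
        draws = rng.vonmises(0.0, kappa, n_knots)
    return np.repeat(draws, knot_len)[:n_samples]


def pink_noise(rng: np.random.Generator, shape: tuple[int, int], sampling_rate: float) -> np.ndarray:
    """1/f-amplitude Gaussian noise, unit RMS per row."""
    n_rows, n = shape
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((n_rows, len(freqs)))
            + 1j * rng.standard_normal((n_rows, len(freqs)))) * scale
    x = np.fft.irfft(spec, n=n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _coupling_components(
    n_regions: int, specs: Sequence[CouplingSpec]
) -> list[tuple[list[int], dict[int, float]]]:
    """Connected components of the coupling graph with accumulated lags.

    Returns (members, lag-by-member) per component; the first member is
    the carrier root with lag 0, other members' lags accumulate along a
    BFS spanning tree.
    """
    adj: dict[int, list[tuple[int, float]]] = {}
    for spec in specs:
        for (i, j) in spec.edges:
            lag = spec.lag_of((i, j))
            if not (0 <= i < n_regions and 0 <= j < n_regions):
                raise ValueError(f"edge ({i},{j}) outside region range")
            adj.setdefault(i, []).append((j, lag))
            adj.setdefault(j, []).append((i, -lag))
    seen: set[int] = set()
    comps = []
    for root in sorted(adj):
        if root in seen:
            continue
        lags = {root: 0.0}
        order = [root]
        seen.add(root)
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v, lag in adj[u]:
                if v not in seen:
                    seen.add(v)
                    # phase(v) = phase(u) + lag(u->v): v lags u by `lag`
                    lags[v] = lags[u] - lag
                    order.append(v)
                    queue.append(v)
        comps.append((order, lags))
    return comps


def _check_duplicate_edges(coupling: Sequence[CouplingSpec]) -> None:
    per_band: dict[str, set[tuple[int, int]]] = {}
    for spec in coupling:
        band = get_band(spec.band)
        book = per_band.setdefault(band.name, set())
        for e in spec.edges:
            if e in book:
                raise ValueError(
                    f"edge {e} specified twice for band {band.name}; "
                    "merge the coupling specs instead"
                )
            book.add(e)


def _simulate_block(
    design: StudyDesign,
    coupling: Sequence[CouplingSpec],
    condition: str,
    noise_sd: float,
    rng: np.random.Generator,
    bands: Sequence[Band] = DEFAULT_BANDS,
) -> np.ndarray:
    """One block of region signals (n_regions x block_samples), microvolt."""
    n = design.block_samples
    fs = design.sampling_rate
    t = np.arange(n) / fs
    out = np.zeros((design.n_regions, n))
    specs_by_band: dict[str, list[CouplingSpec]] = {}
    for spec in coupling:
        specs_by_band.setdefault(get_band(spec.band).name, []).append(spec)

    for band in bands:
        specs = specs_by_band.get(band.name, [])
        comps = _coupling_components(design.n_regions, specs)
        coupled = {r for members, _ in comps for r in members}
        # free-running regions: independent carriers inside the band
        margin = 0.15 * band.width
        for r in range(design.n_regions):
            if r in coupled:
                continue
            f = rng.uniform(band.low + margin, band.high - margin)
            theta = rng.uniform(0, 2 * math.pi)
            drift = np.cumsum(rng.standard_normal(n)) * PHASE_DRIFT_SD
            out[r] += OSCILLATOR_AMPLITUDE_UV * np.cos(2 * math.pi * f * t + theta + drift)
        # coupled components share one carrier per component
        for members, lags in comps:
            f = rng.uniform(band.low + margin, band.high - margin)
            theta = rng.uniform(0, 2 * math.pi)
            drift = np.cumsum(rng.standard_normal(n)) * PHASE_DRIFT_SD
            carrier = 2 * math.pi * f * t + theta + drift
            knot = max(1, int(round(fs / f)))
            # one strength per spec; a member's jitter uses the strength of
            # the spec contributing its tree edge — with a single spec per
            # band (the common case) this is just that spec's strength
            strength = specs[0].strength_in(condition) if specs else 0.0
            kappa = jitter_kappa(strength)
            root = members[0]
            out[root] += OSCILLATOR_AMPLITUDE_UV * np.cos(carrier)
            for r in members[1:]:
                jit = _piecewise_constant_jitter(rng, n, knot, kappa)
                out[r] += OSCILLATOR_AMPLITUDE_UV * np.cos(carrier + lags[r] + jit)

    if noise_sd > 0:
        osc_rms = np.sqrt(np.mean(out**2)) or 1.0
        out += noise_sd * osc_rms * pink_noise(rng, out.shape, fs)
    return out


def simulate_region_signals(
    design: StudyDesign,
    coupling: Sequence[CouplingSpec] = (),
    noise_sd: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    bands: Sequence[Band] = DEFAULT_BANDS,
) -> list[RegionRecording]:
    """Simulate all participant x condition x block recordings.

    Deterministic for a fixed seed. Note the default full-scale design
    is large (27 x 5 x 4 blocks of 36 x 352000 samples); scale the
    design down for anything interactive.
    """
    design.validate_bands(bands)
    _check_duplicate_edges(coupling)
    for spec in coupling:
        b = get_band(spec.band)
        if b.low < 0.5 or b.high > 70.0:
            raise ValueError(f"coupling band {b} outside 0.5-70 Hz")
    root = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    recs = []
    for p in range(design.n_participants):
        for c in design.conditions:
            for blk in range(design.n_blocks_per_condition):
                rng = np.random.default_rng(_stage_seed(root, "signals", p, c, blk))
                sig = _simulate_block(design, coupling, c, noise_sd, rng, bands)
                recs.append(
                    RegionRecording(
                        signals=sig,
                        sampling_rate=design.sampling_rate,
                        region_labels=design.labels,
                        participant=p,
                        condition=c,
                        block=blk,
                    )
                )
    return recs


def _stage_seed(root: np.random.SeedSequence, stage: str, *key) -> np.random.SeedSequence:
    # stable across processes (unlike hash()), so seeded runs reproduce exactly
    tag = zlib.crc32(repr((stage,) + tuple(key)).encode()) % (2**31)
    return np.random.SeedSequence(entropy=root.entropy, spawn_key=(tag,))


# ---------------------------------------------------------------------------
# events and behavior


def _spaced_onsets(
    rng: np.random.Generator, count: int, t_max_ms: float, min_gap_ms: float
) -> np.ndarray:
    """Sorted uniform onsets with a minimum gap (spacing transform)."""
    if count == 0:
        return np.empty(0)
    gap = min(min_gap_ms, 0.5 * t_max_ms / max(count, 1))
    slack = t_max_ms - count * gap
    u = np.sort(rng.uniform(0, slack, count))
    return u + gap * np.arange(count) + gap / 2


def simulate_block_events(
    design: StudyDesign,
    rate_spec: NumeralRateSpec,
    rng: np.random.Generator,
    violation_rate: tuple[float, float] = (20.0, 2.0),
    min_gap_ms: float = 2000.0,
) -> EventList:
    """Events for one block: numerals in both streams, violations in the distractor."""
    t_ms = design.block_duration * 1000.0
    frames = []
    for stream, kind in (("target", "target_numeral"), ("distractor", "nontarget_numeral")):
        k = rate_spec.draw(rng)
        onsets = _spaced_onsets(rng, k, t_ms, min_gap_ms)
        frames.append(pd.DataFrame({"onset_ms": onsets, "kind": kind, "stream": stream}))
    v_mean, v_sd = violation_rate
    kv = max(0, int(round(rng.normal(v_mean, v_sd)))) if v_mean > 0 else 0
    if kv:
        onsets = _spaced_onsets(rng, kv, t_ms, min_gap_ms)
        frames.append(
            pd.DataFrame({"onset_ms": onsets, "kind": "syntactic_violation",
                          "stream": "distractor"})
        )
    frames = [f for f in frames if len(f)]
    ev = pd.concat(frames, ignore_index=True) if frames else empty_event_table()
    return EventList(ev, block_duration_ms=t_ms)


def simulate_events(
    design: StudyDesign,
    rate_spec: NumeralRateSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    violation_rate: tuple[float, float] = (20.0, 2.0),
) -> dict[tuple, EventList]:
    """Event lists for every participant x condition x block."""
    if design.block_duration < 1.0:
        raise ValueError("block duration must be at least 1 s")
    rate_spec = rate_spec or NumeralRateSpec()
    root = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    out = {}
    for p in range(design.n_participants):
        for c in design.conditions:
            for blk in range(design.n_blocks_per_condition):
                rng = np.random.default_rng(_stage_seed(root, "events", p, c, blk))
                out[(p, c, blk)] = simulate_block_events(
                    design, rate_spec, rng, violation_rate
                )
    return out


def simulate_behavior(
    event_list: EventList,
    p_hit: float = 0.9,
    p_fa: float = 0.05,
    rt_mean: float = 800.0,
    rt_sd: float = 250.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    participant=None,
    condition=None,
) -> ResponseLog:
    """Button presses: each target pressed with p_hit at lognormal latency,
    each non-target numeral with p_fa."""
    for name, p in (("p_hit", p_hit), ("p_fa", p_fa)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if rt_mean <= 0 or rt_sd <= 0:
        raise ValueError("RT parameters must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma2 = math.log(1.0 + (rt_sd / rt_mean) ** 2)
    mu = math.log(rt_mean) - sigma2 / 2.0
    sigma = math.sqrt(sigma2)

    targets = event_list.onsets(kind="target_numeral")
    nontargets = event_list.onsets(kind="nontarget_numeral")
    presses = []
    for onset in targets:
        if rng.uniform() < p_hit:
            presses.append(onset + rng.lognormal(mu, sigma))
    for onset in nontargets:
        if rng.uniform() < p_fa:
            presses.append(onset + rng.lognormal(mu, sigma))
    return ResponseLog(
        presses=np.array(presses), targets=targets, nontargets=nontargets,
        participant=participant, condition=condition,
    )


def simulate_study(
    design: StudyDesign,
    effect_spec: Sequence[CouplingSpec] = (),
    behavior_spec: BehaviorSpec | None = None,
    noise_sd: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    rate_spec: NumeralRateSpec | None = None,
    min_epochs: int = 90,
    epoch_length: int = 2048,
    bands: Sequence[Band] = DEFAULT_BANDS,
) -> StudyDataset:
    """A complete dataset: signals, events and responses for every cell.

    Rejects designs that cannot possibly yield ``min_epochs`` epochs of
    ``epoch_length`` samples per participant and condition.
    """
    per_block = design.block_samples // epoch_length
    capacity = per_block * design.n_blocks_per_condition
    if capacity < min_epochs:
        raise ValueError(
            f"design yields at most {capacity} epochs of {epoch_length} samples "
            f"per condition ({design.n_blocks_per_condition} blocks x {per_block}); "
            f"needs >= {min_epochs} — lengthen blocks or add blocks"
        )
    behavior_spec = behavior_spec or BehaviorSpec()
    rate_spec = rate_spec or NumeralRateSpec()
    root = np.random.SeedSequence(seed) if isinstance(seed, int) else seed

    design.validate_bands(bands)
    _check_duplicate_edges(effect_spec)
    recordings: dict[tuple, RegionRecording] = {}
    events: dict[tuple, EventList] = {}
    responses: dict[tuple, ResponseLog] = {}
    for p in range(design.n_participants):
        for c in design.conditions:
            p_hit, p_fa = behavior_spec.probs(c)
            for blk in range(design.n_blocks_per_condition):
                key = (p, c, blk)
                rng_sig = np.random.default_rng(_stage_seed(root, "signals", *key))
                rng_ev = np.random.default_rng(_stage_seed(root, "events", *key))
                rng_beh = np.random.default_rng(_stage_seed(root, "behavior", *key))
                sig = _simulate_block(design, effect_spec, c, noise_sd, rng_sig, bands)
                recordings[key] = RegionRecording(
                    sig, design.sampling_rate, design.labels,
                    participant=p, condition=c, block=blk,
                )
                events[key] = simulate_block_events(design, rate_spec, rng_ev)
                responses[key] = simulate_behavior(
                    events[key], p_hit, p_fa,
                    behavior_spec.rt_mean_ms, behavior_spec.rt_sd_ms,
                    seed=rng_beh, participant=p, condition=c,
                )
    return StudyDataset(
        design=design, coupling=tuple(effect_spec),
        recordings=recordings, events=events, responses=responses,
    )


# ---------------------------------------------------------------------------
# matrix-level generator for statistical calibration


def planted_effect_vector(
    n_regions: int, edges: Iterable[tuple[int, int]], delta: float
) -> np.ndarray:
    """Edge vector that adds ``delta`` PLI on the given edges, 0 elsewhere."""
    out = np.zeros(n_edges(n_regions))
    for i, j in edges:
        out[edge_index(i, j, n_regions)] = delta
    return out


def simulate_pli_dataset(
    n_participants: int = 27,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    n_regions: int = 36,
    n_epochs: int = 90,
    signs_per_epoch: int = 12,
    participant_sd: float = 0.02,
    cell_sd: float = 0.01,
    effects: Mapping[str, np.ndarray] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, np.ndarray]:
    """Per-condition arrays of per-participant edge vectors of averaged PLI.

    Each participant x condition x edge cell is the mean over
    ``n_epochs`` per-epoch PLIs, where a per-epoch PLI is |mean of
    ``signs_per_epoch`` independent fair signs| — the finite-sample null
    law of the PLI. ``signs_per_epoch`` plays the role of the number of
    effectively independent phase-difference signs per epoch (about one
    per oscillation cycle; 12 matches a ~6 Hz carrier over a ~2 s
    epoch). On top of that sit a stable participant-by-edge offset
    (``participant_sd``), independent cell noise (``cell_sd``), and the
    planted per-condition ``effects`` (edge vectors of PLI increments).
    Values are clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    ne = n_edges(n_regions)
    effects = effects or {}
    participant_offset = rng.normal(0.0, participant_sd, (n_participants, ne))
    out: dict[str, np.ndarray] = {}
    for c in conditions:
        counts = rng.binomial(signs_per_epoch, 0.5, (n_participants, n_epochs, ne))
        epoch_pli = np.abs(2.0 * counts - signs_per_epoch) / signs_per_epoch
        cell = epoch_pli.mean(axis=1)
        cell = cell + participant_offset + rng.normal(0.0, cell_sd, (n_participants, ne))
        eff = effects.get(c)
        if eff is not None:
            cell = cell + np.asarray(eff)
        out[c] = np.clip(cell, 0.0, 1.0)
    return out
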