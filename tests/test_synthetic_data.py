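"""Generator contracts: shapes, determinism, spectra, planted coupling."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.signal import periodogram

from pliconn.bands import DEFAULT_BANDS, LOW_ALPHA, THETA
from pliconn.connectivity import fc_matrices
from pliconn.datatypes import EventList, empty_event_table
from pliconn.preprocess import event_free_intervals, extract_event_free_epochs
from pliconn.synthetic_data import (
    BehaviorSpec,
    CouplingSpec,
    NumeralRateSpec,
    StudyDesign,
    expected_null_pli,
    simulate_behavior,
    simulate_block_events,
    simulate_events,
    simulate_pli_dataset,
    simulate_region_signals,
    simulate_study,
)


def _downstream_pli(design, coupling, band, seed, noise_sd=0.0, epoch_length=512):
    recs = simulate_region_signals(design, coupling, noise_sd=noise_sd, seed=seed,
                                   bands=(band,))
    ep = extract_event_free_epochs(recs[0], EventList(empty_event_table()),
                                   epoch_length=epoch_length)
    return fc_matrices(ep, [band])[0]


class TestSignals:
    def test_shape_contract(self):
        """36 regions at 1 kHz for 60 s -> a 36 x 60000 matrix."""
        design = StudyDesign(n_participants=1, conditions=("0",),
                             n_blocks_per_condition=1, block_duration=60.0,
                             sampling_rate=1000.0, n_regions=36)
        recs = simulate_region_signals(design, seed=0, bands=(THETA,))
        assert len(recs) == 1
        assert recs[0].signals.shape == (36, 60000)

    def test_determinism(self, small_design, alpha_pair_coupling):
        a = simulate_region_signals(small_design, [alpha_pair_coupling], seed=7,
                                    bands=(LOW_ALPHA,))
        b = simulate_region_signals(small_design, [alpha_pair_coupling], seed=7,
                                    bands=(LOW_ALPHA,))
        assert np.array_equal(a[0].signals, b[0].signals)
        c = simulate_region_signals(small_design, [alpha_pair_coupling], seed=8,
                                    bands=(LOW_ALPHA,))
        assert not np.array_equal(a[0].signals, c[0].signals)

    def test_full_coupling_forces_pli_one(self, small_design, alpha_pair_coupling):
        """A constant-lag pair yields downstream PLI exactly 1."""
        m = _downstream_pli(small_design, [alpha_pair_coupling], LOW_ALPHA, seed=1)
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_zero_coupling_matches_sign_mean_law(self, small_design):
        """At strength 0 the planted pair's mean PLI follows the
        |mean of N random signs| law, with N between half and all of the
        carrier cycles per analysis window (filtering re-correlates
        adjacent cycles)."""
        design = replace(small_design, block_duration=210.0, n_regions=2)
        spec = CouplingSpec(band=LOW_ALPHA, edges=((0, 1),), coupling_strength=0.0)
        m = _downstream_pli(design, [spec], LOW_ALPHA, seed=3)
        # Monte-Carlo oracle for E|mean of N signs|
        mc = np.random.default_rng(99)
        def law(n):
            signs = mc.integers(0, 2, size=(20000, n)) * 2 - 1
            return np.abs(signs.mean(axis=1)).mean()
        window_s = 512 / design.sampling_rate * 0.8  # 10% trim each side
        n_cycles = int(window_s * LOW_ALPHA.low)  # carrier is inside the band
        upper = law(max(2, n_cycles // 2))
        lower = law(int(window_s * LOW_ALPHA.high))
        assert lower <= m.values[0, 1] <= upper

    def test_coupling_monotonicity(self, small_design):
        """Downstream PLI on a planted edge rises with coupling strength."""
        plis = []
        for strength in (0.0, 0.5, 1.0):
            spec = CouplingSpec(band=LOW_ALPHA, edges=((0, 1),),
                                phase_lag=np.pi / 3, coupling_strength=strength)
            m = _downstream_pli(small_design, [spec], LOW_ALPHA, seed=5)
            plis.append(m.values[0, 1])
        assert plis[0] < plis[1] < plis[2]

    def test_band_power_concentration(self, small_design):
        """>90% of an oscillator's power lies inside its nominal band."""
        design = replace(small_design, n_regions=2, block_duration=60.0)
        recs = simulate_region_signals(design, noise_sd=0.0, seed=2, bands=(THETA,))
        f, pxx = periodogram(recs[0].signals[0], fs=design.sampling_rate)
        in_band = pxx[(f >= THETA.low) & (f <= THETA.high)].sum()
        assert in_band / pxx.sum() > 0.90

    def test_duplicate_edges_rejected(self, small_design):
        s1 = CouplingSpec(band=THETA, edges=((0, 1),))
        s2 = CouplingSpec(band=THETA, edges=((1, 0),))
        with pytest.raises(ValueError, match="twice"):
            simulate_region_signals(small_design, [s1, s2], seed=0, bands=(THETA,))
        with pytest.raises(ValueError, match="duplicate"):
            CouplingSpec(band=THETA, edges=((0, 1), (1, 0)))

    def test_coupling_band_range_enforced(self, small_design):
        spec = CouplingSpec(band=(0.1, 2.0), edges=((0, 1),))
        with pytest.raises(ValueError, match="0.5-70"):
            simulate_region_signals(small_design, [spec], seed=0, bands=(THETA,))


class TestEvents:
    def test_numeral_counts_match_printed_statistics(self):
        """Across many blocks the per-stream numeral count has mean ~50.7
        and SD ~2.7, truncated to 45..57."""
        design = StudyDesign(n_participants=40, conditions=("0",),
                             n_blocks_per_condition=2, block_duration=352.0,
                             sampling_rate=100.0, n_regions=2)
        events = simulate_events(design, seed=11)
        counts = [len(ev.onsets(kind="target_numeral")) for ev in events.values()]
        counts += [len(ev.onsets(kind="nontarget_numeral")) for ev in events.values()]
        counts = np.array(counts)
        assert counts.min() >= 45 and counts.max() <= 57
        assert np.mean(counts) == pytest.approx(50.7, abs=0.2)
        assert np.std(counts) == pytest.approx(2.7, abs=0.45)

    def test_zero_rate_gives_no_numerals(self, small_design, rng):
        spec = NumeralRateSpec(mean=0.0, sd=0.0, bounds=(0, 0))
        ev = simulate_block_events(small_design, spec, rng, violation_rate=(0, 0))
        assert len(ev.onsets(kind="target_numeral")) == 0

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            NumeralRateSpec(mean=-1.0)

    def test_determinism(self, small_design):
        a = simulate_events(small_design, seed=3)
        b = simulate_events(small_design, seed=3)
        for key in a:
            assert a[key].events.equals(b[key].events)

    def test_onsets_sorted_within_duration(self, small_design, rng):
        ev = simulate_block_events(small_design, NumeralRateSpec(mean=6, sd=1, bounds=(3, 9)), rng)
        onsets = ev.onsets()
        assert np.all(np.diff(onsets) >= 0)
        assert onsets.max() <= small_design.block_duration * 1000


class TestBehaviorGeneration:
    def test_perfect_detection(self, small_design, rng):
        ev = simulate_block_events(small_design, NumeralRateSpec(5, 1, (3, 8)), rng)
        log = simulate_behavior(ev, p_hit=1.0, p_fa=0.0, seed=1)
        assert len(log.presses) == len(log.targets)

    def test_determinism(self, small_design, rng):
        ev = simulate_block_events(small_design, NumeralRateSpec(5, 1, (3, 8)), rng)
        a = simulate_behavior(ev, seed=5)
        b = simulate_behavior(ev, seed=5)
        assert np.array_equal(a.presses, b.presses)

    def test_invalid_probabilities_rejected(self, no_events):
        with pytest.raises(ValueError):
            simulate_behavior(no_events, p_hit=1.5)
        with pytest.raises(ValueError):
            simulate_behavior(no_events, rt_mean=-5)


class TestStudy:
    def test_insufficient_duration_rejected(self):
        design = StudyDesign(n_participants=1, conditions=("0",),
                             n_blocks_per_condition=1, block_duration=10.0,
                             sampling_rate=250.0, n_regions=2)
        with pytest.raises(ValueError, match="at most"):
            simulate_study(design, min_epochs=90, epoch_length=512)

    def test_paper_shaped_design_meets_epoch_criterion(self):
        """Event-free 2048-sample windows left by a realistic event stream
        comfortably exceed 90 per condition (events only; no signals)."""
        design = StudyDesign(n_participants=1, conditions=("0",),
                             n_blocks_per_condition=4, block_duration=352.0,
                             sampling_rate=1000.0, n_regions=2)
        events = simulate_events(design, seed=21)
        total = 0
        for (p, c, blk), ev in events.items():
            log = simulate_behavior(ev, p_hit=0.9, p_fa=0.05, seed=blk)
            onsets = np.concatenate([ev.onsets(), log.presses])
            total += len(event_free_intervals(design.block_samples, onsets,
                                              design.sampling_rate, 2048))
        assert total >= 90

    def test_study_bundle_determinism(self):
        design = StudyDesign(n_participants=2, conditions=("0", "+5"),
                             n_blocks_per_condition=1, block_duration=25.0,
                             sampling_rate=200.0, n_regions=3)
        a = simulate_study(design, min_epochs=5, epoch_length=512, seed=9,
                           bands=(THETA,))
        b = simulate_study(design, min_epochs=5, epoch_length=512, seed=9,
                           bands=(THETA,))
        key = (1, "+5", 0)
        assert np.array_equal(a.recordings[key].signals, b.recordings[key].signals)
        assert a.events[key].events.equals(b.events[key].events)
        assert np.array_equal(a.responses[key].presses, b.responses[key].presses)


class TestMatrixLevelGenerator:
    def test_shapes_and_range(self):
        data = simulate_pli_dataset(n_participants=5, n_regions=10, n_epochs=20, seed=0)
        assert set(data) == {"-10", "-5", "0", "+5", "+10"}
        assert data["0"].shape == (5, 45)
        assert np.all((data["0"] >= 0) & (data["0"] <= 1))

    def test_null_mean_tracks_sign_law(self):
        data = simulate_pli_dataset(n_participants=30, n_regions=10,
                                    n_epochs=60, signs_per_epoch=12, seed=1,
                                    participant_sd=0.0, cell_sd=0.0)
        assert np.mean(data["0"]) == pytest.approx(expected_null_pli(12), rel=0.02)

    def test_planted_effect_shifts_mean(self):
        from pliconn.synthetic_data import planted_effect_vector
        eff = {"0": planted_effect_vector(10, [(0, 1)], 0.2)}
        data = simulate_pli_dataset(n_participants=50, n_regions=10, effects=eff, seed=2)
        diff = data["0"][:, 0].mean() - data["+5"][:, 0].mean()
        assert diff == pytest.approx(0.2, abs=0.03)
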