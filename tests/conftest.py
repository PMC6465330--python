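"""Shared fixtures: small study shapes that keep signal-level tests fast."""

import numpy as np
import pytest

from pliconn.bands import LOW_ALPHA, THETA
from pliconn.datatypes import EventList, empty_event_table
from pliconn.synthetic_data import CouplingSpec, StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def no_events():
    return EventList(empty_event_table())


@pytest.fixture
def small_design():
    """One participant, one condition, 40 s at 250 Hz, 4 regions."""
    return StudyDesign(
        n_participants=1, conditions=("0",), n_blocks_per_condition=1,
        block_duration=40.0, sampling_rate=250.0, n_regions=4,
    )


@pytest.fixture
def alpha_pair_coupling():
    return CouplingSpec(
        band=LOW_ALPHA, edges=((0, 1),), phase_lag=np.pi / 3, coupling_strength=1.0
    )


@pytest.fixture
def theta_band():
    return THETA
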