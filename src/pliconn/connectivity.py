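"""Phase lag index (PLI) connectivity.

The PLI between two signals is

    PLI = | < sign(dphi(t_k)) > |,   k = 1..N,

the absolute value of the time-averaged sign of their instantaneous
phase difference. It is 0 for phase differences symmetric around zero
(including genuinely unsynchronised pairs and zero-lag coupling such as
volume conduction) and 1 for a constant nonzero lag. Phases come from
the analytic signal (Hilbert transform) of the band-filtered epoch.

Conventions: sign(0) contributes 0, which also makes the self-PLI
exactly 0; a configurable fraction of samples at each epoch edge is
discarded after the transform, because filter and Hilbert edge effects
distort the phase there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import Band, DEFAULT_BANDS, get_band
from .datatypes import ConnectivityMatrix, EpochSet
from .edgeops import to_matrix
from .preprocess import design_bandpass, _zero_phase

logger = logging.getLogger(__name__)

#: fraction of samples discarded at each epoch edge after the transform
EDGE_TRIM = 0.1


@dataclass
class PhaseSeries:
    """Instantaneous phase per region, radians in (-pi, pi]."""

    phases: np.ndarray  # (n_regions, n_samples)
    band: Band
    sampling_rate: float


def instantaneous_phase(
    epoch: np.ndarray,
    band: Band | str | tuple[float, float],
    sampling_rate: float,
    edge_trim: float = EDGE_TRIM,
) -> PhaseSeries:
    """Band-filter an epoch and return analytic-signal phases.

    ``epoch`` is (n_regions, n_samples) or (n_samples,). The FIR length
    is capped below the epoch length, so very low bands (delta at a
    2048-sample, 1 kHz epoch) get a relaxed transition; the epoch must
    still span at least one cycle of the band's low edge.
    """
    band = get_band(band)
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    n = x.shape[1]
    if n / sampling_rate < 1.0 / band.low:
        raise ValueError(
            f"epoch of {n / sampling_rate:.3f} s shorter than one cycle "
            f"of {band.low} Hz"
        )
    numtaps = min(int(3 * sampling_rate / band.low), n - 1)
    taps = design_bandpass(band.low, band.high, sampling_rate, numtaps)
    filtered = _zero_phase(x, taps)
    analytic = sps.hilbert(filtered, axis=1)
    phases = np.angle(analytic)
    trim = int(edge_trim * n)
    if trim:
        phases = phases[:, trim : n - trim]
    return PhaseSeries(phases=phases, band=band, sampling_rate=sampling_rate)


def _wrapped_sign(dphi: np.ndarray) -> np.ndarray:
    """sign of the phase difference wrapped to (-pi, pi], with sign(0) = 0."""
    return np.sign(np.angle(np.exp(1j * dphi)))


def pli(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLI of two equal-length phase series."""
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"phase series lengths differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty phase series")
    return float(np.abs(np.mean(_wrapped_sign(a - b))))


def pli_matrix(phases: PhaseSeries) -> np.ndarray:
    """All-pairs PLI for one epoch, exactly symmetric with zero diagonal."""
    p = phases.phases
    n_regions = p.shape[0]
    iu, ju = np.triu_indices(n_regions, 1)
    signs = _wrapped_sign(p[iu] - p[ju])  # (n_pairs, n_samples)
    vec = np.abs(signs.mean(axis=1))
    return to_matrix(vec, n_regions)


def fc_matrices(
    epochs: EpochSet,
    bands: "list[Band] | tuple[Band, ...]" = DEFAULT_BANDS,
    edge_trim: float = EDGE_TRIM,
) -> list[ConnectivityMatrix]:
    """Epoch-wise PLI matrices averaged across epochs, one per band.

    Returns one matrix per band for the epoch set's participant and
    condition; bands whose group has zero epochs are omitted with a log
    message.
    """
    out = []
    if epochs.n_epochs == 0:
        logger.warning(
            "no epochs for participant=%s condition=%s: no FC matrices",
            epochs.participant, epochs.condition,
        )
        return out
    for band in bands:
        acc = np.zeros((len(epochs.region_labels),) * 2)
        for e in range(epochs.n_epochs):
            ph = instantaneous_phase(
                epochs.epochs[e], band, epochs.sampling_rate, edge_trim
            )
            acc += pli_matrix(ph)
        out.append(
            ConnectivityMatrix(
                values=acc / epochs.n_epochs, band=get_band(band),
                region_labels=epochs.region_labels,
                participant=epochs.participant, condition=epochs.condition,
                n_epochs_averaged=epochs.n_epochs,
            )
        )
    return out
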