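"""Canonical EEG frequency bands used throughout the pipeline.

Six bands spanning 0.5–70 Hz. The alpha range is split into a lower
(8–10 Hz) and an upper (10–12 Hz) sub-band, which matters for selective
attention work where the two sub-bands dissociate.
"""

from __future__ import annotations

from typing import NamedTuple


class Band(NamedTuple):
    """A named frequency interval in Hz."""

    name: str
    low: float
    high: float

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, freq: float) -> bool:
        return self.low <= freq <= self.high


DELTA = Band("delta", 0.5, 4.0)
THETA = Band("theta", 4.0, 8.0)
LOW_ALPHA = Band("low_alpha", 8.0, 10.0)
HIGH_ALPHA = Band("high_alpha", 10.0, 12.0)
BETA = Band("beta", 13.0, 30.0)
GAMMA = Band("gamma", 30.0, 70.0)

DEFAULT_BANDS: tuple[Band, ...] = (DELTA, THETA, LOW_ALPHA, HIGH_ALPHA, BETA, GAMMA)

BAND_BY_NAME: dict[str, Band] = {b.name: b for b in DEFAULT_BANDS}


def get_band(band: "Band | str | tuple[float, float]") -> Band:
    """Coerce a band name, (low, high) pair, or Band into a Band."""
    if isinstance(band, Band):
        return band
    if isinstance(band, str):
        try:
            return BAND_BY_NAME[band]
        except KeyError:
            raise KeyError(
                f"unknown band {band!r}; known: {sorted(BAND_BY_NAME)}"
            ) from None
    low, high = band
    return Band(f"{low}-{high}Hz", float(low), float(high))
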