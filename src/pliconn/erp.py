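"""ERP component amplitudes as window means.

Component amplitude is the arithmetic mean of the baseline-corrected
signal at one site over a fixed post-stimulus window, averaged over
epochs — the standard mean-window measure. Default windows: N2b
120–280 ms, N400 350–550 ms, P3b 550–750 ms, all at a parietal site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import EpochSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComponentWindow:
    name: str
    interval_ms: tuple[float, float]
    site: str = "Pz"

    def __post_init__(self) -> None:
        lo, hi = self.interval_ms
        if not lo < hi:
            raise ValueError("component interval must be increasing")


N2B = ComponentWindow("N2b", (120.0, 280.0))
N400 = ComponentWindow("N400", (350.0, 550.0))
P3B = ComponentWindow("P3b", (550.0, 750.0))

DEFAULT_COMPONENTS: tuple[ComponentWindow, ...] = (N2B, N400, P3B)


def component_amplitude(
    epochs: EpochSet,
    window: ComponentWindow,
    site: "str | int | None" = None,
) -> float:
    """Mean amplitude (uV) of ``window`` at one site over event-locked epochs.

    ``site`` is a region label or index; defaults to the window's site
    label. Returns NaN (with a log entry) when the cell has no epochs.
    """
    if epochs.kind != "event_locked":
        raise ValueError("component amplitudes need event-locked epochs")
    if epochs.window_ms is None:
        raise ValueError("epoch set lacks its window metadata")
    w_lo, w_hi = epochs.window_ms
    lo, hi = window.interval_ms
    if not (w_lo <= lo < hi <= w_hi):
        raise ValueError(
            f"component window {window.interval_ms} outside epoch window {epochs.window_ms}"
        )
    if epochs.n_epochs == 0:
        logger.warning("no epochs for %s: amplitude undefined", window.name)
        return float("nan")
    site = window.site if site is None else site
    if isinstance(site, str):
        labels = list(epochs.region_labels)
        if site not in labels:
            raise KeyError(f"site {site!r} not among region labels")
        site_idx = labels.index(site)
    else:
        site_idx = int(site)
    fs = epochs.sampling_rate
    a = int(round((lo - w_lo) * fs / 1000.0))
    b = int(round((hi - w_lo) * fs / 1000.0))
    return float(epochs.epochs[:, site_idx, a:b].mean())


def amplitude_table(
    cells: "dict[tuple, EpochSet]",
    components: tuple[ComponentWindow, ...] = DEFAULT_COMPONENTS,
    site: "str | int | None" = None,
) -> pd.DataFrame:
    """Tidy table of amplitudes: one row per cell x component.

    ``cells`` maps (participant, condition, event_kind) to event-locked
    epoch sets.
    """
    rows = []
    for (participant, condition, event_kind), ep in sorted(cells.items()):
        for comp in components:
            rows.append(
                {
                    "participant": participant,
                    "condition": condition,
                    "event_kind": event_kind,
                    "component": comp.name,
                    "amplitude_uv": component_amplitude(ep, comp, site=site),
                    "n_epochs": ep.n_epochs,
                }
            )
    return pd.DataFrame(rows)
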