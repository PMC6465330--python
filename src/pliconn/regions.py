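"""The 36-region cortical parcellation used as network nodes.

Eighteen regions per hemisphere, grouped by lobe. Labels are the standard
abbreviations prefixed with L/R for hemisphere. Aggregate source time
series from these regions are the nodes of every connectivity graph in
this package.
"""

from __future__ import annotations

# (abbreviation, full name, lobe) — 18 per hemisphere
REGION_TABLE: tuple[tuple[str, str, str], ...] = (
    ("PrCG", "Precentral gyrus", "frontal"),
    ("IFG", "Inferior frontal gyrus", "frontal"),
    ("MFGr", "Rostral middle frontal gyrus", "frontal"),
    ("MFGc", "Caudal middle frontal gyrus", "frontal"),
    ("SFG", "Superior frontal lobe", "frontal"),
    ("OFC", "Orbitofrontal lobe", "frontal"),
    ("STC", "Superior temporal lobe", "temporal"),
    ("MTG", "Middle temporal gyrus", "temporal"),
    ("ITG", "Inferior temporal gyrus", "temporal"),
    ("FFG", "Fusiform gyrus", "temporal"),
    ("PCC", "Posterior cingulate lobe", "cingular"),
    ("ACC", "Anterior cingulate lobe", "cingular"),
    ("PoCG", "Postcentral gyrus", "parietal"),
    ("PCG", "Paracentral gyrus", "parietal"),
    ("SMG", "Supramarginal gyrus", "parietal"),
    ("IPG", "Inferior parietal gyrus", "parietal"),
    ("SPG", "Superior parietal", "parietal"),
    ("Pcun", "Precuneus", "parietal"),
)


def region_labels(n_regions: int = 36) -> list[str]:
    """Hemisphere-prefixed labels, left hemisphere first.

    For the default 36 regions this yields ``L-PrCG ... L-Pcun,
    R-PrCG ... R-Pcun``. Other counts get generic ``R01..`` labels so
    that scaled-down simulations stay self-describing.
    """
    if n_regions == 2 * len(REGION_TABLE):
        return [f"{h}-{abbr}" for h in ("L", "R") for abbr, _, _ in REGION_TABLE]
    return [f"R{i + 1:02d}" for i in range(n_regions)]


def n_possible_edges(n_regions: int) -> int:
    """Number of undirected region pairs: n(n-1)/2 (630 for 36 regions)."""
    return n_regions * (n_regions - 1) // 2
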