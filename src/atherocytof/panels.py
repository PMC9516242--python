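"""Antibody panel definitions.

Two ~30-marker panels mirror the usual peripheral-blood CyTOF setup: a T
cell panel resolving lymphoid subsets and a myeloid panel resolving
monocyte/DC subsets.  Lineage markers are shared identity markers; the rest
are functional readouts.  Each panel also carries the structural channels
(DNA intercalator, viability, event length, bead, time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .events import (
    BEAD,
    DNA,
    EVENT_LENGTH,
    FUNCTIONAL,
    LINEAGE,
    STRUCTURAL_CHANNELS,
    TIME,
    VIABILITY,
    Channel,
)

LINEAGE_MARKERS = [
    "CD45",
    "CD66b",
    "CD3",
    "CD4",
    "CD8",
    "CD19",
    "CD56",
    "CD14",
    "CD16",
    "CD33",
]


@dataclass(frozen=True)
class MarkerPanel:
    name: str
    lineage: tuple[str, ...]
    functional: tuple[str, ...]

    @property
    def markers(self) -> tuple[str, ...]:
        return self.lineage + self.functional

    def channels(self, structural: bool = True) -> list[Channel]:
        chans = [Channel(m, role=LINEAGE) for m in self.lineage]
        chans += [Channel(m, role=FUNCTIONAL) for m in self.functional]
        if structural:
            for name, (mass, role) in STRUCTURAL_CHANNELS.items():
                chans.append(Channel(name, mass=mass, role=role))
        return chans


T_PANEL = MarkerPanel(
    name="T",
    lineage=tuple(LINEAGE_MARKERS) + ("TCRgd",),
    functional=(
        "CD45RA",
        "CCR7",
        "CD27",
        "CD38",
        "CD25",
        "CD127",
        "FoxP3",
        "PD-1",
        "HLA-DR",
        "CD161",
        "GranzymeB",
        "T-bet",
        "CD11b",
        "CD11c",
        "Fas",
    ),
)

MYELOID_PANEL = MarkerPanel(
    name="myeloid",
    lineage=tuple(LINEAGE_MARKERS),
    functional=(
        "CD11b",
        "CD11c",
        "CCR2",
        "CX3CR1",
        "CD36",
        "HLA-DR",
        "CD64",
        "CD68",
        "CD32",
        "CXCR4",
        "CD169",
        "FceRIa",
        "CD54",
        "CD36L1",
        "CD123",
    ),
)

PANELS: dict[str, MarkerPanel] = {"T": T_PANEL, "myeloid": MYELOID_PANEL}


def get_panel(name: str) -> MarkerPanel:
    try:
        return PANELS[name]
    except KeyError:
        raise KeyError(f"unknown panel {name!r}; available: {sorted(PANELS)}") from None
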