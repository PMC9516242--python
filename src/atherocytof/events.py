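"""Event-level cytometry data container and channel metadata.

A :class:`CellEventMatrix` holds one sample's events-by-channels intensity
matrix together with per-channel metadata (marker name, metal mass, and a
functional role).  Roles drive downstream behaviour: gating only consults
structural channels (DNA, viability, event length), and the arcsinh
transform only touches antibody channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Channel roles
LINEAGE = "lineage"
FUNCTIONAL = "functional"
DNA = "dna"
VIABILITY = "viability"
EVENT_LENGTH = "event_length"
BEAD = "bead"
TIME = "time"
UNASSIGNED = "unassigned"

#: roles that are never arcsinh-transformed and never used as markers
STRUCTURAL_ROLES = frozenset({DNA, VIABILITY, EVENT_LENGTH, BEAD, TIME})
MARKER_ROLES = frozenset({LINEAGE, FUNCTIONAL})

# Default metal masses of the structural channels on a CyTOF panel.
STRUCTURAL_CHANNELS = {
    "DNA1": ("Ir191", DNA),
    "DNA2": ("Ir193", DNA),
    "Cisplatin": ("Pt194", VIABILITY),
    "Event_length": ("", EVENT_LENGTH),
    "Bead": ("Ce140", BEAD),
    "Time": ("", TIME),
}


@dataclass(frozen=True)
class Channel:
    """One acquisition channel: marker name, metal mass, functional role."""

    name: str
    mass: str = ""
    role: str = UNASSIGNED


def infer_role(name: str) -> str:
    """Guess a channel role from its name (case-insensitive heuristics)."""
    low = name.lower()
    if low.startswith("dna") or "ir191" in low or "ir193" in low:
        return DNA
    if "cisplatin" in low or "pt194" in low or low.startswith("live"):
        return VIABILITY
    if "event_length" in low or "eventlength" in low or low == "length":
        return EVENT_LENGTH
    if low.startswith("bead") or "ce140" in low:
        return BEAD
    if low == "time":
        return TIME
    return UNASSIGNED


@dataclass
class CellEventMatrix:
    """Events x channels intensity matrix for one sample.

    Parameters
    ----------
    sample_id
        Identifier of the biological sample.
    data
        ``(n_events, n_channels)`` array of nonnegative intensities
        (raw scale) or transformed values once :func:`arcsinh_transform`
        has been applied.
    channels
        Per-column :class:`Channel` metadata.
    transformed
        Whether marker channels are on the arcsinh scale.
    """

    sample_id: str
    data: np.ndarray
    channels: list[Channel] = field(default_factory=list)
    transformed: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("event data must be 2-D (events x channels)")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channels for {self.data.shape[1]} columns"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def index(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        raise KeyError(f"channel {name!r} not present")

    def indices_with_role(self, *roles: str) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c.role in roles]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.index(name)]

    @property
    def marker_names(self) -> list[str]:
        return [c.name for c in self.channels if c.role in MARKER_ROLES]

    def marker_data(self) -> np.ndarray:
        """Intensity matrix restricted to lineage/functional channels."""
        return self.data[:, self.indices_with_role(*MARKER_ROLES)]

    def subset(self, mask: np.ndarray) -> "CellEventMatrix":
        """New matrix keeping only events where ``mask`` is True."""
        return replace(self, data=self.data[np.asarray(mask)])

    def copy(self) -> "CellEventMatrix":
        return replace(self, data=self.data.copy(), channels=list(self.channels))
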