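"""Event preprocessing: I/O, bead normalization, gating, arcsinh transform.

The fixed pipeline order is normalize -> gate -> transform.  Gates operate
on raw intensities (thresholds in cytometry practice are quoted raw-scale),
so gating and transformation commute with respect to which events are
removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fcs
from .events import (
    BEAD,
    DNA,
    EVENT_LENGTH,
    MARKER_ROLES,
    VIABILITY,
    CellEventMatrix,
    Channel,
    infer_role,
)
from .panels import MarkerPanel

DEFAULT_COFACTOR = 5.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_events(
    path: str | Path,
    format: str | None = None,
    panel: MarkerPanel | None = None,
    sample_id: str | None = None,
) -> CellEventMatrix:
    """Load a sample from FCS or CSV.

    Channel roles come from the file (FCS role keywords), else from the
    panel metadata, else from name heuristics.  Unknown channels get the
    role "unassigned" with a warning.
    """
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    format = format.lower()
    if format == "fcs":
        events = fcs.read_fcs(path, sample_id=sample_id)
    elif format == "csv":
        df = pd.read_csv(path)
        channels = [Channel(name=c, role=infer_role(c)) for c in df.columns]
        events = CellEventMatrix(
            sample_id=sample_id or path.stem,
            data=df.to_numpy(dtype=float),
            channels=channels,
        )
    else:
        raise ValueError(f"unknown format {format!r}")

    if panel is not None:
        resolved = []
        panel_roles = {m: "lineage" for m in panel.lineage}
        panel_roles.update({m: "functional" for m in panel.functional})
        for ch in events.channels:
            if ch.name in panel_roles:
                resolved.append(Channel(ch.name, ch.mass, panel_roles[ch.name]))
            elif ch.role != "unassigned":
                resolved.append(ch)
            else:
                warnings.warn(f"channel {ch.name!r} not in panel; role unassigned")
                resolved.append(ch)
        events.channels = resolved
    return events


def write_events(events: CellEventMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a sample as FCS (channel names = marker names) or CSV."""
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format.lower() == "fcs":
        fcs.write_fcs(path, events)
    else:
        pd.DataFrame(events.data, columns=events.channel_names).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Bead normalization (simplified EQ-bead stand-in)
# ---------------------------------------------------------------------------

def bead_normalize(
    events: CellEventMatrix,
    bead_reference: dict[str, float],
    bead_threshold: float = 50.0,
    n_time_bins: int = 10,
    keep_beads: bool = False,
) -> CellEventMatrix:
    """Correct sensitivity drift against spiked-in calibration beads.

    Bead events (bead channel above ``bead_threshold``) are binned over
    acquisition time; within each bin every referenced channel is rescaled
    so its bead median matches ``bead_reference``.  Channels without a
    reference get the bin's median correction factor (drift is dominated by
    overall detector sensitivity).  Bead events are dropped from the output.
    """
    out = events.copy()
    bead_idx = out.indices_with_role(BEAD)
    if not bead_idx:
        warnings.warn("no bead channel present; returning events unchanged")
        return out
    bead_mask = out.data[:, bead_idx[0]] > bead_threshold
    if not bead_mask.any():
        warnings.warn("no bead events found; returning events unchanged")
        return out

    time_idx = out.indices_with_role("time")
    t = out.data[:, time_idx[0]] if time_idx else np.arange(out.n_events, dtype=float)
    edges = np.quantile(t, np.linspace(0, 1, n_time_bins + 1))
    edges[-1] += 1.0  # right-inclusive last bin
    bins = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_time_bins - 1)

    ref_cols = {name: out.index(name) for name in bead_reference if name in out.channel_names}
    correctable = [
        i for i, c in enumerate(out.channels)
        if c.role in MARKER_ROLES or c.role == DNA
    ]
    for b in range(n_time_bins):
        in_bin = bins == b
        bead_in_bin = in_bin & bead_mask
        if not bead_in_bin.any():
            continue
        factors = {}
        for name, col in ref_cols.items():
            med = np.median(out.data[bead_in_bin, col])
            if med > 0:
                factors[col] = bead_reference[name] / med
        if not factors:
            continue
        default = float(np.median(list(factors.values())))
        for col in correctable:
            out.data[in_bin, col] *= factors.get(col, default)

    return out if keep_beads else out.subset(~bead_mask)


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

@dataclass
class GateConfig:
    """Thresholds for debris/dead-cell/doublet removal (raw scale).

    The source procedure is manual; these reproduce it as explicit,
    overridable thresholds.  ``None`` disables the corresponding rule side.
    """

    event_length_max: float | None = None
    dna_min: float | None = None
    dna_max: float | None = None
    viability_max: float | None = None

    def __post_init__(self) -> None:
        if (
            self.dna_min is not None
            and self.dna_max is not None
            and not self.dna_min < self.dna_max
        ):
            raise ValueError("dna_min must be < dna_max")

    @classmethod
    def from_events(
        cls,
        events: CellEventMatrix,
        dna_quantiles: tuple[float, float] = (0.01, 0.99),
        length_quantile: float = 0.99,
        viability_quantile: float = 0.99,
    ) -> "GateConfig":
        """Percentile-based defaults automating the manual gate."""
        dna_idx = events.indices_with_role(DNA)
        via_idx = events.indices_with_role(VIABILITY)
        len_idx = events.indices_with_role(EVENT_LENGTH)
        kwargs: dict[str, float] = {}
        if dna_idx:
            # the gate applies per DNA channel: take the loosest envelope
            lows, highs = [], []
            for i in dna_idx:
                col = events.data[:, i]
                positive = col[col > 0]
                if len(positive):
                    lows.append(float(np.quantile(positive, dna_quantiles[0])))
                    highs.append(float(np.quantile(positive, dna_quantiles[1])))
            if lows:
                kwargs["dna_min"] = min(lows)
                kwargs["dna_max"] = max(highs)
        if len_idx:
            kwargs["event_length_max"] = float(
                np.quantile(events.data[:, len_idx[0]], length_quantile)
            )
        if via_idx:
            kwargs["viability_max"] = float(
                np.quantile(events.data[:, via_idx[0]], viability_quantile)
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GateConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class GateReport:
    """Accounting of removed events, attributed per rule (conjunctive)."""

    n_input: int
    n_retained: int
    failed_per_rule: dict[str, int]        # events failing each rule (overlaps allowed)
    exclusive_per_rule: dict[str, int]     # events failing exactly that one rule
    n_multiply_flagged: int                # events failing >= 2 rules

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained


def gate_events(
    events: CellEventMatrix, cfg: GateConfig
) -> tuple[CellEventMatrix, GateReport]:
    """Apply conjunctive debris/dead/doublet gates on raw intensities.

    An event is retained iff it passes every enabled rule: event length
    <= max, every DNA channel within [min, max], viability <= max.
    """
    fails: dict[str, np.ndarray] = {}
    n = events.n_events

    if cfg.event_length_max is not None:
        idx = events.indices_with_role(EVENT_LENGTH)
        if not idx:
            raise ValueError("event-length gate requested but channel missing")
        fails["event_length"] = events.data[:, idx[0]] > cfg.event_length_max

    if cfg.dna_min is not None or cfg.dna_max is not None:
        idx = events.indices_with_role(DNA)
        if not idx:
            raise ValueError("DNA gate requested but no DNA channel present")
        dna = events.data[:, idx]
        bad = np.zeros(n, dtype=bool)
        if cfg.dna_min is not None:
            bad |= (dna < cfg.dna_min).any(axis=1)
        if cfg.dna_max is not None:
            bad |= (dna > cfg.dna_max).any(axis=1)
        fails["dna"] = bad

    if cfg.viability_max is not None:
        idx = events.indices_with_role(VIABILITY)
        if not idx:
            raise ValueError("viability gate requested but channel missing")
        fails["viability"] = events.data[:, idx[0]] > cfg.viability_max

    if fails:
        fail_matrix = np.stack(list(fails.values()))
        n_failed_rules = fail_matrix.sum(axis=0)
    else:
        fail_matrix = np.zeros((0, n), dtype=bool)
        n_failed_rules = np.zeros(n, dtype=int)

    keep = n_failed_rules == 0
    report = GateReport(
        n_input=n,
        n_retained=int(keep.sum()),
        failed_per_rule={r: int(m.sum()) for r, m in fails.items()},
        exclusive_per_rule={
            r: int((m & (n_failed_rules == 1)).sum()) for r, m in fails.items()
        },
        n_multiply_flagged=int((n_failed_rules >= 2).sum()),
    )
    return events.subset(keep), report


# ---------------------------------------------------------------------------
# Arcsinh transform
# ---------------------------------------------------------------------------

def arcsinh_transform(
    events: CellEventMatrix, cofactor: float = DEFAULT_COFACTOR
) -> CellEventMatrix:
    """x -> asinh(x / cofactor) on lineage/functional channels only."""
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    out = events.copy()
    cols = out.indices_with_role(*MARKER_ROLES)
    out.data[:, cols] = np.arcsinh(out.data[:, cols] / cofactor)
    out.transformed = True
    return out


def inverse_arcsinh(
    events: CellEventMatrix, cofactor: float = DEFAULT_COFACTOR
) -> CellEventMatrix:
    """Undo :func:`arcsinh_transform` (marker channels back to raw scale)."""
    out = events.copy()
    cols = out.indices_with_role(*MARKER_ROLES)
    out.data[:, cols] = np.sinh(out.data[:, cols]) * cofactor
    out.transformed = False
    return out


def preprocess_sample(
    events: CellEventMatrix,
    gate_cfg: GateConfig | None = None,
    bead_reference: dict[str, float] | None = None,
    cofactor: float = DEFAULT_COFACTOR,
) -> tuple[CellEventMatrix, GateReport | None]:
    """Full pipeline: normalize (optional) -> gate (optional) -> transform."""
    if bead_reference is not None:
        events = bead_normalize(events, bead_reference)
    report = None
    if gate_cfg is not None:
        events, report = gate_events(events, gate_cfg)
    return arcsinh_transform(events, cofactor=cofactor), report
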