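"""Gensini coronary plaque-burden scoring.

Total score = sum over coronary segments of a stenosis severity step score
times a segment importance weight.  Severity doubles at each canonical
luminal-reduction level (25/50/75/90/99/100 percent); segments are weighted
by the myocardium they supply (left main heaviest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Fixed segment vocabulary with canonical importance weights.
SEGMENT_WEIGHTS: dict[str, float] = {
    "LM": 5.0,
    "LAD_prox": 2.5,
    "LAD_mid": 1.5,
    "LAD_dist": 1.0,
    "D1": 1.0,
    "D2": 0.5,
    "LCX_prox": 2.5,
    "LCX_dist": 1.0,
    "RCA_prox": 1.0,
    "RCA_mid": 1.0,
    "RCA_dist": 1.0,
}

#: Upper edges of the luminal-reduction bands and their severity scores.
#: Bands are half-open, closed on the right: (lo, hi] -> score.
SEVERITY_LEVELS: tuple[tuple[float, int], ...] = (
    (25.0, 1),
    (50.0, 2),
    (75.0, 4),
    (90.0, 8),
    (99.0, 16),
    (100.0, 32),
)


def severity_score(
    stenosis_pct: float,
    levels: tuple[tuple[float, int], ...] = SEVERITY_LEVELS,
) -> int:
    """Map a luminal-reduction percentage onto the severity step scale.

    0 scores 0 (no lesion); otherwise the score of the first band whose
    right edge is >= the stenosis.
    """
    if not 0.0 <= stenosis_pct <= 100.0:
        raise ValueError(f"stenosis must be in [0, 100], got {stenosis_pct}")
    if stenosis_pct == 0:
        return 0
    for upper, score in levels:
        if stenosis_pct <= upper:
            return score
    raise AssertionError("unreachable: levels must end at 100")


def segment_weight(segment: str) -> float:
    """Importance weight of a coronary segment."""
    try:
        return SEGMENT_WEIGHTS[segment]
    except KeyError:
        raise KeyError(
            f"unknown segment {segment!r}; expected one of {sorted(SEGMENT_WEIGHTS)}"
        ) from None


@dataclass
class SegmentStenosisProfile:
    """Per-segment stenosis percentages for one patient."""

    patient_id: str
    stenoses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seg, pct in self.stenoses.items():
            if seg not in SEGMENT_WEIGHTS:
                raise KeyError(f"unknown segment {seg!r}")
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"stenosis out of range for {seg}: {pct}")

    @property
    def max_stenosis(self) -> float:
        return max(self.stenoses.values(), default=0.0)


@dataclass
class GensiniScore:
    patient_id: str
    total: float
    contributions: pd.DataFrame  # columns: segment, stenosis_pct, severity, weight, product


def gensini_score(profile: SegmentStenosisProfile) -> GensiniScore:
    """Score one patient's stenosis profile."""
    rows = []
    for seg, pct in profile.stenoses.items():
        sev = severity_score(pct)
        w = segment_weight(seg)
        rows.append((seg, pct, sev, w, sev * w))
    contrib = pd.DataFrame(
        rows, columns=["segment", "stenosis_pct", "severity", "weight", "product"]
    )
    total = float(contrib["product"].sum()) if len(contrib) else 0.0
    return GensiniScore(patient_id=profile.patient_id, total=total, contributions=contrib)


def read_stenosis_csv(path: str | Path) -> list[SegmentStenosisProfile]:
    """Read long-format CSV (patient_id, segment, stenosis_pct)."""
    df = pd.read_csv(path)
    required = {"patient_id", "segment", "stenosis_pct"}
    if not required.issubset(df.columns):
        raise ValueError(f"stenosis CSV needs columns {sorted(required)}")
    profiles = []
    for pid, grp in df.groupby("patient_id", sort=False):
        profiles.append(
            SegmentStenosisProfile(
                patient_id=str(pid),
                stenoses=dict(zip(grp["segment"], grp["stenosis_pct"].astype(float))),
            )
        )
    return profiles


def write_stenosis_csv(profiles: list[SegmentStenosisProfile], path: str | Path) -> None:
    rows = [
        {"patient_id": p.patient_id, "segment": seg, "stenosis_pct": pct}
        for p in profiles
        for seg, pct in p.stenoses.items()
    ]
    pd.DataFrame(rows, columns=["patient_id", "segment", "stenosis_pct"]).to_csv(
        path, index=False
    )


def score_table(profiles: list[SegmentStenosisProfile]) -> pd.DataFrame:
    """Score many profiles into a tidy table (one row per patient)."""
    seen = set()
    rows = []
    for p in profiles:
        if p.patient_id in seen:
            warnings.warn(f"duplicate patient_id {p.patient_id!r}; keeping both")
        seen.add(p.patient_id)
        score = gensini_score(p)
        row = {"patient_id": p.patient_id, "gensini_total": score.total}
        for seg in SEGMENT_WEIGHTS:
            contrib = score.contributions
            hit = contrib.loc[contrib["segment"] == seg, "product"]
            row[seg] = float(hit.iloc[0]) if len(hit) else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
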