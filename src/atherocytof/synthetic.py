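"""Synthetic cohort generation.

Produces per-sample event matrices with known cluster structure, a clinical
covariate table, per-segment stenosis profiles, and the ground truth needed
to test every downstream stage (cluster labels, mixture weights, planted
informative features, injected artifact flags).

Event intensities are Gaussian on the arcsinh scale per cluster, mapped
back through the inverse transform to the raw scale and truncated at zero.
Between-sample frequency variation is Dirichlet around group-level mixture
weights; group effects enter as log-fold shifts of those weights and as
additive marker shifts on the transformed scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import CellEventMatrix, STRUCTURAL_CHANNELS
from .panels import MarkerPanel, get_panel

GROUPS = ("NC", "CAS", "ASCVD")

#: desk-scale default group sizes (real cohort: 13 / 38 / 32)
DEFAULT_N_PER_GROUP = {"NC": 13, "CAS": 38, "ASCVD": 32}

# Group-level clinical covariate distributions (mean, SD) and comorbidity
# probabilities, patterned on the cohort summary table used for acceptance
# testing.  These are generator defaults, not estimates.
DEFAULT_CLINICAL_MODEL = {
    "NC": {
        "age": (56.38, 5.04), "BMI": (23.78, 2.98), "TC": (5.02, 0.90),
        "TG": (1.35, 0.48), "HDL": (1.40, 0.26), "LDL": (2.60, 0.57),
        "comorbidities": {
            "hypertension": 0.154, "hyperlipidemia": 0.154,
            "diabetes": 0.0, "smoker": 0.231, "statins": 0.0,
        },
    },
    "CAS": {
        "age": (56.50, 7.94), "BMI": (23.48, 3.21), "TC": (4.40, 0.77),
        "TG": (1.62, 0.91), "HDL": (1.31, 0.30), "LDL": (2.19, 0.61),
        "comorbidities": {
            "hypertension": 0.395, "hyperlipidemia": 0.368,
            "diabetes": 0.132, "smoker": 0.342, "statins": 0.316,
        },
    },
    "ASCVD": {
        "age": (60.03, 7.59), "BMI": (25.35, 3.63), "TC": (4.22, 0.96),
        "TG": (1.87, 0.65), "HDL": (1.10, 0.24), "LDL": (2.14, 0.67),
        "comorbidities": {
            "hypertension": 0.688, "hyperlipidemia": 0.656,
            "diabetes": 0.125, "smoker": 0.563, "statins": 0.594,
        },
    },
}

DEFAULT_STENOSIS_MODEL = {
    # (min segments, max segments, min stenosis, max stenosis); NC has none
    "CAS": {"segments": (1, 3), "stenosis": (10.0, 49.5)},
    "ASCVD": {"segments": (1, 4), "stenosis": (50.0, 99.0)},
}


@dataclass
class ClusterProfile:
    """Per-cluster marker distribution on the arcsinh scale."""

    cluster_id: str
    lineage: str
    location: dict[str, float]
    scale: dict[str, float]

    def __post_init__(self) -> None:
        for m, s in self.scale.items():
            if s < 0:
                raise ValueError(f"{self.cluster_id}: negative scale for {m}")


@dataclass
class CohortDesign:
    """Full specification of a synthetic cohort."""

    n_per_group: dict[str, int]
    cells_per_sample: int
    panel: str
    cluster_profiles: list[ClusterProfile]
    base_weights: dict[str, float] | None = None
    #: group -> cluster -> log-fold shift of the mixture weight
    frequency_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    #: group -> cluster -> marker -> additive shift (arcsinh scale)
    marker_effects: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    clinical_model: dict = field(default_factory=lambda: DEFAULT_CLINICAL_MODEL)
    stenosis_model: dict = field(default_factory=lambda: DEFAULT_STENOSIS_MODEL)
    dirichlet_concentration: float = 200.0
    cofactor: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n <= 0:
                raise ValueError(f"group count must be positive, got {g}={n}")
        if self.cells_per_sample <= 0:
            raise ValueError("cells_per_sample must be positive")
        markers = set(get_panel(self.panel).markers)
        for p in self.cluster_profiles:
            missing = markers - set(p.location) | markers - set(p.scale)
            if missing:
                raise ValueError(
                    f"cluster {p.cluster_id} missing profile for {sorted(missing)}"
                )
        if self.base_weights is not None:
            ids = {p.cluster_id for p in self.cluster_profiles}
            if set(self.base_weights) != ids:
                raise ValueError("base_weights keys must match cluster ids")
            if not np.isclose(sum(self.base_weights.values()), 1.0):
                raise ValueError("base_weights must sum to 1")

    @property
    def cluster_ids(self) -> list[str]:
        return [p.cluster_id for p in self.cluster_profiles]

    def group_weights(self, group: str) -> np.ndarray:
        """Group-level mixture weights: base weights under log-fold shifts."""
        ids = self.cluster_ids
        if self.base_weights is None:
            w = np.full(len(ids), 1.0 / len(ids))
        else:
            w = np.array([self.base_weights[c] for c in ids])
        shifts = self.frequency_effects.get(group, {})
        w = w * np.exp([shifts.get(c, 0.0) for c in ids])
        return w / w.sum()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["cluster_profiles"] = [ClusterProfile(**p) for p in raw["cluster_profiles"]]
        return cls(**raw)


@dataclass
class ArtifactFlags:
    doublet: np.ndarray
    dead: np.ndarray


@dataclass
class SyntheticTruth:
    """Ground truth recorded during generation."""

    cell_labels: dict[str, np.ndarray]            # sample -> per-event cluster id
    sample_weights: dict[str, dict[str, float]]   # sample -> cluster -> weight
    informative_features: list[str]
    artifact_flags: dict[str, ArtifactFlags] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cell_labels": {s: v.tolist() for s, v in self.cell_labels.items()},
            "sample_weights": self.sample_weights,
            "informative_features": self.informative_features,
            "artifact_flags": {
                s: {"doublet": f.doublet.tolist(), "dead": f.dead.tolist()}
                for s, f in self.artifact_flags.items()
            },
        }
        Path(path).write_text(json.dumps(payload))


def _sample_ids(design: CohortDesign) -> list[tuple[str, str]]:
    out = []
    for g in GROUPS:
        for i in range(design.n_per_group.get(g, 0)):
            out.append((g, f"{g}{i + 1:02d}"))
    return out


def generate_cohort(
    design: CohortDesign,
) -> tuple[list[CellEventMatrix], pd.DataFrame, SyntheticTruth]:
    """Generate one event matrix per sample plus clinical table and truth.

    Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    panel = get_panel(design.panel)
    markers = list(panel.markers)
    ids = design.cluster_ids
    K, M = len(ids), len(markers)

    loc = np.array([[p.location[m] for m in markers] for p in design.cluster_profiles])
    scale = np.array([[p.scale[m] for m in markers] for p in design.cluster_profiles])

    # per-group location matrices with additive marker effects
    group_loc = {}
    for g in GROUPS:
        L = loc.copy()
        for k, cid in enumerate(ids):
            for m, shift in design.marker_effects.get(g, {}).get(cid, {}).items():
                L[k, markers.index(m)] += shift
        group_loc[g] = L

    channels = panel.channels(structural=True)
    struct_names = list(STRUCTURAL_CHANNELS)
    samples: list[CellEventMatrix] = []
    cell_labels: dict[str, np.ndarray] = {}
    sample_weights: dict[str, dict[str, float]] = {}
    clinical_rows = []

    for group, sid in _sample_ids(design):
        w_group = design.group_weights(group)
        w = rng.dirichlet(design.dirichlet_concentration * w_group)
        n = design.cells_per_sample
        labels = rng.choice(K, size=n, p=w)

        transformed = rng.normal(group_loc[group][labels], scale[labels])
        raw = np.maximum(np.sinh(transformed) * design.cofactor, 0.0)

        struct = np.empty((n, len(struct_names)))
        struct[:, 0] = np.maximum(rng.normal(600.0, 60.0, n), 1.0)   # DNA1
        struct[:, 1] = np.maximum(rng.normal(450.0, 45.0, n), 1.0)   # DNA2
        struct[:, 2] = np.abs(rng.normal(2.0, 1.0, n))               # Cisplatin
        struct[:, 3] = np.maximum(rng.normal(25.0, 3.0, n), 5.0)     # Event_length
        struct[:, 4] = 0.0                                            # Bead
        struct[:, 5] = np.arange(n, dtype=float)                      # Time

        samples.append(
            CellEventMatrix(
                sample_id=sid,
                data=np.hstack([raw, struct]),
                channels=list(channels),
            )
        )
        cell_labels[sid] = np.array([ids[k] for k in labels])
        sample_weights[sid] = dict(zip(ids, w.tolist()))

        cm = design.clinical_model[group]
        row = {"sample_id": sid, "group": group}
        for var in ("age", "BMI", "TC", "TG", "HDL", "LDL"):
            mu, sd = cm[var]
            row[var] = rng.normal(mu, sd)
        for name, p in cm.get("comorbidities", {}).items():
            row[name] = int(rng.random() < p)
        clinical_rows.append(row)

    informative = sorted(
        {c for g in design.frequency_effects.values() for c, v in g.items() if v != 0}
    )
    truth = SyntheticTruth(
        cell_labels=cell_labels,
        sample_weights=sample_weights,
        informative_features=informative,
    )
    return samples, pd.DataFrame(clinical_rows), truth


# ---------------------------------------------------------------------------
# Artifact injection (fixtures for the gating stage)
# ---------------------------------------------------------------------------

def inject_artifacts(
    events: CellEventMatrix,
    doublet_rate: float,
    dead_rate: float,
    seed: int = 0,
    dead_viability: float = 80.0,
) -> tuple[CellEventMatrix, ArtifactFlags]:
    """Flag round(rate * n) events as doublets / dead cells and distort them.

    Doublets get doubled DNA intensity and doubled event length; dead cells
    get a high cisplatin signal.  Flag sets are disjoint.  Truth flags are
    returned alongside the modified matrix.
    """
    for r in (doublet_rate, dead_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {r}")
    out = events.copy()
    n = out.n_events
    rng = np.random.default_rng(seed)

    n_doublet = round(doublet_rate * n)
    n_dead = round(dead_rate * n)
    perm = rng.permutation(n)
    doublet_idx = perm[:n_doublet]
    dead_idx = perm[n_doublet:n_doublet + n_dead]

    dna_cols = out.indices_with_role("dna")
    len_cols = out.indices_with_role("event_length")
    via_cols = out.indices_with_role("viability")
    if n_doublet:
        out.data[np.ix_(doublet_idx, dna_cols)] *= 2.0
        out.data[np.ix_(doublet_idx, len_cols)] *= 2.0
    if n_dead:
        out.data[np.ix_(dead_idx, via_cols)] = np.abs(
            rng.normal(dead_viability, 5.0, size=(n_dead, len(via_cols)))
        )

    flags = ArtifactFlags(
        doublet=np.isin(np.arange(n), doublet_idx),
        dead=np.isin(np.arange(n), dead_idx),
    )
    return out, flags


def simulate_sensitivity_drift(
    events: CellEventMatrix, total_decay: float
) -> CellEventMatrix:
    """Linear sensitivity decay over acquisition time.

    Marker, DNA and bead channels are multiplied by a factor falling
    linearly from 1 at the first event to ``1 - total_decay`` at the last.
    """
    if not 0.0 <= total_decay < 1.0:
        raise ValueError("total_decay must be in [0, 1)")
    out = events.copy()
    t = out.channel("Time")
    span = t.max() - t.min()
    frac = (t - t.min()) / span if span > 0 else np.zeros_like(t)
    factor = 1.0 - total_decay * frac
    cols = out.indices_with_role("lineage", "functional", "dna", "bead")
    out.data[:, cols] *= factor[:, None]
    return out


def inject_beads(
    events: CellEventMatrix,
    n_beads: int,
    bead_intensities: dict[str, float],
    bead_signal: float = 1000.0,
    seed: int = 0,
) -> CellEventMatrix:
    """Append calibration-bead events spread uniformly over acquisition time.

    Beads carry ``bead_signal`` on the bead channel and the given reference
    intensities on the listed channels; all other channels are zero.
    """
    out = events.copy()
    rng = np.random.default_rng(seed)
    rows = np.zeros((n_beads, out.data.shape[1]))
    rows[:, out.indices_with_role("bead")] = bead_signal
    for name, value in bead_intensities.items():
        rows[:, out.index(name)] = value
    t = out.channel("Time")
    time_col = out.index("Time")
    t_lo, t_hi = (t.min(), t.max()) if len(t) else (0.0, 1.0)
    rows[:, time_col] = rng.uniform(t_lo, t_hi, n_beads)
    data = np.vstack([out.data, rows])
    order = np.argsort(data[:, time_col], kind="stable")
    out.data = data[order]
    return out


# ---------------------------------------------------------------------------
# Stenosis profiles (fixtures for Gensini scoring)
# ---------------------------------------------------------------------------

def generate_stenosis_profiles(design: CohortDesign):
    """Per-sample stenosis profiles respecting the group definitions.

    NC samples have no stenosis anywhere; CAS lesions stay below 50%;
    ASCVD lesions lie in [50%, 99%].
    """
    from .gensini import SEGMENT_WEIGHTS, SegmentStenosisProfile

    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 911]))
    segments = list(SEGMENT_WEIGHTS)
    profiles = []
    for group, sid in _sample_ids(design):
        if group == "NC":
            profiles.append(SegmentStenosisProfile(patient_id=sid, stenoses={}))
            continue
        model = design.stenosis_model[group]
        lo_k, hi_k = model["segments"]
        lo_s, hi_s = model["stenosis"]
        k = int(rng.integers(lo_k, hi_k + 1))
        chosen = rng.choice(segments, size=k, replace=False)
        stenoses = {seg: float(rng.uniform(lo_s, hi_s)) for seg in chosen}
        profiles.append(SegmentStenosisProfile(patient_id=sid, stenoses=stenoses))
    return profiles


# ---------------------------------------------------------------------------
# Default event-level designs
# ---------------------------------------------------------------------------

_NEG, _DIM, _POS, _HI = 0.3, 1.5, 3.0, 4.2

# marker signatures of the default myeloid clusters: marker -> level
_MYELOID_SIGNATURES: dict[str, tuple[str, dict[str, float]]] = {
    "M01": ("mDC", {"CD33": _POS, "HLA-DR": _HI, "CD11c": _POS, "CD123": _POS}),
    "M02": ("M-MDSC", {"CD14": _POS, "CD33": _HI, "CD11b": _POS, "HLA-DR": _NEG, "CXCR4": _POS}),
    "M03": ("ncMon", {"CD16": _POS, "CD14": _NEG, "CD33": _POS, "CX3CR1": _HI, "HLA-DR": _POS, "CD68": _POS}),
    "M04": ("iMon", {"CD14": _POS, "CD16": _POS, "HLA-DR": _POS, "CCR2": _DIM, "CD36": _DIM}),
    "M05": ("ncMon", {"CD16": _POS, "CD14": _NEG, "CD33": _POS, "CX3CR1": _HI, "HLA-DR": _POS, "CD32": _POS}),
    "M06": ("mDC", {"CD33": _POS, "HLA-DR": _HI, "CD11c": _POS, "FceRIa": _POS}),
    "M07": ("cMon", {"CD14": _POS, "CCR2": _POS, "CD54": _NEG, "CD36": _DIM}),
    "M08": ("cMon", {"CD14": _POS, "CCR2": _POS, "CD11b": _POS, "CD36": _POS, "CD54": _POS}),
    "M09": ("cMon", {"CD14": _POS, "CCR2": _POS, "CD11b": _POS, "CD64": _POS}),
    "M10": ("cMon", {"CD14": _POS, "CCR2": _POS, "CX3CR1": _POS, "CD68": _POS}),
    "M11": ("cMon", {"CD14": _POS, "CCR2": _POS, "CD36": _POS, "CD32": _POS}),
    "M12": ("cMon", {"CD14": _POS, "CCR2": _POS, "CXCR4": _POS, "CD36L1": _POS}),
    "M13": ("cMon", {"CD14": _POS, "CCR2": _POS, "HLA-DR": _HI, "CD11c": _DIM}),
    "M14": ("cMon", {"CD14": _POS, "CCR2": _POS, "CD11b": _HI, "CX3CR1": _DIM}),
    "M15": ("cMon", {"CD14": _POS, "CCR2": _POS, "CD169": _POS, "CD64": _DIM}),
}

_T_SIGNATURES: dict[str, tuple[str, dict[str, float]]] = {
    "T01": ("CD4 T", {"CD3": _POS, "CD4": _POS, "GranzymeB": _POS, "T-bet": _POS}),
    "T02": ("CD4 T", {"CD3": _POS, "CD4": _POS, "CD45RA": _POS, "CCR7": _POS}),
    "T03": ("CD4 T", {"CD3": _POS, "CD4": _POS, "CCR7": _POS, "CD27": _POS}),
    "T05": ("CD4 T", {"CD3": _POS, "CD4": _POS, "CD25": _POS, "FoxP3": _POS}),
    "T13": ("CD4 T", {"CD3": _POS, "CD4": _POS, "CD161": _POS}),
    "T14": ("DNT", {"CD3": _POS, "CD11b": _DIM}),
    "T15": ("gdT", {"CD3": _POS, "TCRgd": _POS}),
    "T17": ("gdT", {"CD3": _POS, "TCRgd": _POS, "GranzymeB": _POS}),
    "T20": ("CD8 T", {"CD3": _POS, "CD8": _POS, "CD45RA": _POS, "CCR7": _POS}),
    "T23": ("CD8 T", {"CD3": _POS, "CD8": _POS, "GranzymeB": _POS, "PD-1": _DIM}),
    "B01": ("B", {"CD19": _POS, "CD38": _POS, "HLA-DR": _POS}),
    "B02": ("B", {"CD19": _POS, "CD27": _POS, "HLA-DR": _POS}),
    "NK01": ("NK", {"CD56": _POS, "CD38": _HI}),
    "NK02": ("NK", {"CD56": _POS, "GranzymeB": _HI, "CD45RA": _HI}),
    "NK03": ("NK", {"CD56": _POS, "CD11c": _DIM, "T-bet": _DIM}),
    "NK04": ("NK", {"CD56": _POS, "CD11b": _POS, "T-bet": _POS}),
}


def make_profiles(
    panel: MarkerPanel,
    signatures: dict[str, tuple[str, dict[str, float]]],
    baseline: float = _NEG,
    dispersion: float = 0.35,
) -> list[ClusterProfile]:
    """Build cluster profiles from marker signatures.

    All clusters are CD45-positive; unmentioned markers sit at baseline.
    """
    profiles = []
    for cid, (lineage, sig) in signatures.items():
        loc = {m: baseline for m in panel.markers}
        loc["CD45"] = _HI
        loc.update({m: v for m, v in sig.items() if m in loc})
        profiles.append(
            ClusterProfile(
                cluster_id=cid,
                lineage=lineage,
                location=loc,
                scale={m: dispersion for m in panel.markers},
            )
        )
    return profiles


def default_design(
    panel: str = "myeloid",
    n_per_group: dict[str, int] | None = None,
    cells_per_sample: int = 2000,
    seed: int = 0,
    frequency_effects: dict[str, dict[str, float]] | None = None,
    dispersion: float = 0.35,
) -> CohortDesign:
    """Desk-scale default cohort design for either panel."""
    p = get_panel(panel)
    signatures = _MYELOID_SIGNATURES if panel == "myeloid" else _T_SIGNATURES
    if frequency_effects is None:
        # group-dependent shifts mirroring the qualitative cohort structure
        frequency_effects = {
            "CAS": {"M02": 0.8, "M04": 0.4} if panel == "myeloid" else {"T23": 0.4},
            "ASCVD": {"M15": 0.8, "M03": -0.6} if panel == "myeloid" else {"T01": 0.5},
        }
    return CohortDesign(
        n_per_group=dict(n_per_group or DEFAULT_N_PER_GROUP),
        cells_per_sample=cells_per_sample,
        panel=panel,
        cluster_profiles=make_profiles(p, signatures, dispersion=dispersion),
        frequency_effects=frequency_effects,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Feature-level cohort (direct fixtures for the model layer)
# ---------------------------------------------------------------------------

@dataclass
class FeatureCohortTruth:
    informative_immune: list[str]
    informative_clinical: list[str]


def generate_feature_cohort(
    n_per_class: tuple[int, int] = (22, 23),
    n_immune: int = 30,
    n_informative_immune: int = 4,
    n_clinical: int = 6,
    n_informative_clinical: int = 2,
    immune_effect: float = 1.2,
    clinical_effect: float = 1.2,
    concentration: float = 150.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, FeatureCohortTruth]:
    """Sample-level feature table with planted class signal.

    Immune features are compositional cluster frequencies drawn from a
    Dirichlet whose centre is shifted (log-fold ``immune_effect``) for the
    positive class on the informative clusters.  Clinical features are
    Gaussian with the informative ones shifted by ``clinical_effect`` SDs.
    """
    rng = np.random.default_rng(seed)
    n0, n1 = n_per_class
    labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])

    immune_names = [f"C{i + 1:02d}" for i in range(n_immune)]
    base = rng.dirichlet(np.full(n_immune, 5.0))
    informative_idx = rng.choice(n_immune, size=n_informative_immune, replace=False)
    shifted = base * np.exp(
        immune_effect * np.isin(np.arange(n_immune), informative_idx)
    )
    shifted /= shifted.sum()
    freq = np.vstack([
        rng.dirichlet(concentration * (shifted if y else base)) for y in labels
    ])
    immune = pd.DataFrame(freq, columns=immune_names)

    clinical_names = ["age", "BMI", "TC", "TG", "HDL", "LDL"][:n_clinical]
    clin = rng.normal(size=(n0 + n1, n_clinical))
    informative_clin = rng.choice(n_clinical, size=n_informative_clinical, replace=False)
    clin[np.ix_(labels == 1, informative_clin)] += clinical_effect
    clinical = pd.DataFrame(clin, columns=clinical_names)

    truth = FeatureCohortTruth(
        informative_immune=[immune_names[i] for i in sorted(informative_idx)],
        informative_clinical=[clinical_names[i] for i in sorted(informative_clin)],
    )
    return immune, clinical, labels, truth
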