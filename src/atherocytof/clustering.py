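"""Graph-based clustering, lineage annotation, embedding, frequency tables.

Events (pooled across samples, arcsinh scale) are clustered by kNN-graph
community detection: exact k-nearest-neighbour graph, optional weak-edge
pruning, Leiden modularity partition, and merging of communities below a
minimum size — the algorithmic skeleton of PARC-style phenotyping.
Clusters are then annotated by ordered marker-predicate rules over their
median profiles, and per-sample relative frequency tables are built for the
statistics and model layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors


# ---------------------------------------------------------------------------
# kNN graph
# ---------------------------------------------------------------------------

def build_knn_graph(
    X: np.ndarray,
    k: int = 30,
    metric: str = "euclidean",
    mode: str = "union",
    prune_quantile: float = 0.0,
) -> ig.Graph:
    """Exact kNN graph with similarity edge weights.

    Parameters
    ----------
    mode
        "union": edge if either point lists the other among its k nearest;
        "mutual": edge only if both do.
    prune_quantile
        Drop this fraction of the weakest (lowest-similarity) edges.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported metric {metric!r}")

    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric)
    nn.fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    pairs: dict[tuple[int, int], float] = {}
    directed: set[tuple[int, int]] = set()
    for i in range(n):
        for j, d in zip(idx[i], dist[i]):
            directed.add((i, int(j)))
            key = (i, int(j)) if i < j else (int(j), i)
            pairs.setdefault(key, float(d))
    if mode == "mutual":
        pairs = {
            (a, b): d for (a, b), d in pairs.items()
            if (a, b) in directed and (b, a) in directed
        }
    elif mode != "union":
        raise ValueError(f"unknown mode {mode!r}")

    edges = list(pairs)
    weights = [1.0 / (1.0 + d) for d in pairs.values()]
    if prune_quantile > 0 and edges:
        cut = np.quantile(weights, prune_quantile)
        kept = [(e, w) for e, w in zip(edges, weights) if w > cut]
        if kept:  # never prune to an empty graph
            edges, weights = map(list, zip(*kept))

    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


# ---------------------------------------------------------------------------
# Community clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Partition of pooled events into clusters."""

    labels: np.ndarray                      # per-event integer cluster label
    sizes: pd.Series = field(default=None)  # cluster -> size
    medians: pd.DataFrame | None = None     # cluster x marker median profile
    lineages: dict[int, str] | None = None  # cluster -> lineage label

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.sizes is None:
            self.sizes = pd.Series(self.labels).value_counts().sort_index()
        if int(self.sizes.sum()) != len(self.labels):
            raise ValueError("cluster sizes must sum to event count")

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def with_medians(self, X: np.ndarray, marker_names: list[str]) -> "ClusterAssignment":
        med = pd.DataFrame(
            [np.median(X[self.labels == c], axis=0) for c in self.sizes.index],
            index=self.sizes.index,
            columns=marker_names,
        )
        return replace(self, medians=med)


def community_cluster(
    graph: ig.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    min_size_frac: float = 0.001,
) -> ClusterAssignment:
    """Leiden modularity partition with small-community merging.

    Communities smaller than ``min_size_frac`` of all events are absorbed
    into the neighbouring community they connect to most strongly.  Labels
    are renumbered 0..K-1 by descending size.
    """
    n = graph.vcount()
    if n == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=graph.es["weight"] if graph.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.array(part.membership)

    min_size = max(1, int(np.ceil(min_size_frac * n)))
    adj = graph.get_adjlist()
    weights_of = [
        dict(zip(adj[v], graph.es[graph.incident(v)]["weight"])) if adj[v] else {}
        for v in range(n)
    ] if graph.ecount() else [{} for _ in range(n)]

    for _ in range(len(set(labels))):  # at most K merge passes
        counts = pd.Series(labels).value_counts()
        small = counts[counts < min_size]
        if small.empty or len(counts) == 1:
            break
        c = small.index[0]
        members = np.where(labels == c)[0]
        conn: dict[int, float] = {}
        for v in members:
            for u, w in weights_of[v].items():
                if labels[u] != c:
                    conn[labels[u]] = conn.get(labels[u], 0.0) + w
        if not conn:
            # disconnected small component: merge into the largest cluster
            target = counts.index[0] if counts.index[0] != c else counts.index[1]
        else:
            target = max(conn, key=conn.get)
        labels[members] = target

    # relabel by descending size, ties broken by old label for determinism
    counts = pd.Series(labels).value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in labels])
    return ClusterAssignment(labels=labels)


def cluster_events(
    X: np.ndarray,
    marker_names: list[str],
    k: int = 30,
    metric: str = "euclidean",
    resolution: float = 1.0,
    seed: int = 0,
    min_size_frac: float = 0.001,
    prune_quantile: float = 0.0,
) -> ClusterAssignment:
    """Convenience wrapper: graph -> partition -> median profiles."""
    graph = build_knn_graph(X, k=k, metric=metric, prune_quantile=prune_quantile)
    assignment = community_cluster(
        graph, resolution=resolution, seed=seed, min_size_frac=min_size_frac
    )
    return assignment.with_medians(X, marker_names)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

Predicate = "callable[[pd.Series, dict[str, float]], bool]"


def _pos(profile: pd.Series, thr: dict[str, float], marker: str) -> bool:
    if marker not in profile.index:
        raise KeyError(f"annotation rule needs marker {marker!r}, not in panel")
    return bool(profile[marker] > thr[marker])


@dataclass
class AnnotationRules:
    """Ordered (label, predicate) rules over cluster median profiles.

    The first matching rule wins; clusters matching nothing are labelled
    "unassigned".  ``thresholds`` holds per-marker positivity cut-offs on
    the arcsinh scale.
    """

    major: list[tuple[str, object]]
    thresholds: dict[str, float]

    @classmethod
    def default(cls, thresholds: dict[str, float]) -> "AnnotationRules":
        """Canonical lineage rules over the shared identity markers."""
        P = _pos
        major = [
            ("granulocyte", lambda p, t: P(p, t, "CD66b") and not P(p, t, "CD3")),
            ("T", lambda p, t: P(p, t, "CD3")),
            ("B", lambda p, t: P(p, t, "CD19")),
            ("NK", lambda p, t: P(p, t, "CD56")),
            ("myeloid", lambda p, t: P(p, t, "CD33") or P(p, t, "CD14")),
        ]
        return cls(major=major, thresholds=thresholds)

    def major_label(self, profile: pd.Series) -> str:
        for label, pred in self.major:
            if pred(profile, self.thresholds):
                return label
        return "unassigned"

    def refine(self, profile: pd.Series, major: str) -> str:
        """Subset labels within T cells and monocytes."""
        t = self.thresholds
        if major == "T":
            if "TCRgd" in profile.index and _pos(profile, t, "TCRgd"):
                return "gdT"
            cd4 = _pos(profile, t, "CD4")
            cd8 = _pos(profile, t, "CD8")
            if cd4 and not cd8:
                return "CD4 T"
            if cd8 and not cd4:
                return "CD8 T"
            if not cd4 and not cd8:
                return "DNT"
            return "T"
        if major == "myeloid":
            cd14 = _pos(profile, t, "CD14")
            cd16 = _pos(profile, t, "CD16")
            if cd14 and not cd16:
                return "cMon"
            if cd14 and cd16:
                return "iMon"
            if not cd14 and cd16:
                return "ncMon"
            return "myeloid"
        return major


def bimodal_thresholds(
    X: np.ndarray,
    marker_names: list[str],
    seed: int = 0,
    min_separation: float = 1.0,
) -> dict[str, float]:
    """Per-marker positivity cut-off: midpoint of a 2-component 1-D fit.

    Automates the manual positive/negative gate.  Markers whose two fitted
    components sit closer than ``min_separation`` arcsinh units (or than
    twice the pooled component SD) are treated as lacking a positive mode —
    zero-truncated negative noise is pseudo-bimodal — and get a
    conservative cut-off above the bulk (mean + 2 SD).
    """
    thresholds = {}
    for j, m in enumerate(marker_names):
        x = X[:, j].reshape(-1, 1)
        if np.ptp(x) == 0:
            thresholds[m] = float(x[0, 0])
            continue
        gm = GaussianMixture(n_components=2, random_state=seed, n_init=2).fit(x)
        mu = np.sort(gm.means_.ravel())
        pooled_sd = float(np.sqrt(gm.covariances_.ravel().mean()))
        if (mu[1] - mu[0]) < max(2.0 * pooled_sd, min_separation):
            thresholds[m] = float(x.mean() + 2.0 * x.std())
        else:
            thresholds[m] = float(mu.mean())
    return thresholds


def annotate(
    assignment: ClusterAssignment, rules: AnnotationRules, refine: bool = True
) -> ClusterAssignment:
    """Attach a lineage label to every cluster (total: none left unlabelled)."""
    if assignment.medians is None:
        raise ValueError("assignment needs median profiles; call with_medians first")
    lineages = {}
    for c in assignment.sizes.index:
        profile = assignment.medians.loc[c]
        major = rules.major_label(profile)
        lineages[int(c)] = (
            rules.refine(profile, major) if refine and major != "unassigned" else major
        )
    return replace(assignment, lineages=lineages)


# ---------------------------------------------------------------------------
# Embedding (visualization only)
# ---------------------------------------------------------------------------

def embed_tsne(X: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE of events; reproducible given seed."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 4 * perplexity:
        raise ValueError(
            f"need at least {int(4 * perplexity)} events for perplexity {perplexity}"
        )
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    return tsne.fit_transform(X)


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Samples x features matrix of relative frequencies.

    ``denominator`` declares what each feature is a fraction of ("total"
    for all retained CD45+ events).  Rows over one partition sum to 1.
    """

    frame: pd.DataFrame
    denominator: str = "total"


def frequency_table(
    per_sample_labels: dict[str, np.ndarray],
    label_space: list | None = None,
    denominator: str = "total",
    prefix: str = "",
) -> FrequencyTable:
    """Relative label frequencies per sample over a shared label space.

    Labels absent from a sample get frequency 0; a sample with zero events
    gets missing values and a warning.
    """
    if label_space is None:
        label_space = sorted(
            {l for v in per_sample_labels.values() for l in np.asarray(v).tolist()}
        )
    rows = {}
    for sid, labels in per_sample_labels.items():
        labels = np.asarray(labels)
        if labels.size == 0:
            warnings.warn(f"sample {sid!r} has zero events in denominator")
            rows[sid] = pd.Series(np.nan, index=label_space)
            continue
        counts = pd.Series(labels).value_counts()
        rows[sid] = counts.reindex(label_space, fill_value=0) / labels.size
    frame = pd.DataFrame(rows).T
    frame.index.name = "sample_id"
    if prefix:
        frame.columns = [f"{prefix}{c}" for c in frame.columns]
    else:
        frame.columns = [str(c) for c in frame.columns]
    return FrequencyTable(frame=frame, denominator=denominator)


def split_pooled_labels(
    pooled_labels: np.ndarray, sample_ids: np.ndarray
) -> dict[str, np.ndarray]:
    """Recover per-sample label vectors after pooled clustering."""
    pooled_labels = np.asarray(pooled_labels)
    sample_ids = np.asarray(sample_ids)
    if pooled_labels.shape[0] != sample_ids.shape[0]:
        raise ValueError("labels and sample ids must align")
    return {
        sid: pooled_labels[sample_ids == sid] for sid in pd.unique(sample_ids)
    }
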