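"""Risk-model layer: bootstrap class balancing, repeated random-forest
stability feature selection, 70/30 split with 10-fold CV ensemble training,
and evaluation by ROC, decision-curve net benefit, and cutoff analysis.

Two tasks are supported: a disease model (controls vs pooled patients,
with the small control class boosted by bootstrap resampling) and a
progression model (low- vs high-severity patients, balanced by plain
subsampling).  Feature selection repeats a balanced draw, per-draw z-score
normalization, and a 10-fold cross-validated random forest many times,
counting how often each feature's average impurity importance exceeds a
threshold; features exceeding the count criterion are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

CLINICAL_FEATURES = ("age", "BMI", "TC", "TG", "HDL", "LDL")


@dataclass(frozen=True)
class FeatureSet:
    """Named feature collection: immune, clinical, or their union."""

    kind: str  # immune | clinical | combined
    names: tuple[str, ...]

    @classmethod
    def combined(cls, immune: "FeatureSet", clinical: "FeatureSet") -> "FeatureSet":
        return cls(kind="combined", names=immune.names + clinical.names)


# ---------------------------------------------------------------------------
# Class balancing
# ---------------------------------------------------------------------------

@dataclass
class BalancedDataset:
    X: pd.DataFrame
    y: np.ndarray
    provenance: pd.DataFrame  # original_index, label, resampled (bool)
    seed: int


def balance_groups(
    X: pd.DataFrame,
    y: np.ndarray,
    target_n_per_class: int,
    seed: int = 0,
) -> BalancedDataset:
    """Equalize class sizes at ``target_n_per_class``.

    Classes at or above the target are subsampled without replacement;
    smaller classes are bootstrap-resampled with replacement.  Every output
    row traces back to an original row via the provenance map.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, got {classes}")
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    resampled_flags: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) == 0:
            raise ValueError(f"class {c} is empty")
        if len(idx) >= target_n_per_class:
            pick = rng.choice(idx, size=target_n_per_class, replace=False)
            resampled_flags.append(np.zeros(target_n_per_class, dtype=bool))
        else:
            pick = rng.choice(idx, size=target_n_per_class, replace=True)
            resampled_flags.append(np.ones(target_n_per_class, dtype=bool))
        chosen.append(pick)
    order = np.concatenate(chosen)
    flags = np.concatenate(resampled_flags)
    prov = pd.DataFrame(
        {
            "original_index": np.asarray(X.index)[order],
            "label": y[order],
            "resampled": flags,
        }
    )
    return BalancedDataset(
        X=X.iloc[order].reset_index(drop=True),
        y=y[order],
        provenance=prov,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Stability feature selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityParams:
    """Parameters of the repeated-forest stability selection."""

    n_repeats: int = 1000
    importance_threshold: float = 0.04
    count_threshold: int | None = None  # default: n_repeats // 2
    n_per_class: int = 25
    n_folds: int = 10
    n_estimators: int = 100
    max_features: str | float = "sqrt"

    def resolved_count_threshold(self) -> int:
        return self.count_threshold if self.count_threshold is not None else self.n_repeats // 2


@dataclass
class StabilitySelectionResult:
    counts: pd.Series            # feature -> repeats with importance > threshold
    mean_importance: pd.Series   # feature -> mean importance over repeats
    selected: list[str]
    params: StabilityParams


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _forest_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    max_features,
    rng: np.random.Generator,
) -> np.ndarray:
    """Impurity importance of a random forest, averaged over its trees.

    Grows the bootstrap trees directly (identical to what
    ``RandomForestClassifier.feature_importances_`` averages) to avoid the
    estimator-wrapper overhead that dominates at these tiny sample sizes —
    the stability selection fits tens of thousands of forests.
    """
    n = len(y)
    imps = np.zeros(X.shape[1])
    for _ in range(n_trees):
        idx = rng.integers(0, n, n)  # bootstrap sample, as in bagging
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[idx], y[idx])
        imps += tree.feature_importances_
    return imps / n_trees


def _cv_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int,
    n_estimators: int,
    max_features,
    rng: np.random.Generator,
) -> np.ndarray:
    """Average impurity importance over the fold-forests of a k-fold CV."""
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    imps = np.zeros(X.shape[1])
    for train_idx, _ in skf.split(X, y):
        imps += _forest_importance(
            X[train_idx], y[train_idx], n_estimators, max_features, rng
        )
    return imps / n_folds


def stability_select(
    X: pd.DataFrame,
    y: np.ndarray,
    params: StabilityParams | None = None,
    seed: int = 0,
) -> StabilitySelectionResult:
    """Repeated balanced-resample random-forest feature selection.

    Each repeat draws a fresh balanced subsample (bootstrap for the smaller
    class), z-scores features within the subsample, fits a 10-fold
    cross-validated random forest, and records the average impurity
    importance per feature.  A feature scores 1 in a repeat when that
    importance exceeds the threshold; features scoring in more than half
    the repeats (by default) are selected.
    """
    params = params or StabilityParams()
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    features = list(X.columns)
    counts = np.zeros(len(features), dtype=int)
    importance_sum = np.zeros(len(features))

    for _ in range(params.n_repeats):
        bal = balance_groups(
            X, y, params.n_per_class, seed=int(rng.integers(2**31 - 1))
        )
        Xb = _zscore(bal.X.to_numpy(dtype=float))
        imp = _cv_importance(
            Xb,
            bal.y,
            params.n_folds,
            params.n_estimators,
            params.max_features,
            rng,
        )
        counts += imp > params.importance_threshold
        importance_sum += imp

    thr = params.resolved_count_threshold()
    counts_s = pd.Series(counts, index=features, name="count")
    mean_imp = pd.Series(importance_sum / params.n_repeats, index=features)
    return StabilitySelectionResult(
        counts=counts_s,
        mean_importance=mean_imp,
        selected=[f for f in features if counts_s[f] > thr],
        params=params,
    )


# ---------------------------------------------------------------------------
# Ensemble training
# ---------------------------------------------------------------------------

@dataclass
class TrainedEnsemble:
    """Fold-models of a 10-fold CV; prediction = mean fold probability."""

    models: list[RandomForestClassifier]
    feature_names: list[str]
    seed: int
    X_test: pd.DataFrame | None = None
    y_test: np.ndarray | None = None

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        arr = X[self.feature_names].to_numpy(dtype=float)
        probs = np.mean([m.predict_proba(arr)[:, 1] for m in self.models], axis=0)
        return probs


def train_ensemble(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    test_size: float = 0.3,
    balance_train_to: int | None = None,
    n_folds: int = 10,
    n_estimators: int = 500,
    max_features: str | float = "sqrt",
) -> TrainedEnsemble:
    """70/30 stratified split, optional bootstrap balancing of the training
    set, then one random forest per CV fold; the ensemble prediction is the
    mean predicted probability over the fold-models."""
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    X_train, X_test, y_train, y_test = train_test_split(
        X,
        y,
        test_size=test_size,
        stratify=y,
        random_state=int(rng.integers(2**31 - 1)),
    )
    if balance_train_to is not None:
        bal = balance_groups(
            X_train, y_train, balance_train_to, seed=int(rng.integers(2**31 - 1))
        )
        X_train, y_train = bal.X, bal.y

    _, counts = np.unique(y_train, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest training class ({counts.min()}) cannot fill {n_folds} "
            "stratified folds"
        )
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    arr = X_train.to_numpy(dtype=float)
    models = []
    for fold_train, _ in skf.split(arr, y_train):
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features=max_features,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(arr[fold_train], y_train[fold_train])
        models.append(rf)
    return TrainedEnsemble(
        models=models,
        feature_names=list(X.columns),
        seed=seed,
        X_test=X_test,
        y_test=y_test,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def roc_points(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve and trapezoidal AUC.

    The trapezoidal integral equals the pairwise concordance estimator
    (ties counted 1/2).  Raises if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("ROC needs both classes")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}), auc


def decision_curve(
    scores,
    labels,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Net benefit of the model vs treat-all and treat-none strategies.

    net_benefit(pt) = TP/N - (FP/N) * pt / (1 - pt), with the model calling
    positive at score >= pt.  treat_none is identically 0; treat_all is
    prevalence - (1 - prevalence) * pt / (1 - pt).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie strictly in (0, 1)")
    n = len(labels)
    prevalence = labels.mean()
    rows = []
    for pt in thresholds:
        called = scores >= pt
        tp = int((called & (labels == 1)).sum())
        fp = int((called & (labels == 0)).sum())
        odds = pt / (1 - pt)
        rows.append(
            {
                "threshold": pt,
                "net_benefit": tp / n - (fp / n) * odds,
                "treat_all": prevalence - (1 - prevalence) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def cutoff_analysis(
    scores, labels, cutoffs: np.ndarray | None = None
) -> tuple[pd.DataFrame, float]:
    """Sensitivity/specificity per cutoff; best cutoff maximizes Youden's J."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if cutoffs is None:
        cutoffs = np.round(np.linspace(0.1, 0.9, 9), 10)
    rows = []
    for c in np.asarray(cutoffs, dtype=float):
        called = scores >= c
        pos = labels == 1
        sens = (called & pos).sum() / max(pos.sum(), 1)
        spec = (~called & ~pos).sum() / max((~pos).sum(), 1)
        rows.append(
            {"cutoff": c, "sensitivity": sens, "specificity": spec,
             "youden_j": sens + spec - 1}
        )
    table = pd.DataFrame(rows)
    best = float(table.loc[table["youden_j"].idxmax(), "cutoff"])
    return table, best


@dataclass
class ModelEvaluation:
    roc: pd.DataFrame
    auc: float
    net_benefit: pd.DataFrame
    cutoffs: pd.DataFrame
    best_cutoff: float


def evaluate_ensemble(
    ensemble: TrainedEnsemble,
    X: pd.DataFrame | None = None,
    y: np.ndarray | None = None,
) -> ModelEvaluation:
    """Evaluate on the held-out test split (or explicit data)."""
    if X is None:
        X, y = ensemble.X_test, ensemble.y_test
    if X is None or y is None:
        raise ValueError("no evaluation data available")
    scores = ensemble.predict_proba(X)
    roc, auc = roc_points(scores, y)
    nb = decision_curve(scores, y)
    cut_table, best = cutoff_analysis(scores, y)
    return ModelEvaluation(
        roc=roc, auc=auc, net_benefit=nb, cutoffs=cut_table, best_cutoff=best
    )


# ---------------------------------------------------------------------------
# Task presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskPreset:
    """Balancing geometry of the two modelling tasks."""

    name: str
    selection_n_per_class: int
    train_balance_to: int | None


#: disease model: 13 controls vs 70 patients -> 25 + 25 per selection repeat,
#: training classes boosted to 50 each
DP = TaskPreset(name="dp", selection_n_per_class=25, train_balance_to=50)
#: progression model: 38 vs 32 patients -> 15 + 15 per selection repeat
DPP = TaskPreset(name="dpp", selection_n_per_class=15, train_balance_to=None)

TASKS = {"dp": DP, "dpp": DPP}
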