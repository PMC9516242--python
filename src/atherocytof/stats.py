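"""Cohort-level statistics.

Group comparisons of immune-feature tables (pairwise t-tests with
Benjamini-Hochberg adjustment), contingency and summary-statistic tests for
the demographic table, correlations with plaque burden and serum lipids,
and cross-feature correlation networks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: significance stars at the conventional adjusted-p thresholds
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p_adj: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p_adj < thr:
            return stars
    return ""


# ---------------------------------------------------------------------------
# Contingency and summary-statistic tests
# ---------------------------------------------------------------------------

def chisq_test(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    Returns (statistic, df, p).  df = (rows-1)(cols-1).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p)


@dataclass
class SummaryStatsRow:
    """Per-group mean, SD, n for one continuous variable."""

    means: list[float]
    sds: list[float]
    ns: list[int]

    def __post_init__(self) -> None:
        if not len(self.means) == len(self.sds) == len(self.ns):
            raise ValueError("means, sds, ns must have equal length")
        if any(sd < 0 for sd in self.sds):
            raise ValueError("SDs must be nonnegative")
        if any(n < 2 for n in self.ns):
            raise ValueError("each group needs n >= 2")


def anova_from_summary(row: SummaryStatsRow) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from group means, SDs, and ns.

    Between-group SS comes from the means, within-group SS from the SDs;
    the result is identical to raw-data ANOVA when the summaries are exact.
    Returns (F, df1, df2, p).
    """
    means = np.asarray(row.means, dtype=float)
    sds = np.asarray(row.sds, dtype=float)
    ns = np.asarray(row.ns, dtype=float)
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    grand = (ns * means).sum() / ns.sum()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df1 = len(means) - 1
    df2 = int(ns.sum()) - len(means)
    if ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
        return f, df1, df2, 0.0 if ss_between > 0 else 1.0
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), df1, df2, float(sps.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def group_compare(
    features: pd.DataFrame,
    groups: pd.Series,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise unpaired two-sided t-tests per feature with BH adjustment.

    BH is applied within one family per pair (all features of the table).
    Degenerate comparisons (zero variance in both groups) get p = 1 with a
    warning.  Returns a tidy frame: feature, pair, t, p, p_adj, stars.
    """
    groups = pd.Series(groups)
    if pairs is None:
        levels = list(pd.unique(groups))
        pairs = list(itertools.combinations(levels, 2))
    out = []
    for a, b in pairs:
        xa = features.loc[groups[groups == a].index]
        xb = features.loc[groups[groups == b].index]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"need >= 2 samples per group for pair ({a}, {b})")
        rows = []
        for feat in features.columns:
            va, vb = xa[feat].dropna(), xb[feat].dropna()
            if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
                warnings.warn(f"degenerate variance for {feat!r} in ({a}, {b})")
                rows.append((feat, np.nan, 1.0))
                continue
            t, p = sps.ttest_ind(va, vb)
            rows.append((feat, float(t), float(p)))
        df = pd.DataFrame(rows, columns=["feature", "t", "p"])
        df["pair"] = f"{a}_vs_{b}"
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        df["stars"] = df["p_adj"].map(significance_stars)
        out.append(df)
    return pd.concat(out, ignore_index=True)[
        ["feature", "pair", "t", "p", "p_adj", "stars"]
    ]


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    method: str
    r: float
    p: float
    n: int
    degenerate: bool = False


def correlate(
    x, y, method: str = "pearson", x_name: str = "x", y_name: str = "y"
) -> CorrelationResult:
    """Pearson or Spearman correlation with two-sided p (listwise deletion)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(x_name, y_name, method, np.nan, np.nan, n, True)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(x_name, y_name, method, float(r), float(p), n)


@dataclass
class CorrelationNetwork:
    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame          # True where p < alpha (off-diagonal)
    n_significant_pairs: int
    method: str
    alpha: float


def correlation_network(
    features: pd.DataFrame,
    method: str = "pearson",
    alpha: float = 0.05,
) -> CorrelationNetwork:
    """Full symmetric correlation matrix with an unadjusted significance mask.

    The diagonal is exactly 1 and excluded from the significant-pair count.
    """
    cols = list(features.columns)
    m = len(cols)
    r = np.eye(m)
    p = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        res = correlate(features[cols[i]], features[cols[j]], method=method)
        r[i, j] = r[j, i] = res.r
        p[i, j] = p[j, i] = res.p
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    mask = (p_df < alpha) & ~np.eye(m, dtype=bool)
    return CorrelationNetwork(
        r=r_df,
        p=p_df,
        mask=mask,
        n_significant_pairs=int(mask.to_numpy().sum() // 2),
        method=method,
        alpha=alpha,
    )
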