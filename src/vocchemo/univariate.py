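"""Univariate differential-expression screening of VOC features.

Per feature: a two-tailed t test (Student pooled-variance by default, Welch as
an option), the log2 fold change of class means (case over reference, so a
feature upregulated in cases plots right of zero on a volcano), and volcano
coordinates.  No multiple-testing adjustment is applied on the primary path —
raw p thresholds (0.05, 0.10) drive downstream feature subsets — but a
Benjamini-Hochberg column is available as a labeled opt-in.

Also provides the deterministic hierarchical heatmap ordering (per-feature
z-scores, agglomerative clustering of rows and columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .feature_table import BinaryComparison, FeatureMatrix

__all__ = [
    "ttest_two_tailed",
    "log2_fold_change",
    "univariate_table",
    "hierarchical_order",
    "HeatmapOrdering",
]


def ttest_two_tailed(x_ref, x_case, variant: str = "student"):
    """Two-tailed t test of ``x_case`` against ``x_ref``; returns ``(t, p)``.

    ``student`` pools variances (df = n0 + n1 - 2); ``welch`` uses the
    Welch-Satterthwaite df.  t > 0 means the case mean is larger.  Degenerate
    zero-variance input: equal means give (0, 1); unequal means give the
    (+-inf, 0) limit with a warning.
    """
    x_ref = np.asarray(x_ref, dtype=float)
    x_case = np.asarray(x_case, dtype=float)
    if x_ref.size < 2 or x_case.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(x_ref)) and np.all(np.isfinite(x_case))):
        raise ValueError("non-finite values in t-test input")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    if x_ref.var(ddof=1) == 0 and x_case.var(ddof=1) == 0:
        if x_ref.mean() == x_case.mean():
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means: p -> 0 limit")
        return float(np.sign(x_case.mean() - x_ref.mean()) * np.inf), 0.0
    res = stats.ttest_ind(x_case, x_ref, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def log2_fold_change(x_ref, x_case, epsilon: float | None = None):
    """log2(mean_case / mean_ref) of nonnegative normalized signals.

    If either mean is 0 and ``epsilon`` is given, *both* means are offset by
    ``epsilon`` before the ratio (the caller supplies half the smallest nonzero
    normalized value of the matrix).  If both means are 0 the fold change is
    undefined and NaN is returned — the caller flags and excludes the feature.
    """
    m_ref = float(np.mean(x_ref))
    m_case = float(np.mean(x_case))
    if m_ref < 0 or m_case < 0:
        raise ValueError("signals must be nonnegative")
    if m_ref == 0.0 and m_case == 0.0:
        return float("nan")
    if m_ref == 0.0 or m_case == 0.0:
        if epsilon is None or epsilon <= 0:
            return float("nan")
        m_ref += epsilon
        m_case += epsilon
    return float(np.log2(m_case / m_ref))


def _vectorized_ttests(X_ref, X_case, variant):
    """Row-wise t tests with explicit handling of zero-variance rows."""
    t, p = stats.ttest_ind(X_case, X_ref, axis=1, equal_var=(variant == "student"))
    v0 = X_ref.var(axis=1, ddof=1)
    v1 = X_case.var(axis=1, ddof=1)
    degen = (v0 == 0) & (v1 == 0)
    if degen.any():
        d_mean = X_case[degen].mean(axis=1) - X_ref[degen].mean(axis=1)
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        t[degen] = np.where(d_mean == 0, 0.0, np.sign(d_mean) * np.inf)
        p[degen] = np.where(d_mean == 0, 1.0, 0.0)
    return np.asarray(t, dtype=float), np.asarray(p, dtype=float)


def univariate_table(fm: FeatureMatrix, cmp: BinaryComparison,
                     variant: str = "student",
                     thresholds=(0.05, 0.10),
                     bh_column: bool = False):
    """Per-feature t statistic, p value and log2 fold change (volcano table).

    Returns ``(DataFrame, counts)`` where ``counts`` maps each threshold to the
    number of features with p below it.  Columns: feature_id, t_stat, p_value,
    log2_fc, mean_ref, mean_case, direction, neglog10_p, volcano_ok (False for
    the both-means-zero degenerate case) and optionally p_bh.
    """
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    y = cmp.y_for(fm.sample_ids)
    X_ref = fm.signals[:, y == 0]
    X_case = fm.signals[:, y == 1]
    if X_ref.shape[1] < 2 or X_case.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples")
    t, p = _vectorized_ttests(X_ref, X_case, variant)

    nonzero = fm.signals[fm.signals > 0]
    eps = 0.5 * nonzero.min() if nonzero.size else None
    m_ref = X_ref.mean(axis=1)
    m_case = X_case.mean(axis=1)
    lfc = np.array([
        log2_fold_change(X_ref[i], X_case[i], epsilon=eps)
        for i in range(fm.n_features)
    ])
    ok = ~np.isnan(lfc)
    with np.errstate(divide="ignore"):
        neglog10 = -np.log10(p)
    df = pd.DataFrame({
        "feature_id": fm.feature_ids,
        "t_stat": t,
        "p_value": p,
        "log2_fc": lfc,
        "mean_ref": m_ref,
        "mean_case": m_case,
        "direction": np.where(lfc > 0, "up", "down"),
        "neglog10_p": neglog10,
        "volcano_ok": ok,
    })
    if bh_column:
        df["p_bh"] = multipletests(p, method="fdr_bh")[1]
    counts = {thr: int((p < thr).sum()) for thr in thresholds}
    return df, counts


@dataclass
class HeatmapOrdering:
    """Deterministic row/column ordering for a clustered heatmap."""

    row_order: np.ndarray          # permutation of feature indices
    col_order: np.ndarray          # permutation of sample indices
    feature_ids: np.ndarray        # in row_order
    sample_ids: np.ndarray         # in col_order
    z_values: np.ndarray           # per-feature z-scores, input order
    linkage_method: str
    metric: str
    constant_rows: np.ndarray      # feature ids whose z-score is all-zeros


def hierarchical_order(fm: FeatureMatrix, method: str = "average",
                       metric: str = "euclidean") -> HeatmapOrdering:
    """Cluster features and samples of a (typically significant-subset) matrix.

    Rows are z-scored per feature; a constant row gets an all-zero z-score and
    is flagged rather than erroring.  Average-linkage (UPGMA) Euclidean
    clustering by default; leaf order is scipy's deterministic order, so ties
    resolve by input order.
    """
    if fm.n_features < 2:
        raise ValueError("need at least 2 features to cluster rows")
    if fm.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster columns")
    X = fm.signals
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (X - mu) / sd_safe
    row_order = leaves_list(linkage(z, method=method, metric=metric))
    col_order = leaves_list(linkage(z.T, method=method, metric=metric))
    return HeatmapOrdering(
        row_order=row_order,
        col_order=col_order,
        feature_ids=fm.feature_ids[row_order],
        sample_ids=fm.sample_ids[col_order],
        z_values=z,
        linkage_method=method,
        metric=metric,
        constant_rows=fm.feature_ids[constant],
    )
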