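"""Fisher LDA, staged forward panel selection, and hold-out ROC validation.

The classifier is two-class Fisher linear discriminant analysis with a ridge-
regularised pooled covariance:

    w = (S_w + lambda * (tr(S_w)/p) * I)^-1 (mu_1 - mu_0)

with equal class priors, so the LD1 score of a sample x is ``w.x - w.(mu_0 +
mu_1)/2`` and a positive score predicts the case class.  The regularisation is
scaled by the mean pooled variance so lambda is dimensionless; it is needed
whenever the panel size approaches the per-fold training size.

Panel building is a staged forward search: all 3-subsets of the candidate
pool are scored by a cross-validated criterion (pooled held-out-score AUC
from stratified k-fold by default; thresholded accuracy available); the best
triple seeds the panel, which then grows one feature per stage.  Two expansion
modes are provided, because "keep part of the current panel and re-search the
rest" can be read at different search widths:

* ``reserve_one`` — every (k+1)-subset that keeps at least one member of the
  current panel (the literal, combinatorially wide reading);
* ``swap_add``    — the current panel plus one feature, or the panel with one
  member swapped out and two features added (a tractable neighbourhood).

``auto`` picks ``reserve_one`` while its model-fit count stays under a budget
and falls back to ``swap_add``; the mode used at each stage is recorded.  The
search stops when the best enlarged panel no longer improves the criterion, or
at a maximum panel size.

Model stability is assessed by repeated stratified hold-out perturbation:
many random splits, an ROC per held-out set, vertical averaging of the curves
on a fixed FPR grid, AUC of the averaged curve, and a Youden operating point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .feature_table import BinaryComparison, FeatureMatrix

__all__ = [
    "LDAModel", "FisherLDA", "fit_lda", "lda_scores",
    "ROCCurve", "roc_and_auc", "youden_operating_point",
    "SearchConfig", "PanelSearchResult", "ForwardPanelSelector",
    "cv_criterion", "forward_select",
    "ROCSummary", "perturbation_validate", "training_metrics",
]

FPR_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


# =====================================================================  LDA


@dataclass
class LDAModel:
    """Fitted two-class Fisher discriminant: LD1 score = weights.x - offset."""

    feature_ids: tuple
    weights: np.ndarray
    offset: float
    ridge_lambda: float
    class_means: np.ndarray  # shape (2, p): [reference, case]
    degenerate: bool = False


def _fit_lda_arrays(X, y, ridge):
    """Core fit; returns (weights, offset, class_means, degenerate)."""
    X0 = X[y == 0]
    X1 = X[y == 1]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("each class needs at least 2 samples to fit LDA")
    mu0 = X0.mean(axis=0)
    mu1 = X1.mean(axis=0)
    p = X.shape[1]
    R0 = X0 - mu0
    R1 = X1 - mu1
    Sw = (R0.T @ R0 + R1.T @ R1) / (len(X0) + len(X1) - 2)
    tr = float(np.trace(Sw))
    delta = mu1 - mu0
    degenerate = bool(np.allclose(delta, 0.0))
    if tr == 0.0:
        if degenerate:
            w = np.zeros(p)
            return w, 0.0, np.stack([mu0, mu1]), True
        raise ValueError("constant features: zero pooled covariance; "
                         "LDA direction undefined")
    A = Sw + (ridge * tr / p) * np.eye(p)
    if ridge == 0.0 and np.linalg.cond(A) > 1e12:
        raise ValueError("singular pooled covariance; set ridge > 0 "
                         "to regularise")
    w = np.linalg.solve(A, delta)
    offset = float(w @ (mu0 + mu1) / 2.0)
    return w, offset, np.stack([mu0, mu1]), degenerate


class FisherLDA(ClassifierMixin, BaseEstimator):
    """Two-class Fisher LDA with trace-scaled ridge regularisation.

    Fitted attributes: ``weights_``, ``offset_``, ``class_means_``,
    ``classes_`` (reference first), ``degenerate_`` (True when the class means
    coincide and the weight vector collapses to zero).
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("FisherLDA is strictly two-class")
        ybin = (y == self.classes_[1]).astype(int)
        w, b, means, degen = _fit_lda_arrays(X, ybin, self.ridge)
        self.weights_ = w
        self.offset_ = b
        self.coef_ = w[None, :]
        self.intercept_ = np.array([-b])
        self.class_means_ = means
        self.degenerate_ = degen
        self.n_features_in_ = X.shape[1]
        if degen:
            warnings.warn("identical class means: degenerate LDA model")
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"X must have {self.n_features_in_} columns")
        return X @ self.weights_ - self.offset_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def fit_lda(X, y, ridge_lambda: float = 1e-6, feature_ids=None) -> LDAModel:
    """Functional interface returning a plain :class:`LDAModel` record."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    w, b, means, degen = _fit_lda_arrays(X, y, ridge_lambda)
    if feature_ids is None:
        feature_ids = tuple(range(X.shape[1]))
    return LDAModel(tuple(feature_ids), w, b, ridge_lambda, means, degen)


def lda_scores(model: LDAModel, X) -> np.ndarray:
    """LD1 score per sample (empty input gives an empty array)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0)
    if X.ndim != 2 or X.shape[1] != len(model.weights):
        raise ValueError(f"X must have {len(model.weights)} columns")
    return X @ model.weights - model.offset


# =====================================================================  ROC


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # score cutoffs; predictions are score >= threshold


def _roc_points(scores, y):
    """ROC vertices from a full threshold sweep; tied scores collapse to one
    threshold (yielding a diagonal segment)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    ys = y[order]
    ss = scores[order]
    # last index of each run of tied scores
    ends = np.r_[np.flatnonzero(np.diff(ss)), len(ss) - 1]
    tps = np.cumsum(ys)[ends]
    fps = (ends + 1) - tps
    fpr = np.r_[0.0, fps / n0]
    tpr = np.r_[0.0, tps / n1]
    thresholds = np.r_[np.inf, ss[ends]]
    return fpr, tpr, thresholds


def roc_and_auc(scores, y):
    """Full-sweep ROC curve and trapezoidal AUC (ties give diagonal segments).

    The AUC equals the Mann-Whitney statistic U/(n0*n1) with the usual 1/2
    credit for ties.
    """
    fpr, tpr, thr = _roc_points(scores, y)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, thr), auc


def youden_operating_point(roc: ROCCurve):
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties break toward higher specificity (lower FPR).  Returns
    ``(sensitivity, specificity, threshold)``.
    """
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j == j.max())
    i = best[np.argmin(roc.fpr[best])]
    thr = float(roc.thresholds[i]) if roc.thresholds is not None else float("nan")
    return float(roc.tpr[i]), float(1.0 - roc.fpr[i]), thr


def _fast_auc(scores, y):
    """Rank-form AUC (identical to the trapezoidal full-sweep value)."""
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    r = rankdata(scores)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


# ==========================================================  CV criterion


def _make_folds(y, n_folds, seed):
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(f"smallest class ({counts.min()}) < folds ({n_folds})")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _pooled_cv_metric(X, y, folds, ridge, criterion):
    scores = np.empty(len(y))
    for train, test in folds:
        w, b, _, _ = _fit_lda_arrays(X[train], y[train], ridge)
        scores[test] = X[test] @ w - b
    if criterion == "cv_auc":
        return _fast_auc(scores, y)
    if criterion == "cv_accuracy":
        return float(((scores > 0).astype(int) == y).mean())
    raise ValueError(f"unknown criterion {criterion!r}")


class _FoldCache:
    """Per-fold sufficient statistics over the full candidate pool.

    A candidate panel's LDA fit only needs the submatrix of the pooled
    training covariance and the subvector of the mean difference, so both are
    computed once per fold for all pool features; scoring a candidate is then
    a small solve plus a test-set projection.  Gives results identical to
    :func:`_pooled_cv_metric` (same arithmetic, shared across candidates).
    """

    def __init__(self, X, y, folds, ridge):
        self.y = y
        self.n = len(y)
        self.ridge = ridge
        self.folds = []
        for train, test in folds:
            Xtr, ytr = X[train], y[train]
            X0, X1 = Xtr[ytr == 0], Xtr[ytr == 1]
            mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
            R0, R1 = X0 - mu0, X1 - mu1
            Sw = (R0.T @ R0 + R1.T @ R1) / (len(X0) + len(X1) - 2)
            self.folds.append((Sw, mu0, mu1,
                               np.ascontiguousarray(X[test]), test))

    def metric(self, idx, criterion):
        idx = np.asarray(idx, dtype=int)
        k = len(idx)
        scores = np.empty(self.n)
        eye = np.eye(k)
        for Sw, mu0, mu1, Xte, test in self.folds:
            A = Sw[np.ix_(idx, idx)]
            tr = A.trace()
            w = np.linalg.solve(A + (self.ridge * tr / k) * eye,
                                mu1[idx] - mu0[idx])
            scores[test] = Xte[:, idx] @ w - w @ (mu0[idx] + mu1[idx]) / 2.0
        if criterion == "cv_auc":
            return _fast_auc(scores, self.y)
        return float(((scores > 0).astype(int) == self.y).mean())


def cv_criterion(panel, fm: FeatureMatrix, cmp: BinaryComparison,
                 folds: int = 5, seed: int = 0, criterion: str = "cv_auc",
                 ridge: float = 1e-6) -> float:
    """Stratified k-fold criterion of one panel: pooled held-out LD1 scores,
    summarized as AUC (default) or accuracy at threshold 0.  Deterministic
    given ``seed``."""
    idx = fm.feature_index(panel)
    X = fm.signals[idx].T
    y = cmp.y_for(fm.sample_ids)
    return _pooled_cv_metric(X, y, _make_folds(y, folds, seed), ridge, criterion)


# ===================================================  forward panel search


@dataclass
class SearchConfig:
    mode: str = "auto"               # auto | reserve_one | swap_add
    criterion: str = "cv_auc"        # cv_auc | cv_accuracy
    folds: int = 5
    max_size: int = 10
    budget: int = 2_000_000          # model-fit budget for reserve_one
    ridge: float = 1e-6
    pool_p: float | None = None      # univariate pre-filter p threshold
    seed: int = 0


@dataclass
class PanelSearchResult:
    """Staged trace of the search: one entry per accepted panel size."""

    stages: list                     # dicts: panel, criterion, mode, n_candidates
    final_panel: tuple
    stopping_reason: str             # no_improvement | max_size
    search_modes: list
    tie_log: list = field(default_factory=list)
    criterion_name: str = "cv_auc"
    folds: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "stages": [dict(s, panel=list(s["panel"])) for s in self.stages],
            "final_panel": list(self.final_panel),
            "stopping_reason": self.stopping_reason,
            "search_modes": list(self.search_modes),
            "tie_log": list(self.tie_log),
            "criterion": self.criterion_name,
            "folds": self.folds,
            "seed": self.seed,
        }


def _n_reserve_one_candidates(m, k_panel, new_size):
    """(new_size)-subsets of an m-pool intersecting the current k_panel-panel."""
    return math.comb(m, new_size) - math.comb(m - k_panel, new_size)


class ForwardPanelSelector(BaseEstimator):
    """Staged forward feature selection wrapped around cross-validated LDA.

    ``fit(X, y, feature_names=...)`` runs the search; fitted attributes:
    ``panel_ids_``, ``panel_indices_``, ``stages_``, ``stopping_reason_``,
    ``result_`` (full :class:`PanelSearchResult`).
    """

    def __init__(self, mode="auto", criterion="cv_auc", folds=5, max_size=10,
                 budget=2_000_000, ridge=1e-6, seed=0):
        self.mode = mode
        self.criterion = criterion
        self.folds = folds
        self.max_size = max_size
        self.budget = budget
        self.ridge = ridge
        self.seed = seed

    # -- candidate enumeration -------------------------------------------
    def _reserve_one_candidates(self, panel, m):
        pool = set(range(m))
        cands = set()
        k = len(panel)
        for r in panel:
            rest = sorted(pool - {r})
            for S in combinations(rest, k):
                cands.add(tuple(sorted((r,) + S)))
        return sorted(cands)

    def _swap_add_candidates(self, panel, m):
        pool = sorted(set(range(m)) - set(panel))
        cands = set()
        for a in pool:
            cands.add(tuple(sorted(panel + (a,))))
        for d in panel:
            base = tuple(x for x in panel if x != d)
            for a, b in combinations(pool, 2):
                cands.add(tuple(sorted(base + (a, b))))
        return sorted(cands)

    def _evaluate_best(self, cache, candidates, names, tie_log, stage):
        best_crit = -np.inf
        best_cand = None
        ties = 0
        for cand in candidates:
            crit = cache.metric(cand, self.criterion)
            if crit > best_crit:
                best_crit, best_cand, ties = crit, cand, 0
            elif crit == best_crit:
                ties += 1
                # tie-break: lexicographically smallest feature-id tuple
                if (tuple(sorted(names[i] for i in cand))
                        < tuple(sorted(names[i] for i in best_cand))):
                    best_cand = cand
        if ties:
            tie_log.append({"stage": stage, "n_tied": ties,
                            "criterion": best_crit,
                            "panel": [names[i] for i in best_cand]})
        return best_cand, float(best_crit)

    # -- search ----------------------------------------------------------
    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n, m = X.shape
        if m < 3:
            raise ValueError(f"candidate pool has {m} features; need >= 3")
        names = (list(feature_names) if feature_names is not None
                 else [f"f{i}" for i in range(m)])
        if len(names) != m:
            raise ValueError("feature_names length mismatch")
        folds = _make_folds(y, self.folds, self.seed)
        cache = _FoldCache(X, y, folds, self.ridge)
        tie_log: list = []
        stages: list = []
        modes: list = []

        cands3 = list(combinations(range(m), 3))
        panel, crit = self._evaluate_best(cache, cands3, names,
                                          tie_log, stage=3)
        stages.append({"panel": tuple(names[i] for i in sorted(panel)),
                       "criterion": crit, "mode": "exhaustive_3",
                       "n_candidates": len(cands3)})
        modes.append("exhaustive_3")
        stopping = "max_size" if len(panel) >= self.max_size else None

        while stopping is None and len(panel) < self.max_size:
            new_size = len(panel) + 1
            n_res = _n_reserve_one_candidates(m, len(panel), new_size)
            if self.mode == "reserve_one":
                if n_res * self.folds > self.budget:
                    raise ValueError(
                        f"reserve_one needs {n_res * self.folds} fits; "
                        f"budget is {self.budget}")
                mode = "reserve_one"
            elif self.mode == "swap_add":
                mode = "swap_add"
            elif self.mode == "auto":
                mode = ("reserve_one" if n_res * self.folds <= self.budget
                        else "swap_add")
            else:
                raise ValueError(f"unknown mode {self.mode!r}")
            if mode == "reserve_one":
                cands = self._reserve_one_candidates(panel, m)
            else:
                cands = self._swap_add_candidates(panel, m)
            cand, cand_crit = self._evaluate_best(cache, cands, names,
                                                  tie_log, stage=new_size)
            if cand_crit <= crit:
                stopping = "no_improvement"
                break
            panel, crit = cand, cand_crit
            stages.append({"panel": tuple(names[i] for i in sorted(panel)),
                           "criterion": crit, "mode": mode,
                           "n_candidates": len(cands)})
            modes.append(mode)
            if len(panel) >= self.max_size:
                stopping = "max_size"
        if stopping is None:  # pragma: no cover - loop guard
            stopping = "max_size"

        self.panel_indices_ = tuple(sorted(panel))
        self.panel_ids_ = tuple(names[i] for i in self.panel_indices_)
        self.criterion_value_ = crit
        self.stages_ = stages
        self.stopping_reason_ = stopping
        self.tie_log_ = tie_log
        self.result_ = PanelSearchResult(
            stages=stages, final_panel=self.panel_ids_,
            stopping_reason=stopping, search_modes=modes, tie_log=tie_log,
            criterion_name=self.criterion, folds=self.folds, seed=self.seed)
        self.n_features_in_ = m
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, list(self.panel_indices_)]

    def get_support(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[list(self.panel_indices_)] = True
        return mask


def forward_select(fm: FeatureMatrix, cmp: BinaryComparison,
                   config: SearchConfig | None = None) -> PanelSearchResult:
    """Run the staged search on a (normalized) feature matrix.

    With ``config.pool_p`` set, the candidate pool is pre-filtered to features
    with a univariate p value below the threshold (the usual way to make the
    wide search modes tractable on a few-hundred-feature matrix).
    """
    from .univariate import univariate_table  # late import, avoids a cycle

    config = config or SearchConfig()
    if config.pool_p is not None:
        table, _ = univariate_table(fm, cmp)
        pool_ids = table.loc[table["p_value"] < config.pool_p, "feature_id"]
        pool = fm.subset_features(list(pool_ids))
    else:
        pool = fm
    if pool.n_features < 3:
        raise ValueError(f"candidate pool has {pool.n_features} features; "
                         "need >= 3 (relax pool_p?)")
    y = cmp.y_for(pool.sample_ids)
    sel = ForwardPanelSelector(mode=config.mode, criterion=config.criterion,
                               folds=config.folds, max_size=config.max_size,
                               budget=config.budget, ridge=config.ridge,
                               seed=config.seed)
    sel.fit(pool.signals.T, y, feature_names=list(pool.feature_ids))
    return sel.result_


# =======================================================  hold-out ROC


@dataclass
class ROCSummary:
    """Averaged ROC over repeated hold-outs (or a training ROC when n_reps=0)."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    auc: float
    sensitivity: float
    specificity: float
    n_reps: int
    holdout_fraction: float
    seed: int
    threshold: float = float("nan")  # score cutoff (training ROC only)
    n_redraws: int = 0
    mean_rep_auc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "fpr_grid": [float(v) for v in self.fpr_grid],
            "mean_tpr": [float(v) for v in self.mean_tpr],
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_reps": self.n_reps,
            "holdout_fraction": self.holdout_fraction,
            "seed": self.seed,
            "threshold": self.threshold,
            "n_redraws": self.n_redraws,
            "mean_rep_auc": self.mean_rep_auc,
        }


def _interp_tpr(fpr, tpr, grid):
    """Staircase interpolation: TPR at the largest curve FPR <= grid point."""
    idx = np.searchsorted(fpr, grid, side="right") - 1
    return tpr[np.clip(idx, 0, len(tpr) - 1)]


def _stratified_split(y, frac, rng):
    """Indices of a stratified hold-out test set (at least 1 per class)."""
    test = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        n_test = max(1, int(round(frac * len(idx))))
        if len(idx) - n_test < 2:
            raise ValueError(f"class {cls}: {len(idx)} samples cannot support "
                             f"holdout fraction {frac}")
        test.append(rng.choice(idx, size=n_test, replace=False))
    return np.sort(np.concatenate(test))


def _validate_arrays(X, y, n_reps, frac, seed, ridge):
    if not 0.0 < frac < 1.0:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    grid = FPR_GRID
    tpr_sum = np.zeros_like(grid)
    rep_auc = 0.0
    n_redraws = 0
    children = np.random.SeedSequence(seed).spawn(n_reps)
    n = len(y)
    for child in children:
        rng = np.random.default_rng(child)
        for _ in range(100):
            test = _stratified_split(y, frac, rng)
            train = np.setdiff1d(np.arange(n), test)
            if len(np.unique(y[test])) == 2 and len(np.unique(y[train])) == 2:
                break
            n_redraws += 1  # pragma: no cover - stratified split prevents this
        w, b, _, _ = _fit_lda_arrays(X[train], y[train], ridge)
        scores = X[test] @ w - b
        fpr, tpr, _ = _roc_points(scores, y[test])
        tpr_sum += _interp_tpr(fpr, tpr, grid)
        rep_auc += np.trapezoid(tpr, fpr)
    mean_tpr = tpr_sum / n_reps
    auc = float(np.trapezoid(mean_tpr, grid))
    sens, spec, _ = youden_operating_point(ROCCurve(grid, mean_tpr, None))
    return ROCSummary(grid.copy(), mean_tpr, auc, sens, spec, n_reps, frac,
                      seed, n_redraws=n_redraws,
                      mean_rep_auc=float(rep_auc / n_reps))


def perturbation_validate(panel, fm: FeatureMatrix, cmp: BinaryComparison,
                          n_reps: int = 1000, holdout_fraction: float = 0.2,
                          seed: int = 0, ridge: float = 1e-6) -> ROCSummary:
    """Repeated stratified hold-out validation of a fixed panel.

    Per repeat, ``holdout_fraction`` of each class is held out for testing,
    LDA is fitted on the remainder, and the held-out ROC is computed; curves
    are averaged vertically on a fixed FPR grid (step 0.01).  The summary AUC
    is the trapezoid of the averaged curve; sensitivity/specificity are read
    at its Youden point.  Bit-reproducible given ``seed``.
    """
    idx = fm.feature_index(panel)
    X = fm.signals[idx].T
    y = cmp.y_for(fm.sample_ids)
    return _validate_arrays(X, y, n_reps, holdout_fraction, seed, ridge)


def training_metrics(panel, fm: FeatureMatrix, cmp: BinaryComparison,
                     ridge: float = 1e-6) -> ROCSummary:
    """In-sample ROC of a panel fitted on all samples (``n_reps = 0``)."""
    if len(panel) == 0:
        raise ValueError("empty panel")
    idx = fm.feature_index(panel)
    X = fm.signals[idx].T
    y = cmp.y_for(fm.sample_ids)
    w, b, _, _ = _fit_lda_arrays(X, y, ridge)
    scores = X @ w - b
    roc, auc = roc_and_auc(scores, y)
    sens, spec, thr = youden_operating_point(roc)
    mean_tpr = _interp_tpr(roc.fpr, roc.tpr, FPR_GRID)
    return ROCSummary(FPR_GRID.copy(), mean_tpr, auc, sens, spec,
                      n_reps=0, holdout_fraction=0.0, seed=0, threshold=thr)
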