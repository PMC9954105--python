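"""Principal component analysis of VOC feature subsets.

PCA is run on the samples x features orientation of a (normalized) feature
matrix, column-centered and — by default — autoscaled to unit variance, the
usual chemometric convention when features span orders of magnitude.  A
deterministic sign convention (each loading vector's largest-magnitude entry
is positive) makes score files reproducible across runs and platforms.

Beyond the decomposition itself, two small analyses used on VOC data are
provided: a class-significance t test on a chosen component's scores, and a
"separation accuracy" — the training accuracy of a linear discriminant fitted
on the first k score dimensions, which operationalizes "the classes are
distinguished in the k-dimensional PCA plot".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SkPCA

from .feature_table import BinaryComparison, FeatureMatrix
from .univariate import ttest_two_tailed

__all__ = ["PCAResult", "ScaledPCA", "pca_fit", "pc_class_significance",
           "pca_separation_accuracy"]


@dataclass
class PCAResult:
    loadings: np.ndarray            # features x components, orthonormal
    scores: np.ndarray              # samples x components
    explained_fraction: np.ndarray  # descending, sums to 1 over all components
    center: np.ndarray              # per-feature mean removed
    scale: np.ndarray               # per-feature divisor (ones if no scaling)
    feature_ids: np.ndarray
    sample_ids: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


class ScaledPCA(TransformerMixin, BaseEstimator):
    """PCA with optional autoscaling and a deterministic sign convention.

    Parameters
    ----------
    n_components : int or None
        Components to keep (None keeps the full rank).
    scaling : {"unit_variance", "none"}
        "unit_variance" (default) divides each centered feature by its sample
        standard deviation before the SVD; zero-variance features get scale 1.
    """

    def __init__(self, n_components=None, scaling: str = "unit_variance"):
        self.n_components = n_components
        self.scaling = scaling

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 2:
            raise ValueError("PCA needs at least 2 samples")
        if self.scaling not in ("unit_variance", "none"):
            raise ValueError("scaling must be 'unit_variance' or 'none'")
        self.center_ = X.mean(axis=0)
        if self.scaling == "unit_variance":
            sd = X.std(axis=0, ddof=1)
            self.scale_ = np.where(sd == 0, 1.0, sd)
        else:
            self.scale_ = np.ones(p)
        Z = (X - self.center_) / self.scale_
        if np.allclose(Z, 0):
            raise ValueError("matrix has zero variance; PCA undefined")
        max_rank = min(p, n - 1)
        k = max_rank if self.n_components is None else int(self.n_components)
        if not 1 <= k <= max_rank:
            raise ValueError(f"n_components must lie in [1, {max_rank}]")
        pca = _SkPCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(Z)
        comps = pca.components_  # k x p
        # sign convention: largest-|loading| entry of each component positive
        flip = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = comps * flip[:, None]
        self.scores_ = scores * flip[None, :]
        self.explained_fraction_ = pca.explained_variance_ratio_
        return self

    def transform(self, X):
        Z = (np.asarray(X, dtype=float) - self.center_) / self.scale_
        return Z @ self.components_.T


def pca_fit(fm: FeatureMatrix, n_components=None,
            scaling: str = "unit_variance") -> PCAResult:
    """Fit PCA on ``fm`` (samples as observations) and package the result."""
    est = ScaledPCA(n_components=n_components, scaling=scaling)
    est.fit(fm.signals.T)
    return PCAResult(
        loadings=est.components_.T,
        scores=est.scores_,
        explained_fraction=est.explained_fraction_,
        center=est.center_,
        scale=est.scale_,
        feature_ids=fm.feature_ids.copy(),
        sample_ids=fm.sample_ids.copy(),
    )


def pc_class_significance(res: PCAResult, cmp: BinaryComparison,
                          component: int = 0, variant: str = "student") -> float:
    """Two-tailed t test p value comparing one component's scores between classes."""
    if not 0 <= component < res.n_components:
        raise IndexError(f"component {component} out of range "
                         f"[0, {res.n_components - 1}]")
    y = cmp.y_for(res.sample_ids)
    s = res.scores[:, component]
    _, p = ttest_two_tailed(s[y == 0], s[y == 1], variant=variant)
    return p


def pca_separation_accuracy(res: PCAResult, cmp: BinaryComparison,
                            k_components: int = 2) -> float:
    """Training accuracy of Fisher LDA on the first ``k_components`` scores.

    1.0 means the classes are linearly separable in the k-dimensional score
    plot (e.g. a 2-D PCA plot that "distinguishes the classes completely").
    """
    from .panel_selection import FisherLDA  # local import to avoid a cycle

    if not 1 <= k_components <= res.n_components:
        raise ValueError(f"k_components must lie in [1, {res.n_components}]")
    y = cmp.y_for(res.sample_ids)
    X = res.scores[:, :k_components]
    model = FisherLDA(ridge=1e-6).fit(X, y)
    return float((model.predict(X) == y).mean())
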