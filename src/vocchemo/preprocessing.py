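"""Screening cascade and relative-abundance normalization.

A raw aligned feature table is turned into the analysis matrix by four rules,
applied in a fixed order so that removal counts are reproducible:

1. retention-time spread — drop features whose RT spread exceeds a tolerance
   (misaligned features masquerading as one compound);
2. presence — drop features detected (signal > 0) in fewer than a minimum
   fraction of samples in every class (``any_class`` mode, the default: keep a
   feature if it reaches the fraction in at least one class);
3. exclusion — drop features flagged as exogenous (siloxanes, plasticizers)
   or matching a user-supplied exclusion list of ids/compound names;
4. relative-abundance normalization — divide each signal by its sample's total
   so every sample column sums to 1, cancelling urine dilution differences.

Each rule is available standalone; :func:`screen` composes them and returns a
:class:`ScreeningReport` that accounts for every removed feature exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .feature_table import BinaryComparison, FeatureMatrix

__all__ = [
    "ScreeningConfig",
    "ScreeningReport",
    "Screener",
    "filter_rt_spread",
    "filter_presence",
    "filter_exclusion",
    "normalize_relative_abundance",
    "screen",
]


@dataclass
class ScreeningConfig:
    """Knobs of the screening cascade.

    ``max_rt_spread`` defaults to 0.10 min, a typical capillary-GC alignment
    tolerance (the threshold is a configuration knob, not a claim about any
    particular instrument).  ``presence_mode`` is ``any_class`` by default;
    ``all_classes`` requires the minimum detected fraction in every class.
    """

    max_rt_spread: float = 0.10
    presence_min_fraction: float = 0.5
    presence_mode: str = "any_class"
    exclusion_ids: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence_min_fraction <= 1.0:
            raise ValueError("presence_min_fraction must lie in [0, 1]")
        if self.max_rt_spread < 0:
            raise ValueError("max_rt_spread must be >= 0")
        if self.presence_mode not in ("any_class", "all_classes"):
            raise ValueError("presence_mode must be any_class or all_classes")


@dataclass
class ScreeningReport:
    """Sequential accounting of the cascade: removed-per-rule counts sum with
    the retained count to the input feature count."""

    n_input: int
    removed: dict  # rule name -> count, in application order
    removed_ids: dict  # rule name -> list of feature ids
    retained: int
    rule_order: tuple = ("rt_spread", "presence", "exclusion")

    def __post_init__(self) -> None:
        if sum(self.removed.values()) + self.retained != self.n_input:
            raise ValueError("screening report does not balance")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "removed_ids": {k: list(v) for k, v in self.removed_ids.items()},
            "retained": self.retained,
            "rule_order": list(self.rule_order),
        }


def _class_partition(labels, sample_ids) -> dict:
    """Map class label -> boolean sample mask.  ``labels`` may be a
    BinaryComparison or any mapping/Series sample_id -> class label (so a
    four-class partition can drive the presence rule)."""
    if isinstance(labels, BinaryComparison):
        series = labels.labels
    elif isinstance(labels, pd.Series):
        series = labels
    else:
        series = pd.Series(dict(labels))
    values = series.loc[list(sample_ids)].to_numpy()
    out = {}
    for cls in pd.unique(values):
        mask = values == cls
        if mask.sum() == 0:  # pragma: no cover - unique() guarantees nonzero
            raise ValueError(f"class {cls!r} has zero samples")
        out[cls] = mask
    if len(out) < 2:
        raise ValueError("presence filtering needs at least two classes")
    return out


def filter_rt_spread(fm: FeatureMatrix, max_spread: float) -> FeatureMatrix:
    """Retain exactly the features with rt_spread <= ``max_spread``."""
    return fm.subset_features(fm.rt_spread <= max_spread)


def filter_presence(fm: FeatureMatrix, labels, min_fraction: float = 0.5,
                    mode: str = "any_class") -> FeatureMatrix:
    """Drop features not detected often enough.  Presence means signal > 0.

    ``any_class``: keep a feature iff its detected fraction reaches
    ``min_fraction`` in at least one class; ``all_classes``: in every class.
    """
    parts = _class_partition(labels, fm.sample_ids)
    detected = fm.signals > 0
    fracs = np.column_stack([detected[:, m].mean(axis=1) for m in parts.values()])
    if mode == "any_class":
        keep = (fracs >= min_fraction).any(axis=1)
    elif mode == "all_classes":
        keep = (fracs >= min_fraction).all(axis=1)
    else:
        raise ValueError(f"unknown presence mode {mode!r}")
    return fm.subset_features(keep)


def filter_exclusion(fm: FeatureMatrix, exclusion_ids=()) -> FeatureMatrix:
    """Drop features whose id or compound name is in ``exclusion_ids`` or whose
    ``is_exogenous`` annotation flag is set."""
    excl = set(exclusion_ids)
    drop = np.array([f in excl for f in fm.feature_ids])
    if fm.annotations is not None:
        ann = fm.annotations.loc[fm.feature_ids]
        if "compound_name" in ann.columns:
            names = ann["compound_name"].fillna("").to_numpy()
            drop |= np.array([n in excl for n in names])
        if "is_exogenous" in ann.columns:
            drop |= ann["is_exogenous"].fillna(0).astype(int).to_numpy() == 1
    return fm.subset_features(~drop)


def normalize_relative_abundance(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide each signal by its sample's total; every column then sums to 1.

    Zeros stay zero.  An all-zero sample column is an error (the sample has no
    detected signal to normalize by) and the offending sample is named.
    """
    totals = fm.signals.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample(s) with zero total signal: {list(fm.sample_ids[zero])}"
        )
    out = fm.copy()
    out.signals = fm.signals / totals
    return out


def screen(fm: FeatureMatrix, labels, config: ScreeningConfig | None = None):
    """Apply the full cascade; returns ``(normalized FeatureMatrix, ScreeningReport)``."""
    config = config or ScreeningConfig()
    n_input = fm.n_features
    removed, removed_ids = {}, {}

    stage = filter_rt_spread(fm, config.max_rt_spread)
    removed_ids["rt_spread"] = sorted(set(fm.feature_ids) - set(stage.feature_ids))
    removed["rt_spread"] = len(removed_ids["rt_spread"])

    prev = stage
    stage = filter_presence(prev, labels, config.presence_min_fraction,
                            config.presence_mode)
    removed_ids["presence"] = sorted(set(prev.feature_ids) - set(stage.feature_ids))
    removed["presence"] = len(removed_ids["presence"])

    prev = stage
    stage = filter_exclusion(prev, config.exclusion_ids)
    removed_ids["exclusion"] = sorted(set(prev.feature_ids) - set(stage.feature_ids))
    removed["exclusion"] = len(removed_ids["exclusion"])

    report = ScreeningReport(n_input, removed, removed_ids, stage.n_features)
    return normalize_relative_abundance(stage), report


class Screener(BaseEstimator):
    """Estimator wrapper around :func:`screen`.

    ``fit(fm, labels)`` runs the cascade and stores ``retained_ids_`` and
    ``report_``; ``transform(fm)`` restricts any matrix with the same feature
    vocabulary to the retained set and normalizes it.
    """

    def __init__(self, max_rt_spread: float = 0.10,
                 presence_min_fraction: float = 0.5,
                 presence_mode: str = "any_class",
                 exclusion_ids=()):
        self.max_rt_spread = max_rt_spread
        self.presence_min_fraction = presence_min_fraction
        self.presence_mode = presence_mode
        self.exclusion_ids = exclusion_ids

    def _config(self) -> ScreeningConfig:
        return ScreeningConfig(self.max_rt_spread, self.presence_min_fraction,
                               self.presence_mode, set(self.exclusion_ids))

    def fit(self, fm: FeatureMatrix, labels):
        screened, report = screen(fm, labels, self._config())
        self.retained_ids_ = list(screened.feature_ids)
        self.report_ = report
        self.screened_ = screened
        return self

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if not hasattr(self, "retained_ids_"):
            raise RuntimeError("Screener is not fitted")
        return normalize_relative_abundance(fm.subset_features(self.retained_ids_))

    def fit_transform(self, fm: FeatureMatrix, labels) -> FeatureMatrix:
        return self.fit(fm, labels).screened_


def _disabled_config() -> ScreeningConfig:
    """A configuration under which screening reduces to normalization only."""
    return ScreeningConfig(max_rt_spread=math.inf, presence_min_fraction=0.0,
                           exclusion_ids=set())
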