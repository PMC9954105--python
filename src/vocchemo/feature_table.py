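"""Aligned GC-MS VOC feature tables, sample metadata, and binary class labelings.

The central container is :class:`FeatureMatrix`: a features x samples table of
nonnegative integrated signal intensities, carrying per-feature retention-time
statistics (mean and across-sample spread, in minutes) and optional compound
annotations.  A signal of 0 always means *not detected* — missing cells are not
allowed, so the presence/absence predicate used by downstream screening is
unambiguous.

Sample metadata lives in a separate CSV keyed by ``sample_id`` with columns
``cohort`` (human/mouse), ``isup_grade`` (0-5, human), ``tumor_status``
(control/tumor, mouse) and an optional ``run_order``.  Class labelings are
derived from the metadata by :func:`binarize_labels`:

* ``cancer_vs_none``     — case iff ISUP grade >= 1 (any biopsy-positive sample),
* ``aggressive_vs_rest`` — case iff ISUP grade >= 3 (grades 0-2 pooled as reference),
* ``tumor_vs_control``   — case iff mouse tumor_status == "tumor".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "BinaryComparison",
    "COMPARISON_SCHEMES",
    "ANNOTATION_COLUMNS",
    "read_feature_table",
    "write_feature_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "validate_metadata",
    "read_exclusion_list",
    "binarize_labels",
]

#: Reserved (non-sample) columns of the feature-table CSV dialect, in order.
REQUIRED_COLUMNS = ("feature_id", "rt_mean", "rt_spread")
ANNOTATION_COLUMNS = ("compound_name", "functional_group", "is_exogenous")

COMPARISON_SCHEMES = ("cancer_vs_none", "aggressive_vs_rest", "tumor_vs_control")


class FormatError(ValueError):
    """Malformed input file (missing columns, non-numeric cells)."""


@dataclass
class FeatureMatrix:
    """Features x samples matrix of nonnegative integrated GC-MS signals.

    Parameters
    ----------
    feature_ids : array of str, unique
    sample_ids : array of str, unique
    signals : ndarray, shape (n_features, n_samples), all values >= 0
    rt_mean : per-feature retention time, minutes
    rt_spread : per-feature retention-time spread across samples, minutes, >= 0
    annotations : optional DataFrame indexed by feature_id with any of
        ``compound_name``, ``functional_group``, ``is_exogenous`` (0/1).
    """

    feature_ids: np.ndarray
    sample_ids: np.ndarray
    signals: np.ndarray
    rt_mean: np.ndarray
    rt_spread: np.ndarray
    annotations: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.signals = np.asarray(self.signals, dtype=float)
        self.rt_mean = np.asarray(self.rt_mean, dtype=float)
        self.rt_spread = np.asarray(self.rt_spread, dtype=float)
        self.validate()

    # ------------------------------------------------------------------ checks
    def validate(self) -> None:
        nf, ns = len(self.feature_ids), len(self.sample_ids)
        if self.signals.shape != (nf, ns):
            raise ValueError(
                f"signals shape {self.signals.shape} != ({nf} features, {ns} samples)"
            )
        if len(np.unique(self.feature_ids)) != nf:
            raise ValueError("duplicate feature_ids")
        if len(np.unique(self.sample_ids)) != ns:
            raise ValueError("duplicate sample_ids")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("non-finite signal values")
        if np.any(self.signals < 0):
            raise ValueError("negative signal values (0 encodes not-detected)")
        if self.rt_mean.shape != (nf,) or self.rt_spread.shape != (nf,):
            raise ValueError("rt_mean / rt_spread must have one entry per feature")
        if np.any(self.rt_spread < 0):
            raise ValueError("rt_spread must be >= 0")
        if self.annotations is not None:
            missing = set(self.feature_ids) - set(self.annotations.index)
            if missing:
                raise ValueError(f"annotations missing for features: {sorted(missing)[:5]}")

    # -------------------------------------------------------------- accessors
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, ids) -> np.ndarray:
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message detail
            raise KeyError(f"unknown feature id {exc.args[0]!r}") from None

    def subset_features(self, mask_or_ids) -> "FeatureMatrix":
        """Return a new matrix restricted to a boolean mask or id sequence (order kept)."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = self.feature_index(arr)
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[self.feature_ids[idx]]
        return FeatureMatrix(
            self.feature_ids[idx],
            self.sample_ids.copy(),
            self.signals[idx],
            self.rt_mean[idx],
            self.rt_spread[idx],
            ann,
        )

    def subset_samples(self, sample_ids) -> "FeatureMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return FeatureMatrix(
            self.feature_ids.copy(),
            self.sample_ids[idx],
            self.signals[:, idx],
            self.rt_mean.copy(),
            self.rt_spread.copy(),
            None if self.annotations is None else self.annotations.copy(),
        )

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.feature_ids.copy(),
            self.sample_ids.copy(),
            self.signals.copy(),
            self.rt_mean.copy(),
            self.rt_spread.copy(),
            None if self.annotations is None else self.annotations.copy(),
        )

    def equals(self, other: "FeatureMatrix") -> bool:
        """Exact (bitwise) equality of ids, RT statistics and signals."""
        return (
            np.array_equal(self.feature_ids, other.feature_ids)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.signals, other.signals)
            and np.array_equal(self.rt_mean, other.rt_mean)
            and np.array_equal(self.rt_spread, other.rt_spread)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature_id": self.feature_ids,
                           "rt_mean": self.rt_mean,
                           "rt_spread": self.rt_spread})
        if self.annotations is not None:
            ann = self.annotations.loc[self.feature_ids]
            for col in ANNOTATION_COLUMNS:
                if col in ann.columns:
                    df[col] = ann[col].to_numpy()
        sig = pd.DataFrame(self.signals, columns=list(self.sample_ids))
        return pd.concat([df, sig], axis=1)


# ---------------------------------------------------------------------- I/O


def read_feature_table(path) -> FeatureMatrix:
    """Read the feature-table CSV dialect into a validated :class:`FeatureMatrix`.

    Malformed numeric cells and negative signals are rejected, never coerced.
    """
    df = pd.read_csv(path, dtype={"feature_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    ann_cols = [c for c in ANNOTATION_COLUMNS if c in df.columns]
    sample_cols = [c for c in df.columns
                   if c not in REQUIRED_COLUMNS and c not in ANNOTATION_COLUMNS]
    if not sample_cols:
        raise FormatError("no sample columns found")
    try:
        signals = df[sample_cols].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric signal cell: {exc}") from exc
    annotations = None
    if ann_cols:
        annotations = df[ann_cols].copy()
        annotations.index = pd.Index(df["feature_id"], name="feature_id")
        if "is_exogenous" in annotations.columns:
            annotations["is_exogenous"] = annotations["is_exogenous"].fillna(0).astype(int)
    return FeatureMatrix(
        df["feature_id"].to_numpy(dtype=object),
        np.array(sample_cols, dtype=object),
        signals,
        df["rt_mean"].to_numpy(dtype=float),
        df["rt_spread"].to_numpy(dtype=float),
        annotations,
    )


def write_feature_table(fm: FeatureMatrix, path) -> None:
    """Write ``fm`` as CSV; full float precision is preserved (repr round-trip)."""
    if fm.n_features == 0:
        raise ValueError("refusing to write an empty feature set")
    fm.to_frame().to_csv(path, index=False)


def read_exclusion_list(path) -> set[str]:
    """One feature id or compound name per line; '#' starts a comment."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out


# ------------------------------------------------------------------ metadata


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    if "sample_id" not in meta.columns or "cohort" not in meta.columns:
        raise FormatError("metadata requires sample_id and cohort columns")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in metadata")
    bad = set(meta["cohort"]) - {"human", "mouse"}
    if bad:
        raise ValueError(f"unknown cohort values: {sorted(bad)}")
    human = meta[meta["cohort"] == "human"]
    if len(human):
        if "isup_grade" not in meta.columns or human["isup_grade"].isna().any():
            raise ValueError("human samples require an isup_grade")
        g = human["isup_grade"].astype(int)
        if ((g < 0) | (g > 5)).any():
            raise ValueError("isup_grade must lie in [0, 5]")
    mouse = meta[meta["cohort"] == "mouse"]
    if len(mouse):
        if "tumor_status" not in meta.columns or mouse["tumor_status"].isna().any():
            raise ValueError("mouse samples require a tumor_status")
        bad = set(mouse["tumor_status"]) - {"control", "tumor"}
        if bad:
            raise ValueError(f"unknown tumor_status values: {sorted(bad)}")
    return meta


def read_sample_metadata(path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, dtype={"sample_id": str}))


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    validate_metadata(meta).to_csv(path, index=False)


# ------------------------------------------------------------ binary labeling


@dataclass
class BinaryComparison:
    """A named two-class labeling: 0 = reference, 1 = case, keyed by sample_id."""

    name: str
    labels: pd.Series  # index sample_id, values in {0, 1}

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        if not set(self.labels.unique()) <= {0, 1}:
            raise ValueError("labels must be 0 (reference) or 1 (case)")
        if (self.labels == 0).sum() == 0 or (self.labels == 1).sum() == 0:
            raise ValueError(f"comparison {self.name!r}: one class is empty")

    @property
    def n_reference(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def n_case(self) -> int:
        return int((self.labels == 1).sum())

    def y_for(self, sample_ids) -> np.ndarray:
        """Label vector aligned with ``sample_ids`` (raises on unlabeled samples)."""
        try:
            return self.labels.loc[list(sample_ids)].to_numpy()
        except KeyError as exc:
            raise KeyError(f"sample without a label: {exc.args[0]!r}") from None


def binarize_labels(meta: pd.DataFrame, scheme: str) -> BinaryComparison:
    """Derive a :class:`BinaryComparison` from sample metadata.

    ``cancer_vs_none`` labels case iff ISUP grade >= 1; ``aggressive_vs_rest``
    labels case iff ISUP grade >= 3 (grades 0-2 pooled as reference);
    ``tumor_vs_control`` labels case iff tumor_status == "tumor".
    """
    validate_metadata(meta)
    if scheme not in COMPARISON_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {COMPARISON_SCHEMES}")
    if scheme == "tumor_vs_control":
        rows = meta[meta["cohort"] == "mouse"]
        if rows.empty:
            raise ValueError("tumor_vs_control requires mouse metadata")
        y = (rows["tumor_status"] == "tumor").astype(int)
    else:
        rows = meta[meta["cohort"] == "human"]
        if rows.empty:
            raise ValueError(f"{scheme} requires human metadata")
        grades = rows["isup_grade"].astype(int)
        cut = 1 if scheme == "cancer_vs_none" else 3
        y = (grades >= cut).astype(int)
    labels = pd.Series(y.to_numpy(), index=pd.Index(rows["sample_id"], name="sample_id"))
    return BinaryComparison(scheme, labels)
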