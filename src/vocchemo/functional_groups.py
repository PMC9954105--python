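"""Functional-group profiling of significant VOC sets.

Each significant feature is assigned exactly one chemical class from a fixed
vocabulary (terpene/terpenoid, aromatic, nonaromatic cyclic, ketone, aldehyde,
ester, alcohol, sulfur-containing, other); a compound annotated with several
groups is resolved by a configurable priority order, defaulting to the
vocabulary order.  The profile reports per-group frequencies (counts) and
frequency ratios (count / total significant features), so ratios sum to 1
whenever every feature is assignable (unresolvable annotations fall into
"other" with a warning, never silently dropped).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["GROUP_VOCABULARY", "FunctionalGroupProfile",
           "assign_primary_group", "group_profile"]

GROUP_VOCABULARY = (
    "terpene_terpenoid",
    "aromatic",
    "nonaromatic_cyclic",
    "ketone",
    "aldehyde",
    "ester",
    "alcohol",
    "sulfur_containing",
    "other",
)

_SYNONYMS = {
    "terpene": "terpene_terpenoid",
    "terpenoid": "terpene_terpenoid",
    "terpene_terpenoid": "terpene_terpenoid",
    "aromatic": "aromatic",
    "aryl": "aromatic",
    "nonaromatic_cyclic": "nonaromatic_cyclic",
    "nonaromatic cyclic": "nonaromatic_cyclic",
    "cyclic": "nonaromatic_cyclic",
    "ketone": "ketone",
    "aldehyde": "aldehyde",
    "ester": "ester",
    "alcohol": "alcohol",
    "sulfur": "sulfur_containing",
    "sulfide": "sulfur_containing",
    "disulfide": "sulfur_containing",
    "sulfur_containing": "sulfur_containing",
    "thiol": "sulfur_containing",
    "other": "other",
}


def _tokenize(annotation) -> list[str]:
    if annotation is None or (isinstance(annotation, float) and pd.isna(annotation)):
        return []
    if isinstance(annotation, (list, tuple, set)):
        tokens = [str(t) for t in annotation]
    else:
        tokens = re.split(r"[;,|/]+", str(annotation))
    return [t.strip().lower().replace("-", "_") for t in tokens if t.strip()]


def assign_primary_group(annotation, priority=GROUP_VOCABULARY) -> str:
    """Resolve an annotation to one group from the fixed vocabulary.

    ``annotation`` may be a single label, a delimited string (";", ",", "|",
    "/"), or a sequence.  Multi-group compounds take the group earliest in
    ``priority``.  Unresolvable annotations yield "other" with a warning.
    """
    groups = set()
    for tok in _tokenize(annotation):
        canonical = _SYNONYMS.get(tok, _SYNONYMS.get(tok.replace("_", " ")))
        if canonical is not None:
            groups.add(canonical)
    if not groups:
        warnings.warn(f"unresolvable functional-group annotation {annotation!r}; "
                      "assigning 'other'")
        return "other"
    for g in priority:
        if g in groups:
            return g
    return "other"  # pragma: no cover - vocabulary covers all canonical groups


@dataclass
class FunctionalGroupProfile:
    comparison: str
    frequency: dict   # group -> count of significant features
    ratio: dict       # group -> count / total
    total: int
    vocabulary: tuple = GROUP_VOCABULARY

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": list(self.vocabulary),
            "frequency": [self.frequency.get(g, 0) for g in self.vocabulary],
            "ratio": [self.ratio.get(g, 0.0) for g in self.vocabulary],
        })


def group_profile(significant_ids, annotations, comparison: str = "",
                  priority=GROUP_VOCABULARY) -> FunctionalGroupProfile:
    """Frequency and frequency-ratio profile of one significant feature set.

    ``annotations`` maps feature_id -> functional-group annotation (a mapping,
    a Series, or a DataFrame with a ``functional_group`` column indexed by
    feature id).
    """
    significant_ids = list(significant_ids)
    if not significant_ids:
        raise ValueError("empty significant set: profile undefined")
    if isinstance(annotations, pd.DataFrame):
        ann = annotations["functional_group"]
    elif isinstance(annotations, pd.Series):
        ann = annotations
    else:
        ann = pd.Series(dict(annotations))
    missing = set(significant_ids) - set(ann.index)
    if missing:
        raise KeyError(f"features without annotation: {sorted(missing)[:5]}")
    freq = {g: 0 for g in priority}
    for fid in significant_ids:
        freq[assign_primary_group(ann.loc[fid], priority)] += 1
    total = len(significant_ids)
    ratio = {g: c / total for g, c in freq.items()}
    return FunctionalGroupProfile(comparison, freq, ratio, total,
                                  tuple(priority))
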