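"""Synthetic VOC cohort generator and the stratified run-order utility.

Real urine-headspace GC-MS cohorts are not bundled with this package, so the
generator emulates the statistical structure the analysis pipeline assumes:

* log-normal integrated signals (positive, right-skewed) with per-feature
  baseline log-means drawn over several orders of magnitude;
* multiplicative class effects on a minority of *informative* features,
  expressed as log2 fold changes with a configurable up-regulated fraction;
* a per-sample multiplicative dilution factor (urine concentration nuisance)
  that relative-abundance normalization removes exactly;
* limit-of-detection censoring — signals below a global quantile threshold
  are recorded as 0, producing class-structured missingness on raw data;
* planted nuisance features: high retention-time-spread (misaligned) features
  and flagged exogenous contaminants, which screening should remove.

Scenario presets mirror the cohorts the pipeline is designed around: a small
mouse experiment (8 controls vs 9 tumor-bearing, 161 features, large effects,
low intraclass variance) and a human biopsy cohort (67 negative vs 95 positive
with ISUP grades 38/30/8/5/14 across 1-5, 367 features, moderate effects, high
intraclass variance), plus a ``null`` scenario with no planted effects for
type-I-error checks.  Every draw is bit-reproducible given the seed; the
signal, dilution, feature and metadata streams are independent, so switching
dilution off does not perturb the signal draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import FeatureMatrix, validate_metadata

__all__ = ["ScenarioConfig", "SyntheticTruth", "generate_cohort",
           "generate_run_order", "SCENARIOS"]

_HUMAN_GRADES = {0: 67, 1: 38, 2: 30, 3: 8, 4: 5, 5: 14}

_EXOGENOUS_NAMES = (
    "hexamethylcyclotrisiloxane", "octamethylcyclotetrasiloxane",
    "decamethylcyclopentasiloxane", "dibutyl phthalate",
    "diethyl phthalate", "bis(2-ethylhexyl) phthalate",
    "butylated hydroxytoluene", "2,4-di-tert-butylphenol",
)

#: Endogenous functional-group draw weights (roughly the mix reported for
#: urinary volatiles: cyclics, aromatics, ketones, terpenes and esters common).
_GROUP_WEIGHTS = {
    "nonaromatic_cyclic": 0.20, "aromatic": 0.18, "ketone": 0.18,
    "terpene_terpenoid": 0.14, "ester": 0.10, "alcohol": 0.08,
    "aldehyde": 0.07, "sulfur_containing": 0.05, "other": 0.00,
}

SCENARIOS = ("mouse_like", "human_screen", "human_aggressive", "null", "custom")


@dataclass
class ScenarioConfig:
    """Generator settings; use :meth:`for_scenario` for the preset defaults."""

    scenario: str = "custom"
    cohort: str = "human"                 # human | mouse
    grade_counts: dict = field(default_factory=lambda: dict(_HUMAN_GRADES))
    n_control: int = 8                    # mouse only
    n_tumor: int = 9                      # mouse only
    comparison: str = "cancer_vs_none"    # which labeling carries the effect
    n_features: int = 367
    n_informative: int = 6
    log2_fc: float = 1.0                  # effect magnitude, log2 scale
    up_fraction: float = 0.7              # fraction of informative features up
    baseline_log_mean_range: tuple = (9.0, 16.0)  # natural-log signal units
    intraclass_log_sd: float = 0.8
    dilution_log_sd: float = 0.5          # 0 disables dilution
    lod_quantile: float | None = 0.05     # None disables censoring
    n_high_rt_spread: int = 8
    n_exogenous: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        n_special = self.n_high_rt_spread + self.n_exogenous
        if self.n_informative + n_special > self.n_features:
            raise ValueError("n_informative + planted nuisance features "
                             "exceed n_features")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ValueError("up_fraction must lie in [0, 1]")
        if self.lod_quantile is not None and not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError("lod_quantile must lie in [0, 1)")
        if self.cohort == "mouse" and (self.n_control < 2 or self.n_tumor < 2):
            raise ValueError("mouse classes need at least 2 samples")

    @classmethod
    def for_scenario(cls, name: str, seed: int = 0, **overrides) -> "ScenarioConfig":
        presets = {
            "mouse_like": dict(
                cohort="mouse", comparison="tumor_vs_control",
                n_control=8, n_tumor=9, n_features=161, n_informative=16,
                log2_fc=2.0, up_fraction=0.6, intraclass_log_sd=0.25,
                dilution_log_sd=0.3, lod_quantile=0.05,
                n_high_rt_spread=6, n_exogenous=4),
            "human_screen": dict(
                cohort="human", comparison="cancer_vs_none",
                n_features=367, n_informative=6, log2_fc=1.0,
                up_fraction=0.7, intraclass_log_sd=0.8, dilution_log_sd=0.5,
                lod_quantile=0.05, n_high_rt_spread=8, n_exogenous=6),
            "human_aggressive": dict(
                cohort="human", comparison="aggressive_vs_rest",
                n_features=367, n_informative=6, log2_fc=1.0,
                up_fraction=0.3, intraclass_log_sd=0.8, dilution_log_sd=0.5,
                lod_quantile=0.05, n_high_rt_spread=8, n_exogenous=6),
            "null": dict(
                cohort="human", comparison="cancer_vs_none",
                n_features=367, n_informative=0, log2_fc=0.0,
                intraclass_log_sd=0.8, dilution_log_sd=0.5,
                lod_quantile=None, n_high_rt_spread=0, n_exogenous=0),
            "custom": {},
        }
        if name not in presets:
            raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
        kwargs = dict(presets[name])
        kwargs.update(overrides)
        return cls(scenario=name, seed=seed, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort, for recovery tests."""

    informative_ids: tuple
    directions: dict          # feature_id -> +1 (up in cases) or -1
    log2_fc: float
    dilution: pd.Series       # sample_id -> multiplicative factor
    censor_threshold: float | None
    exogenous_ids: tuple
    high_rt_spread_ids: tuple
    case_sample_ids: tuple

    def to_dict(self) -> dict:
        return {
            "informative_ids": list(self.informative_ids),
            "directions": {k: int(v) for k, v in self.directions.items()},
            "log2_fc": self.log2_fc,
            "dilution": {k: float(v) for k, v in self.dilution.items()},
            "censor_threshold": self.censor_threshold,
            "exogenous_ids": list(self.exogenous_ids),
            "high_rt_spread_ids": list(self.high_rt_spread_ids),
            "case_sample_ids": list(self.case_sample_ids),
        }


def _case_mask(config: ScenarioConfig, meta: pd.DataFrame) -> np.ndarray:
    if config.comparison == "tumor_vs_control":
        return (meta["tumor_status"] == "tumor").to_numpy()
    grades = meta["isup_grade"].astype(int).to_numpy()
    cut = 1 if config.comparison == "cancer_vs_none" else 3
    return grades >= cut


def generate_cohort(config: ScenarioConfig):
    """Draw one cohort; returns ``(FeatureMatrix, metadata DataFrame, SyntheticTruth)``.

    Signals: ``exp(baseline + effect + N(0, intraclass_log_sd)) * dilution``,
    where the effect ``direction * ln(2) * log2_fc`` applies to informative
    features in case samples; censoring then zeroes signals below the global
    ``lod_quantile`` threshold.  Informative features draw their baselines from
    the upper three quarters of the baseline range so that planted biomarkers
    are consistently detected (a mostly-censored feature could never be
    recovered by any screening pipeline).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_feat, rng_sig, rng_dil, rng_meta = (np.random.default_rng(c)
                                            for c in ss.spawn(4))
    nf = config.n_features

    # ---- metadata -------------------------------------------------------
    if config.cohort == "mouse":
        n = config.n_control + config.n_tumor
        status = np.array(["control"] * config.n_control
                          + ["tumor"] * config.n_tumor, dtype=object)
        rng_meta.shuffle(status)
        meta = pd.DataFrame({
            "sample_id": [f"M{i + 1:03d}" for i in range(n)],
            "cohort": "mouse",
            "isup_grade": np.nan,
            "tumor_status": status,
        })
    else:
        grades = np.concatenate([
            np.full(cnt, g) for g, cnt in sorted(config.grade_counts.items())
        ])
        rng_meta.shuffle(grades)
        n = len(grades)
        meta = pd.DataFrame({
            "sample_id": [f"S{i + 1:03d}" for i in range(n)],
            "cohort": "human",
            "isup_grade": grades.astype(int),
            "tumor_status": pd.NA,
        })
    validate_metadata(meta)
    case = _case_mask(config, meta)
    if config.n_informative > 0 and (case.sum() < 2 or (~case).sum() < 2):
        raise ValueError("comparison leaves a class with < 2 samples")

    # ---- feature roles --------------------------------------------------
    feature_ids = np.array([f"V{i + 1:04d}" for i in range(nf)], dtype=object)
    roles = rng_feat.permutation(nf)
    hi_rt = np.sort(roles[:config.n_high_rt_spread])
    exo = np.sort(roles[config.n_high_rt_spread:
                        config.n_high_rt_spread + config.n_exogenous])
    clean = roles[config.n_high_rt_spread + config.n_exogenous:]
    informative = np.sort(clean[:config.n_informative])

    rt_mean = rng_feat.uniform(2.0, 30.0, nf)
    rt_spread = np.minimum(np.abs(rng_feat.normal(0.0, 0.03, nf)), 0.09)
    rt_spread[hi_rt] = rng_feat.uniform(0.15, 0.50, len(hi_rt))

    lo, hi = config.baseline_log_mean_range
    baseline = rng_feat.uniform(lo, hi, nf)
    baseline[informative] = rng_feat.uniform(lo + 0.25 * (hi - lo), hi,
                                             len(informative))
    direction = np.where(rng_feat.random(len(informative)) < config.up_fraction,
                         1, -1)

    groups = rng_feat.choice(list(_GROUP_WEIGHTS), size=nf,
                             p=np.array(list(_GROUP_WEIGHTS.values()))
                             / sum(_GROUP_WEIGHTS.values()))
    compound_names = np.array([f"compound_{fid}" for fid in feature_ids],
                              dtype=object)
    compound_names[exo] = [
        _EXOGENOUS_NAMES[i % len(_EXOGENOUS_NAMES)] for i in range(len(exo))]
    is_exo = np.zeros(nf, dtype=int)
    is_exo[exo] = 1
    annotations = pd.DataFrame({
        "compound_name": compound_names,
        "functional_group": groups,
        "is_exogenous": is_exo,
    }, index=pd.Index(feature_ids, name="feature_id"))

    # ---- signals --------------------------------------------------------
    loc = np.tile(baseline[:, None], (1, n))
    effect = np.log(2.0) * config.log2_fc
    for j, f in enumerate(informative):
        loc[f, case] += direction[j] * effect
    log_signal = loc + rng_sig.normal(0.0, config.intraclass_log_sd, (nf, n))
    signals = np.exp(log_signal)

    if config.dilution_log_sd > 0:
        dilution = np.exp(rng_dil.normal(0.0, config.dilution_log_sd, n))
    else:
        dilution = np.ones(n)
    signals = signals * dilution

    threshold = None
    if config.lod_quantile:
        threshold = float(np.quantile(signals, config.lod_quantile))
        signals = np.where(signals < threshold, 0.0, signals)

    fm = FeatureMatrix(feature_ids, meta["sample_id"].to_numpy(dtype=object),
                       signals, rt_mean, rt_spread, annotations)
    truth = SyntheticTruth(
        informative_ids=tuple(feature_ids[informative]),
        directions={feature_ids[f]: int(d)
                    for f, d in zip(informative, direction)},
        log2_fc=config.log2_fc,
        dilution=pd.Series(dilution, index=meta["sample_id"].to_numpy()),
        censor_threshold=threshold,
        exogenous_ids=tuple(feature_ids[exo]),
        high_rt_spread_ids=tuple(feature_ids[hi_rt]),
        case_sample_ids=tuple(meta["sample_id"].to_numpy()[case]),
    )
    return fm, meta, truth


# ----------------------------------------------------------------- run order


def generate_run_order(meta: pd.DataFrame, seed: int = 0):
    """Randomized run order in which no two consecutive samples share a grade.

    Samples are keyed by ISUP grade (human) or tumor status (mouse).  Feasible
    whenever the largest key count is at most ceil(n/2); otherwise the order
    is best-effort and the adjacency violations are counted, never raised.
    Returns ``(ordered sample_ids, n_violations)``.
    """
    validate_metadata(meta)
    rng = np.random.default_rng(seed)
    keys = np.where(meta["cohort"] == "mouse",
                    "mouse:" + meta["tumor_status"].astype(str),
                    "human:" + meta["isup_grade"].astype("Int64").astype(str))
    queues: dict[str, list] = {}
    for sid, key in zip(meta["sample_id"], keys):
        queues.setdefault(key, []).append(sid)
    for q in queues.values():
        rng.shuffle(q)
    counts = {k: len(q) for k, q in queues.items()}

    order: list = []
    violations = 0
    prev = None
    remaining = sum(counts.values())
    while remaining:
        # a key holding a strict majority of what remains must be placed now
        forced = [k for k, c in counts.items() if c > remaining // 2]
        candidates = [k for k, c in counts.items() if c > 0 and k != prev]
        if forced and forced[0] != prev:
            pick = forced[0]
        elif candidates:
            weights = np.array([counts[k] for k in candidates], dtype=float)
            pick = candidates[rng.choice(len(candidates),
                                         p=weights / weights.sum())]
        else:  # only the previous key is left
            pick = prev
            violations += 1
        order.append(queues[pick].pop())
        counts[pick] -= 1
        prev = pick
        remaining -= 1
    return order, violations
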