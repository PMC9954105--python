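"""End-to-end pipeline: screening -> univariate -> PCA -> panel selection ->
hold-out validation -> functional groups, with a reproducibility manifest.

A single master seed is fanned out deterministically to per-stage seeds which
are recorded in the manifest, so any stage can be replayed in isolation; with
identical configuration and seed every artifact is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .feature_table import (binarize_labels, read_exclusion_list,
                            read_feature_table, read_sample_metadata,
                            write_feature_table, write_sample_metadata)
from .functional_groups import group_profile
from .panel_selection import (SearchConfig, forward_select,
                              perturbation_validate, training_metrics)
from .pca import pc_class_significance, pca_fit, pca_separation_accuracy
from .preprocessing import ScreeningConfig, screen
from .synthetic import ScenarioConfig, generate_cohort
from .univariate import univariate_table

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger("vocchemo")

_STAGES = ("simulate", "screen", "univariate", "pca", "select", "validate",
           "fgroups")


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run (YAML-loadable)."""

    # inputs: either file paths or a synthetic scenario
    matrix: str | None = None
    meta: str | None = None
    scenario: str | None = None
    comparison: str = "cancer_vs_none"
    # screening
    max_rt_spread: float = 0.10
    presence_min_fraction: float = 0.5
    presence_mode: str = "any_class"
    exclude: str | None = None
    # univariate
    variant: str = "student"
    alpha: float = 0.05
    alpha_relaxed: float = 0.10
    # pca
    pca_subset: str = "p_lt_alpha"   # p_lt_alpha | top5_p | all
    pca_components: int = 2
    pca_scaling: str = "unit_variance"
    # panel selection
    mode: str = "auto"
    criterion: str = "cv_auc"
    folds: int = 5
    max_panel: int = 10
    pool_p: float | None = 0.10
    # validation
    n_reps: int = 1000
    holdout_fraction: float = 0.2
    # functional groups
    fgroups_alpha: float = 0.05
    # bookkeeping
    seed: int = 17
    outdir: str = "run_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if (self.matrix is None) != (self.meta is None):
            raise ValueError("matrix and meta paths must be given together")
        if self.matrix is None and self.scenario is None:
            raise ValueError("either input paths or a scenario is required")
        for name in ("alpha", "alpha_relaxed", "fgroups_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seeds: dict
    artifacts: dict = field(default_factory=dict)   # name -> sha256
    timings: dict = field(default_factory=dict)     # stage -> seconds
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _stage_seeds(master: int) -> dict:
    rng = np.random.default_rng(master)
    return {stage: int(rng.integers(2 ** 31)) for stage in _STAGES}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order, writing per-stage artifacts and a manifest.

    Any stage error aborts with the stage name; the partial manifest written
    so far is preserved in the output directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(config=asdict(config), version=__version__,
                           stage_seeds=seeds)

    def record(name: str, path: Path) -> None:
        manifest.artifacts[name] = _sha256(path)

    def finish(stage: str, t0: float) -> None:
        manifest.timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", stage, manifest.timings[stage])

    stage = "inputs"
    try:
        t0 = time.perf_counter()
        if config.scenario is not None and config.matrix is None:
            stage = "simulate"
            scen = ScenarioConfig.for_scenario(config.scenario,
                                               seed=seeds["simulate"])
            fm, meta, truth = generate_cohort(scen)
            write_feature_table(fm, outdir / "input_matrix.csv")
            write_sample_metadata(meta, outdir / "input_meta.csv")
            _dump_json(truth.to_dict(), outdir / "input_truth.json")
            record("input_matrix.csv", outdir / "input_matrix.csv")
            record("input_meta.csv", outdir / "input_meta.csv")
            record("input_truth.json", outdir / "input_truth.json")
        else:
            fm = read_feature_table(config.matrix)
            meta = read_sample_metadata(config.meta)
        cmp = binarize_labels(meta, config.comparison)
        finish("inputs", t0)

        stage = "screen"
        t0 = time.perf_counter()
        exclusion = (read_exclusion_list(config.exclude)
                     if config.exclude else set())
        screened, report = screen(fm, cmp, ScreeningConfig(
            config.max_rt_spread, config.presence_min_fraction,
            config.presence_mode, exclusion))
        write_feature_table(screened, outdir / "screened.csv")
        _dump_json(report.to_dict(), outdir / "screening_report.json")
        record("screened.csv", outdir / "screened.csv")
        record("screening_report.json", outdir / "screening_report.json")
        finish(stage, t0)

        stage = "univariate"
        t0 = time.perf_counter()
        table, counts = univariate_table(
            screened, cmp, variant=config.variant,
            thresholds=(config.alpha, config.alpha_relaxed), bh_column=True)
        table.to_csv(outdir / "univariate.csv", index=False)
        _dump_json({f"n_p_lt_{thr}": c for thr, c in counts.items()},
                   outdir / "univariate_summary.json")
        record("univariate.csv", outdir / "univariate.csv")
        record("univariate_summary.json", outdir / "univariate_summary.json")
        finish(stage, t0)

        stage = "pca"
        t0 = time.perf_counter()
        if config.pca_subset == "top5_p":
            subset_ids = table.nsmallest(5, "p_value")["feature_id"]
        elif config.pca_subset == "p_lt_alpha":
            subset_ids = table.loc[table["p_value"] < config.alpha, "feature_id"]
        elif config.pca_subset == "all":
            subset_ids = table["feature_id"]
        else:
            raise ValueError(f"unknown pca_subset {config.pca_subset!r}")
        pca_out: dict = {"subset": list(subset_ids),
                         "n_features": len(subset_ids)}
        if len(subset_ids) >= 2:
            sub = screened.subset_features(list(subset_ids))
            k = min(config.pca_components, min(sub.n_features,
                                               sub.n_samples - 1))
            res = pca_fit(sub, n_components=k, scaling=config.pca_scaling)
            pd.DataFrame(res.scores,
                         index=pd.Index(res.sample_ids, name="sample_id"),
                         columns=[f"PC{i + 1}" for i in range(k)]
                         ).to_csv(outdir / "pca_scores.csv")
            pca_out.update({
                "explained_fraction": [float(v) for v in res.explained_fraction],
                "pc1_p_value": pc_class_significance(res, cmp, 0),
                "separation_accuracy": pca_separation_accuracy(res, cmp, k),
            })
            record("pca_scores.csv", outdir / "pca_scores.csv")
        else:
            manifest.warnings.append("pca skipped: subset has < 2 features")
        _dump_json(pca_out, outdir / "pca_summary.json")
        record("pca_summary.json", outdir / "pca_summary.json")
        finish(stage, t0)

        stage = "select"
        t0 = time.perf_counter()
        search = forward_select(screened, cmp, SearchConfig(
            mode=config.mode, criterion=config.criterion, folds=config.folds,
            max_size=config.max_panel, pool_p=config.pool_p,
            seed=seeds["select"]))
        _dump_json(search.to_dict(), outdir / "panel.json")
        record("panel.json", outdir / "panel.json")
        finish(stage, t0)

        stage = "validate"
        t0 = time.perf_counter()
        panel = list(search.final_panel)
        train = training_metrics(panel, screened, cmp)
        summary = perturbation_validate(panel, screened, cmp,
                                        n_reps=config.n_reps,
                                        holdout_fraction=config.holdout_fraction,
                                        seed=seeds["validate"])
        pd.DataFrame({"fpr": summary.fpr_grid, "mean_tpr": summary.mean_tpr}
                     ).to_csv(outdir / "roc.csv", index=False)
        _dump_json({"training": train.to_dict(),
                    "holdout": summary.to_dict(), "panel": panel},
                   outdir / "validation.json")
        record("roc.csv", outdir / "roc.csv")
        record("validation.json", outdir / "validation.json")
        finish(stage, t0)

        stage = "fgroups"
        t0 = time.perf_counter()
        has_ann = (screened.annotations is not None
                   and "functional_group" in screened.annotations.columns)
        sig = table.loc[table["p_value"] < config.fgroups_alpha, "feature_id"]
        if has_ann and len(sig):
            profile = group_profile(list(sig), screened.annotations,
                                    comparison=config.comparison)
            profile.to_frame().to_csv(outdir / "fgroups.csv", index=False)
            record("fgroups.csv", outdir / "fgroups.csv")
        else:
            manifest.warnings.append(
                "fgroups skipped: no annotations or no significant features")
        finish(stage, t0)
    except Exception as exc:
        (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
        raise RuntimeError(f"pipeline aborted at stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
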