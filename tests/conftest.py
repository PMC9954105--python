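import numpy as np
import pandas as pd
import pytest

from vocchemo import (BinaryComparison, FeatureMatrix, ScenarioConfig,
                      binarize_labels, generate_cohort, screen,
                      univariate_table)


def make_fm(signals, rt_spread=None, rt_mean=None, annotations=None,
            feature_ids=None, sample_ids=None):
    """Small helper to build a FeatureMatrix from a 2-D array."""
    signals = np.asarray(signals, dtype=float)
    nf, ns = signals.shape
    if feature_ids is None:
        feature_ids = [f"F{i + 1}" for i in range(nf)]
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(ns)]
    if rt_mean is None:
        rt_mean = np.linspace(5.0, 20.0, nf)
    if rt_spread is None:
        rt_spread = np.full(nf, 0.02)
    return FeatureMatrix(feature_ids, sample_ids, signals, rt_mean, rt_spread,
                         annotations)


def make_cmp(labels, sample_ids=None, name="tumor_vs_control"):
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(len(labels))]
    return BinaryComparison(name, pd.Series(list(labels), index=sample_ids))


@pytest.fixture
def toy_fm():
    return make_fm([[2.0, 1.0, 4.0, 3.0],
                    [3.0, 5.0, 1.0, 2.0],
                    [5.0, 4.0, 5.0, 5.0]])


@pytest.fixture(scope="session")
def mouse_cohort():
    """One screened mouse-like cohort shared by read-only tests."""
    fm, meta, truth = generate_cohort(ScenarioConfig.for_scenario(
        "mouse_like", seed=42))
    cmp = binarize_labels(meta, "tumor_vs_control")
    screened, report = screen(fm, cmp)
    table, counts = univariate_table(screened, cmp)
    return dict(fm=fm, meta=meta, truth=truth, cmp=cmp, screened=screened,
                report=report, table=table, counts=counts)


@pytest.fixture(scope="session")
def human_cohort():
    """One screened human screening cohort shared by read-only tests."""
    fm, meta, truth = generate_cohort(ScenarioConfig.for_scenario(
        "human_screen", seed=42))
    cmp = binarize_labels(meta, "cancer_vs_none")
    screened, report = screen(fm, cmp)
    table, counts = univariate_table(screened, cmp)
    return dict(fm=fm, meta=meta, truth=truth, cmp=cmp, screened=screened,
                report=report, table=table, counts=counts)
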