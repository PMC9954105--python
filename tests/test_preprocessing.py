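import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocchemo import (Screener, ScreeningConfig, filter_exclusion,
                      filter_presence, filter_rt_spread,
                      normalize_relative_abundance, screen)

from conftest import make_cmp, make_fm


class TestRTSpreadFilter:
    def test_threshold_boundary(self):
        fm = make_fm(np.ones((3, 2)), rt_spread=[0.01, 0.05, 0.30])
        out = filter_rt_spread(fm, 0.10)
        assert list(out.feature_ids) == ["F1", "F2"]
        assert list(out.sample_ids) == list(fm.sample_ids)

    def test_infinite_threshold_is_identity(self):
        fm = make_fm(np.ones((3, 2)), rt_spread=[0.01, 0.5, 2.0])
        assert filter_rt_spread(fm, math.inf).equals(fm)

    def test_all_removed_gives_empty_matrix(self):
        fm = make_fm(np.ones((2, 2)), rt_spread=[0.5, 0.9])
        assert filter_rt_spread(fm, 0.10).n_features == 0


class TestPresenceFilter:
    def setup_method(self):
        # feature detected in 2/4 reference samples, 0/4 case samples
        sig = np.zeros((1, 8))
        sig[0, :2] = 5.0
        self.fm = make_fm(sig, sample_ids=[f"s{i}" for i in range(8)])
        self.cmp = make_cmp([0, 0, 0, 0, 1, 1, 1, 1],
                            sample_ids=[f"s{i}" for i in range(8)])

    def test_any_class_keeps_half_present(self):
        out = filter_presence(self.fm, self.cmp, 0.5, "any_class")
        assert out.n_features == 1

    def test_all_classes_removes_it(self):
        out = filter_presence(self.fm, self.cmp, 0.5, "all_classes")
        assert out.n_features == 0

    def test_zero_fraction_is_identity(self):
        out = filter_presence(self.fm, self.cmp, 0.0, "any_class")
        assert out.equals(self.fm)

    def test_multiclass_partition_accepted(self):
        labels = pd.Series(["a", "a", "b", "b", "c", "c", "d", "d"],
                           index=[f"s{i}" for i in range(8)])
        out = filter_presence(self.fm, labels, 0.5, "any_class")
        assert out.n_features == 1  # detected in 2/2 of class "a"


class TestExclusionFilter:
    def test_exogenous_flag_removed_with_empty_list(self):
        ann = pd.DataFrame({"compound_name": ["x", "y"],
                            "is_exogenous": [1, 0]},
                           index=pd.Index(["F1", "F2"], name="feature_id"))
        fm = make_fm(np.ones((2, 2)), annotations=ann)
        out = filter_exclusion(fm, set())
        assert list(out.feature_ids) == ["F2"]

    def test_compound_name_match_removed(self):
        ann = pd.DataFrame({"compound_name": ["dibutyl phthalate", "acetone"],
                            "is_exogenous": [0, 0]},
                           index=pd.Index(["F1", "F2"], name="feature_id"))
        fm = make_fm(np.ones((2, 2)), annotations=ann)
        out = filter_exclusion(fm, {"dibutyl phthalate"})
        assert list(out.feature_ids) == ["F2"]

    def test_no_flags_no_list_is_identity(self):
        fm = make_fm(np.ones((2, 2)))
        assert filter_exclusion(fm, set()).equals(fm)


class TestNormalization:
    def test_column_divided_by_total(self):
        fm = make_fm(np.array([[2.0], [3.0], [5.0]]))
        out = normalize_relative_abundance(fm)
        assert np.allclose(out.signals[:, 0], [0.2, 0.3, 0.5])

    def test_zeros_stay_zero(self):
        fm = make_fm(np.array([[0.0], [0.0], [7.0]]))
        out = normalize_relative_abundance(fm)
        assert list(out.signals[:, 0]) == [0.0, 0.0, 1.0]

    def test_all_zero_sample_errors_with_name(self):
        fm = make_fm(np.array([[0.0, 1.0], [0.0, 2.0]]))
        with pytest.raises(ValueError, match="s1"):
            normalize_relative_abundance(fm)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(1, 6), st.integers(1, 5), st.integers(0, 10 ** 6))
    def test_columns_sum_to_one(self, nf, ns, seed):
        rng = np.random.default_rng(seed)
        sig = rng.lognormal(5, 2, (nf, ns))
        out = normalize_relative_abundance(make_fm(sig))
        assert np.allclose(out.signals.sum(axis=0), 1.0, atol=1e-9)

    def test_scale_invariance_power_of_two_exact(self):
        rng = np.random.default_rng(0)
        sig = rng.lognormal(5, 2, (7, 4))
        scaled = sig * np.array([1.0, 8.0, 0.25, 2.0 ** 40])
        a = normalize_relative_abundance(make_fm(sig))
        b = normalize_relative_abundance(make_fm(scaled))
        assert np.array_equal(a.signals, b.signals)

    def test_scale_invariance_arbitrary_constant(self):
        rng = np.random.default_rng(1)
        sig = rng.lognormal(5, 2, (7, 4))
        scaled = sig * rng.lognormal(0, 1, 4)
        a = normalize_relative_abundance(make_fm(sig))
        b = normalize_relative_abundance(make_fm(scaled))
        np.testing.assert_allclose(a.signals, b.signals, rtol=1e-12)


def _screen_fixture():
    """6 features: 1 high RT spread, 1 low presence, 1 exogenous, 3 clean."""
    rng = np.random.default_rng(3)
    sig = rng.lognormal(5, 0.5, (6, 8))
    sig[1, :] = 0.0
    sig[1, 0] = 4.0  # detected in 1/4 of each class only
    sig[1, 4] = 4.0
    ann = pd.DataFrame({"compound_name": [f"c{i}" for i in range(6)],
                        "is_exogenous": [0, 0, 1, 0, 0, 0]},
                       index=pd.Index([f"F{i + 1}" for i in range(6)],
                                      name="feature_id"))
    fm = make_fm(sig, rt_spread=[0.4, 0.02, 0.02, 0.02, 0.02, 0.02],
                 annotations=ann, sample_ids=[f"s{i}" for i in range(8)])
    cmp = make_cmp([0, 0, 0, 0, 1, 1, 1, 1],
                   sample_ids=[f"s{i}" for i in range(8)])
    return fm, cmp


class TestScreenCascade:
    def test_composed_rules_and_report(self):
        fm, cmp = _screen_fixture()
        out, report = screen(fm, cmp, ScreeningConfig())
        assert report.removed == {"rt_spread": 1, "presence": 1, "exclusion": 1}
        assert report.retained == 3
        assert out.n_features == 3
        assert sum(report.removed.values()) + report.retained == fm.n_features
        assert np.allclose(out.signals.sum(axis=0), 1.0, atol=1e-9)

    def test_disabled_rules_reduce_to_normalization(self):
        fm, cmp = _screen_fixture()
        fm = fm.subset_features([f for f in fm.feature_ids if f != "F3"])
        cfg = ScreeningConfig(max_rt_spread=math.inf, presence_min_fraction=0.0)
        out, report = screen(fm, cmp, cfg)
        assert report.retained == fm.n_features
        assert out.equals(normalize_relative_abundance(fm))

    def test_screen_is_idempotent_on_retained_set(self):
        fm, cmp = _screen_fixture()
        once, _ = screen(fm, cmp)
        twice, rep2 = screen(once, cmp)
        assert list(twice.feature_ids) == list(once.feature_ids)
        assert sum(rep2.removed.values()) == 0

    def test_retained_set_independent_of_row_order(self):
        fm, cmp = _screen_fixture()
        perm = [4, 2, 0, 5, 1, 3]
        shuffled = fm.subset_features([fm.feature_ids[i] for i in perm])
        a, _ = screen(fm, cmp)
        b, _ = screen(shuffled, cmp)
        assert set(a.feature_ids) == set(b.feature_ids)


class TestScreenerEstimator:
    def test_fit_transform_matches_screen(self):
        fm, cmp = _screen_fixture()
        est = Screener()
        out = est.fit_transform(fm, cmp)
        direct, report = screen(fm, cmp)
        assert out.equals(direct)
        assert est.report_.removed == report.removed

    def test_transform_applies_learned_retention(self):
        fm, cmp = _screen_fixture()
        est = Screener().fit(fm, cmp)
        again = est.transform(fm)
        assert list(again.feature_ids) == est.retained_ids_

    def test_sklearn_param_interface(self):
        est = Screener(max_rt_spread=0.2)
        assert est.get_params()["max_rt_spread"] == 0.2
        est.set_params(presence_mode="all_classes")
        assert est._config().presence_mode == "all_classes"
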