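from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocchemo import (FisherLDA, ForwardPanelSelector, ROCSummary,
                      SearchConfig, cv_criterion, fit_lda, forward_select,
                      lda_scores, perturbation_validate, roc_and_auc,
                      training_metrics, youden_operating_point)
from vocchemo.panel_selection import ROCCurve, _make_folds, _pooled_cv_metric

from conftest import make_cmp, make_fm


def planted_pool(seed=0, n=40, m=8, informative=(0, 1, 2), shift=2.0):
    """Noise pool with a few informative features shifted between classes."""
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n // 2, dtype=int), np.ones(n - n // 2, dtype=int)]
    X = rng.normal(0, 1, (n, m))
    for f in informative:
        if f < m:
            X[y == 1, f] += shift
    return X, y


class TestFisherLDA:
    def test_separable_single_feature(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        model = FisherLDA().fit(X, y)
        assert model.weights_[0] > 0
        assert (model.predict(X) == y).all()

    def test_identical_class_means_degenerate(self):
        X = np.array([[0.0], [2.0], [0.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="degenerate"):
            model = FisherLDA().fit(X, y)
        assert model.degenerate_
        np.testing.assert_allclose(model.weights_, 0.0, atol=1e-9)

    def test_hand_computed_weights_diagonal_covariance(self):
        # pooled covariance diag(1, 4), mean difference (1, 1) -> w ~ (1, 0.25)
        rng = np.random.default_rng(0)
        n = 20000
        X0 = rng.normal(0, 1, (n, 2)) * np.array([1.0, 2.0])
        X1 = X0[n // 2:] + np.array([1.0, 1.0])
        X = np.vstack([X0[: n // 2], X1])
        y = np.r_[np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)]
        model = fit_lda(X, y, ridge_lambda=1e-12)
        ratio = model.weights[1] / model.weights[0]
        assert ratio == pytest.approx(0.25, abs=0.02)

    def test_singular_covariance_without_ridge_instructs(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="ridge"):
            fit_lda(X, y, ridge_lambda=0.0)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            fit_lda(np.ones((3, 1)) * np.arange(3)[:, None],
                    np.array([0, 1, 1]))

    def test_offset_is_midpoint(self):
        X, y = planted_pool(seed=1, m=3)
        model = fit_lda(X, y)
        mid = (model.class_means[0] + model.class_means[1]) / 2
        assert lda_scores(model, mid[None, :])[0] == pytest.approx(0.0, abs=1e-12)


class TestLDAScores:
    def test_feature_rescaling_preserves_ranking(self):
        X, y = planted_pool(seed=2, m=4)
        m1 = fit_lda(X, y, ridge_lambda=1e-12)
        Xs = X * np.array([10.0, 1.0, 0.1, 1.0])
        m2 = fit_lda(Xs, y, ridge_lambda=1e-12)
        r1 = np.argsort(lda_scores(m1, X))
        r2 = np.argsort(lda_scores(m2, Xs))
        assert np.array_equal(r1, r2)

    def test_empty_input_gives_empty_scores(self):
        X, y = planted_pool(seed=3, m=2)
        model = fit_lda(X, y)
        assert lda_scores(model, np.empty((0, 2))).shape == (0,)

    def test_dimension_mismatch(self):
        X, y = planted_pool(seed=3, m=2)
        model = fit_lda(X, y)
        with pytest.raises(ValueError):
            lda_scores(model, np.ones((3, 5)))


class TestROC:
    def test_perfect_separation(self):
        _, auc = roc_and_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 1, 2000)
        y = rng.integers(0, 2, 2000)
        _, auc = roc_and_auc(scores, y)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_ties_get_half_credit(self):
        # all scores equal: AUC must be exactly 1/2 (single diagonal segment)
        _, auc = roc_and_auc([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
        assert auc == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc([1.0, 2.0], [1, 1])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_auc_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.normal(0, 1, n), 1)  # ties likely
        y = np.r_[0, 1, rng.integers(0, 2, n - 2)]
        _, a = roc_and_auc(scores, y)
        _, b = roc_and_auc(-scores, y)
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestYouden:
    def test_perfect_roc(self):
        roc, _ = roc_and_auc([0.1, 0.9], [0, 1])
        sens, spec, _ = youden_operating_point(roc)
        assert (sens, spec) == (1.0, 1.0)

    def test_diagonal_roc_tie_breaks_to_high_specificity(self):
        roc = ROCCurve(np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]),
                       np.array([np.inf, 0.5, 0.0]))
        sens, spec, _ = youden_operating_point(roc)
        assert spec == 1.0 and sens == 0.0

    def test_hand_built_three_point_curve(self):
        # J values: 0.2, 0.5, 0.3 -> middle point wins
        roc = ROCCurve(np.array([0.1, 0.3, 0.5]), np.array([0.3, 0.8, 0.8]),
                       np.array([3.0, 2.0, 1.0]))
        sens, spec, thr = youden_operating_point(roc)
        assert (sens, spec, thr) == (0.8, 0.7, 2.0)


class TestCVCriterion:
    def _fm_cmp(self, X, y):
        ns = len(y)
        X = X - X.min() + 1.0  # signals must be nonnegative
        fm = make_fm(X.T, sample_ids=[f"s{i}" for i in range(ns)])
        cmp = make_cmp(y, sample_ids=[f"s{i}" for i in range(ns)])
        return fm, cmp

    def test_separable_panel_near_one(self):
        X, y = planted_pool(seed=4, shift=6.0)
        fm, cmp = self._fm_cmp(X, y)
        assert cv_criterion(["F1", "F2", "F3"], fm, cmp, seed=0) > 0.95

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(5)
        X, y = planted_pool(seed=5, n=200, shift=0.0)
        fm, cmp = self._fm_cmp(X, rng.permutation(y))
        assert 0.3 < cv_criterion(["F1", "F2", "F3"], fm, cmp, seed=0) < 0.7

    def test_bit_identical_repeat(self):
        X, y = planted_pool(seed=6)
        fm, cmp = self._fm_cmp(X, y)
        a = cv_criterion(["F1", "F4", "F5"], fm, cmp, seed=9)
        b = cv_criterion(["F1", "F4", "F5"], fm, cmp, seed=9)
        assert a == b

    def test_class_smaller_than_folds(self):
        X, y = planted_pool(seed=7, n=8)
        fm, cmp = self._fm_cmp(X, y)
        with pytest.raises(ValueError, match="folds"):
            cv_criterion(["F1", "F2", "F3"], fm, cmp, folds=5)

    def test_fold_cache_matches_reference_path(self):
        # the fast submatrix evaluator must agree with the plain per-panel CV
        from vocchemo.panel_selection import _FoldCache

        X, y = planted_pool(seed=8, m=6)
        folds = _make_folds(y, 5, 3)
        cache = _FoldCache(X, y, folds, ridge=1e-6)
        for panel in combinations(range(6), 3):
            slow = _pooled_cv_metric(X[:, panel], y, folds, 1e-6, "cv_auc")
            fast = cache.metric(panel, "cv_auc")
            assert fast == pytest.approx(slow, abs=1e-12)


class TestForwardSelect:
    def test_planted_triple_recovered(self):
        X, y = planted_pool(seed=10, n=60, m=8, shift=2.5)
        sel = ForwardPanelSelector(max_size=3, seed=1).fit(X, y)
        assert sel.panel_ids_ == ("f0", "f1", "f2")
        assert sel.stages_[0]["mode"] == "exhaustive_3"

    def test_pool_of_exactly_three(self):
        X, y = planted_pool(seed=11, m=3)
        sel = ForwardPanelSelector(seed=1).fit(X, y)
        assert len(sel.panel_ids_) == 3
        assert sel.stopping_reason_ in ("no_improvement", "max_size")

    def test_pool_below_three_rejected(self):
        X, y = planted_pool(seed=12, m=2)
        with pytest.raises(ValueError, match=">= 3"):
            ForwardPanelSelector().fit(X, y)

    def test_reserve_one_candidates_are_supersets_intersecting_panel(self):
        sel = ForwardPanelSelector()
        panel = (1, 4, 6)
        cands = sel._reserve_one_candidates(panel, m=9)
        expected = sorted(tuple(sorted(c)) for c in combinations(range(9), 4)
                          if set(c) & set(panel))
        assert cands == expected

    def test_swap_add_candidates_structure(self):
        sel = ForwardPanelSelector()
        panel = (0, 1, 2)
        cands = set(sel._swap_add_candidates(panel, m=6))
        assert tuple(sorted(panel + (4,))) in cands      # pure addition
        assert (0, 1, 4, 5) in cands                     # drop 2, add 4+5
        assert all(len(c) == 4 for c in cands)
        assert all(len(set(c) & set(panel)) >= 2 for c in cands)

    def test_budget_exceeded_in_forced_reserve_one(self):
        X, y = planted_pool(seed=13, n=60, m=12, shift=2.0)
        with pytest.raises(ValueError, match="budget"):
            ForwardPanelSelector(mode="reserve_one", budget=10,
                                 max_size=5, seed=1).fit(X, y)

    def test_determinism_same_seed(self):
        X, y = planted_pool(seed=14, m=7, shift=1.0)
        a = ForwardPanelSelector(seed=5, max_size=5).fit(X, y)
        b = ForwardPanelSelector(seed=5, max_size=5).fit(X, y)
        assert a.panel_ids_ == b.panel_ids_
        assert a.result_.to_dict() == b.result_.to_dict()

    def test_stage_sizes_increase_by_one_from_three(self):
        X, y = planted_pool(seed=15, m=8, shift=1.5)
        sel = ForwardPanelSelector(seed=2, max_size=6).fit(X, y)
        sizes = [len(s["panel"]) for s in sel.stages_]
        assert sizes == list(range(3, 3 + len(sizes)))
        assert all("criterion" in s for s in sel.stages_)

    def test_feature_rescaling_leaves_panel_unchanged(self):
        X, y = planted_pool(seed=16, n=60, m=7, shift=1.5)
        a = ForwardPanelSelector(seed=3, max_size=4, ridge=1e-12).fit(X, y)
        scale = np.array([10.0, 0.1, 1.0, 5.0, 1.0, 2.0, 0.5])
        b = ForwardPanelSelector(seed=3, max_size=4, ridge=1e-12).fit(X * scale, y)
        assert a.panel_ids_ == b.panel_ids_

    def test_forward_select_wrapper_with_pool_filter(self, mouse_cohort):
        res = forward_select(mouse_cohort["screened"], mouse_cohort["cmp"],
                             SearchConfig(mode="swap_add", folds=3,
                                          max_size=4, pool_p=0.001, seed=1))
        assert len(res.final_panel) >= 3
        assert res.stages[0]["criterion"] <= 1.0


class TestPerturbationValidation:
    def _fm_cmp(self, X, y):
        ns = len(y)
        X = X - X.min() + 1.0  # signals must be nonnegative
        fm = make_fm(X.T, sample_ids=[f"s{i}" for i in range(ns)])
        cmp = make_cmp(y, sample_ids=[f"s{i}" for i in range(ns)])
        return fm, cmp

    def test_separable_panel_perfect_summary(self):
        X, y = planted_pool(seed=20, n=60, shift=8.0)
        fm, cmp = self._fm_cmp(X, y)
        out = perturbation_validate(["F1", "F2", "F3"], fm, cmp, n_reps=50,
                                    seed=1)
        assert out.auc == pytest.approx(1.0, abs=1e-9)
        assert out.sensitivity == 1.0 and out.specificity == 1.0

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(21)
        X, y = planted_pool(seed=21, n=200, shift=0.0)
        fm, cmp = self._fm_cmp(X, rng.permutation(y))
        out = perturbation_validate(["F1", "F2", "F3"], fm, cmp, n_reps=200,
                                    seed=2)
        assert out.auc == pytest.approx(0.5, abs=0.08)

    def test_repeat_with_same_seed_identical(self):
        X, y = planted_pool(seed=22, shift=1.0)
        fm, cmp = self._fm_cmp(X, y)
        a = perturbation_validate(["F1", "F2", "F3"], fm, cmp, n_reps=3, seed=7)
        b = perturbation_validate(["F1", "F2", "F3"], fm, cmp, n_reps=3, seed=7)
        assert a.to_dict() == b.to_dict()

    def test_mean_tpr_monotone(self):
        X, y = planted_pool(seed=23, shift=1.0)
        fm, cmp = self._fm_cmp(X, y)
        out = perturbation_validate(["F1", "F2", "F3"], fm, cmp, n_reps=25,
                                    seed=3)
        assert np.all(np.diff(out.mean_tpr) >= -1e-12)
        assert isinstance(out, ROCSummary)

    def test_invalid_holdout_fraction(self):
        X, y = planted_pool(seed=24)
        fm, cmp = self._fm_cmp(X, y)
        with pytest.raises(ValueError):
            perturbation_validate(["F1"], fm, cmp, holdout_fraction=1.5)


class TestTrainingMetrics:
    def test_separable_panel_full_auc(self):
        rng = np.random.default_rng(30)
        X = rng.normal(0, 1, (40, 3)) + 10.0
        y = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
        X[y == 1] += 10.0
        fm = make_fm(X.T, sample_ids=[f"s{i}" for i in range(40)])
        cmp = make_cmp(y, sample_ids=[f"s{i}" for i in range(40)])
        out = training_metrics(["F1", "F2", "F3"], fm, cmp)
        assert out.auc == 1.0 and out.n_reps == 0

    def test_empty_panel_rejected(self, mouse_cohort):
        with pytest.raises(ValueError, match="empty"):
            training_metrics([], mouse_cohort["screened"],
                             mouse_cohort["cmp"])
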