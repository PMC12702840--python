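"""Metrics, repeated trials, cross-validation and paired tests."""

import numpy as np
import pandas as pd
import pytest

import phenoview as pv
from phenoview.evaluation import (
    PairedTResult,
    ablation_study,
    cross_validate,
    macro_prf,
    ovr_auc,
    paired_t_test,
    relative_improvement,
    run_trials,
)


class TestMacroPRF:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        out = macro_prf(y, y)
        assert out["macro_f1"] == 1.0
        assert out["macro_precision"] == 1.0
        assert out["macro_recall"] == 1.0

    def test_toy_confusion_counts(self):
        # class 1: TP=2, FP=1, FN=1 -> P = R = F1 = 2/3
        y_true = np.array([1, 1, 1, 0, 0, 2])
        y_pred = np.array([1, 1, 0, 1, 0, 2])
        out = macro_prf(y_true, y_pred)
        assert out["precision"][1] == pytest.approx(2 / 3)
        assert out["recall"][1] == pytest.approx(2 / 3)
        assert out["f1"][1] == pytest.approx(2 / 3)

    def test_macro_is_unweighted_mean(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, 100)
        y_pred = rng.integers(0, 3, 100)
        out = macro_prf(y_true, y_pred)
        assert out["macro_f1"] == pytest.approx(np.mean(out["f1"]))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        perm = rng.permutation(60)
        a = macro_prf(y_true, y_pred)
        b = macro_prf(y_true[perm], y_pred[perm])
        assert np.allclose(a["f1"], b["f1"])
        assert a["macro_f1"] == pytest.approx(b["macro_f1"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            macro_prf(np.array([]), np.array([]))

    def test_absent_class_warns(self):
        with pytest.warns(UserWarning, match="absent"):
            macro_prf(np.array([0, 0, 1]), np.array([0, 0, 1]))


class TestOvrAuc:
    def test_perfectly_separating_scores(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        scores = np.eye(3)[y] * 0.9 + 0.05
        out = ovr_auc(y, scores)
        assert np.allclose(out["auc"], 1.0)
        assert out["macro_auc"] == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        n = 3000
        y = rng.integers(0, 3, n)
        scores = rng.dirichlet((1, 1, 1), size=n)
        out = ovr_auc(y, scores)
        for c in range(3):
            n1 = np.sum(y == c)
            n0 = n - n1
            se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
            assert abs(out["auc"][c] - 0.5) < 3 * se

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1, 2, 0, 1, 2, 0, 0, 1, 2])
        scores = rng.uniform(size=(10, 3))
        out = ovr_auc(y, scores)
        for c in range(3):
            pos = scores[y == c, c]
            neg = scores[y != c, c]
            wins = sum(
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in pos
                for q in neg
            )
            assert out["auc"][c] == pytest.approx(wins / (len(pos) * len(neg)))

    def test_macro_equals_unweighted_mean(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 3, 60)
        scores = rng.uniform(size=(60, 3))
        out = ovr_auc(y, scores)
        assert out["macro_auc"] == pytest.approx(np.mean(out["auc"]), abs=1e-12)

    def test_absent_class_excluded_with_warning(self):
        y = np.array([0, 0, 1, 1])
        scores = np.random.default_rng(0).uniform(size=(4, 3))
        with pytest.warns(UserWarning, match="class 2"):
            out = ovr_auc(y, scores)
        assert np.isnan(out["auc"][2])
        assert out["macro_auc"] == pytest.approx(np.nanmean(out["auc"]))


class TestRelativeImprovement:
    @pytest.mark.parametrize(
        "new,base,expected",
        [(0.531, 0.400, 32.8), (0.519, 0.398, 30.4), (0.652, 0.559, 16.6), (0.898, 0.838, 7.2)],
    )
    def test_reported_improvements(self, new, base, expected):
        assert relative_improvement(new, base) == expected

    def test_identity_gives_zero(self):
        assert relative_improvement(0.77, 0.77) == 0.0

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            relative_improvement(0.5, 0.0)


def _dummy_method(score_fn):
    def method(cohort, split):
        return score_fn(cohort, split)

    return method


def _signal_scores(cohort, split):
    """Scores that peek at the labels (for harness-contract tests only)."""
    y = cohort.y[split.test]
    rng = np.random.default_rng(0)
    return np.eye(3)[y] * 0.8 + rng.uniform(0, 0.2, size=(len(y), 3))


class TestRunTrials:
    def test_one_row_per_seed(self, small_cohort):
        table, _ = small_cohort
        report = run_trials(_dummy_method(_signal_scores), table, seeds=range(10))
        assert len(report.trials) == 10
        assert report.trials["seed"].tolist() == list(range(10))

    def test_constant_metric_has_zero_se(self, small_cohort):
        table, _ = small_cohort

        def constant(cohort, split):
            out = np.zeros((len(split.test), 3))
            out[:, 0] = 1.0
            return out

        report = run_trials(_dummy_method(constant), table, seeds=range(3))
        assert report.se["macro_recall"] == pytest.approx(0.0)

    def test_mean_equals_hand_average(self, small_cohort):
        table, _ = small_cohort
        report = run_trials(_dummy_method(_signal_scores), table, seeds=range(4))
        assert report.mean["macro_auc"] == pytest.approx(
            report.trials["macro_auc"].mean()
        )

    def test_failing_trial_annotated(self, small_cohort):
        table, _ = small_cohort

        def broken(cohort, split):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="seed 0"):
            run_trials(_dummy_method(broken), table, seeds=range(2))


class TestCrossValidate:
    def test_single_point_grid_returned(self, small_cohort):
        table, _ = small_cohort
        best, rec = cross_validate(
            lambda **kw: _dummy_method(_signal_scores),
            table,
            np.arange(table.n),
            grid=[{"x": 1}],
            k=3,
        )
        assert best == {"x": 1}
        assert len(rec) == 1

    def test_planted_winner_recovered(self, small_cohort):
        table, _ = small_cohort

        def factory(use_signal):
            if use_signal:
                return _dummy_method(_signal_scores)

            def noise(cohort, split):
                rng = np.random.default_rng(1)
                return rng.dirichlet((1, 1, 1), size=len(split.test))

            return _dummy_method(noise)

        best, rec = cross_validate(
            factory,
            table,
            np.arange(table.n),
            grid=[{"use_signal": False}, {"use_signal": True}],
            k=3,
        )
        assert best == {"use_signal": True}

    def test_empty_grid_rejected(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ValueError, match="grid"):
            cross_validate(lambda **kw: None, table, np.arange(table.n), grid=[])


class TestAblationStudy:
    def test_one_row_per_mode_and_shared_splits(self, small_cohort):
        table, _ = small_cohort
        methods = {
            "a": _dummy_method(_signal_scores),
            "b": _dummy_method(_signal_scores),
        }
        summary, per_mode = ablation_study(table, methods, seeds=range(3))
        assert summary["mode"].tolist() == ["a", "b"]
        # identical methods on identical splits give identical trial vectors
        assert np.array_equal(per_mode["a"], per_mode["b"])


class TestPairedT:
    def test_identical_vectors_degenerate(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert res.t is None and res.p is None

    def test_antisymmetry(self):
        a = [0.6, 0.7, 0.8, 0.75]
        b = [0.5, 0.72, 0.74, 0.7]
        r1 = paired_t_test(a, b)
        r2 = paired_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_hand_computed_t(self):
        res = paired_t_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.t == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [0.0])
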