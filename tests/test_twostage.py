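"""Probability composition, the joint loss, and the hierarchical classifier."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phenoview as pv
from phenoview.twostage import (
    LossConfig,
    compose_probabilities,
    fit,
    hard_labels,
    predict,
    threshold_report,
    two_stage_loss,
)
from phenoview.preprocess import compute_class_weights


class TestCompose:
    @pytest.mark.parametrize(
        "p,stage2,expected",
        [
            (1.0, (0.7, 0.3), (0.0, 0.7, 0.3)),
            (0.0, (0.9, 0.1), (1.0, 0.0, 0.0)),
            (0.4, (0.5, 0.5), (0.6, 0.2, 0.2)),
        ],
    )
    def test_hand_values(self, p, stage2, expected):
        assert compose_probabilities(p, stage2) == pytest.approx(expected)

    def test_invalid_stage2_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            compose_probabilities(0.5, (0.7, 0.6))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            compose_probabilities(1.2, (0.5, 0.5))

    @given(st.integers(0, 2**32 - 1))
    def test_composed_always_a_distribution(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=20)
        q = rng.dirichlet((1.0, 1.0), size=20)
        out = compose_probabilities(p, q)
        assert np.all(out >= -1e-12)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)


class TestTwoStageLoss:
    def _toy_batch(self):
        labels = np.array([0, 1, 2, 0])
        composed = np.array(
            [
                [0.8, 0.15, 0.05],
                [0.2, 0.5, 0.3],
                [0.1, 0.3, 0.6],
                [0.6, 0.3, 0.1],
            ]
        )
        stage1 = np.c_[composed[:, 0], 1.0 - composed[:, 0]]
        stage2 = composed[:, 1:] / composed[:, 1:].sum(axis=1, keepdims=True)
        return composed, stage1, stage2, labels

    def test_zero_tradeoffs_leave_plain_weighted_nll(self):
        composed, stage1, stage2, labels = self._toy_batch()
        cfg = LossConfig(gamma=0.0, lam=0.0)
        w3 = compute_class_weights(labels, n_classes=3)
        expected = -sum(
            w3[y] * np.log(composed[i, y]) for i, y in enumerate(labels)
        )
        got = two_stage_loss(composed, stage1, stage2, labels, cfg)
        assert got == pytest.approx(expected)

    def test_perfect_predictions_give_zero(self):
        labels = np.array([0, 1, 2])
        composed = np.eye(3)
        stage1 = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        stage2 = np.array([[0.5, 0.5], [1.0, 0.0], [0.0, 1.0]])
        # every probability that enters the sum is 1, so the loss is exactly 0
        loss = two_stage_loss(composed, stage1, stage2, labels)
        assert loss == pytest.approx(0.0)

    def test_matches_hand_computed_three_term_sum(self):
        composed, stage1, stage2, labels = self._toy_batch()
        cfg = LossConfig(gamma=0.7, lam=1.3)
        w3 = compute_class_weights(labels, n_classes=3)
        w2 = compute_class_weights((labels > 0).astype(int), n_classes=2)
        wph = compute_class_weights(labels[labels > 0] - 1, n_classes=2)
        term1 = -sum(w3[y] * np.log(composed[i, y]) for i, y in enumerate(labels))
        term2 = -sum(
            w2[int(y > 0)] * np.log(stage1[i, int(y > 0)])
            for i, y in enumerate(labels)
        )
        term3 = -sum(
            wph[y - 1] * np.log(stage2[i, y - 1])
            for i, y in enumerate(labels)
            if y > 0
        )
        expected = term1 + cfg.gamma * term2 + cfg.lam * term3
        assert two_stage_loss(composed, stage1, stage2, labels, cfg) == pytest.approx(
            expected
        )

    def test_terms_nonnegative_and_additive(self):
        composed, stage1, stage2, labels = self._toy_batch()
        l00 = two_stage_loss(composed, stage1, stage2, labels, LossConfig(0.0, 0.0))
        l10 = two_stage_loss(composed, stage1, stage2, labels, LossConfig(1.0, 0.0))
        l11 = two_stage_loss(composed, stage1, stage2, labels, LossConfig(1.0, 1.0))
        assert 0 <= l00 <= l10 <= l11

    def test_negative_tradeoffs_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(gamma=-0.1)


FIT_FAST = LossConfig(hidden=16, epochs=80, batch_size=64, seed=0)


def _separable_fixture(n=240, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 3, size=n)
    x = np.zeros((n, 4))
    x[np.arange(n), y] = 3.0
    x += rng.normal(scale=0.3, size=x.shape)
    return x, y


class TestFitPredict:
    def test_deterministic(self):
        x, y = _separable_fixture()
        p1 = predict(fit(x, y, FIT_FAST), x).composed
        p2 = predict(fit(x, y, FIT_FAST), x).composed
        assert np.array_equal(p1, p2)

    def test_beats_majority_baseline_on_separable_data(self):
        x, y = _separable_fixture()
        model = fit(x, y, FIT_FAST)
        pred = predict(model, x)
        macro = pv.macro_prf(y, pred.labels)["macro_f1"]
        majority = pv.macro_prf(y, np.zeros_like(y))["macro_f1"]
        assert macro > majority

    def test_outputs_are_distributions(self):
        x, y = _separable_fixture(seed=3)
        pred = predict(fit(x, y, FIT_FAST), x)
        for block in (pred.stage1, pred.stage2, pred.composed):
            assert np.all(block >= 0)
            assert np.allclose(block.sum(axis=1), 1.0, atol=1e-9)

    def test_no_mafld_rows_rejected(self):
        x = np.ones((5, 2))
        with pytest.raises(ValueError, match="MAFLD"):
            fit(x, np.zeros(5, int), FIT_FAST)

    def test_input_dimension_checked(self):
        x, y = _separable_fixture()
        model = fit(x, y, FIT_FAST)
        with pytest.raises(ValueError, match="columns"):
            predict(model, x[:, :2])

    def test_order_preserved(self):
        x, y = _separable_fixture(seed=5)
        model = fit(x, y, FIT_FAST)
        full = predict(model, x).composed
        # row order is preserved; tolerance covers BLAS batch-shape effects
        assert np.allclose(full[10:20], predict(model, x[10:20]).composed, atol=1e-12)


class TestHardLabels:
    def test_argmax(self):
        assert hard_labels(np.array([0.6, 0.2, 0.2]))[0] == 0

    def test_tie_breaks_to_lower_index(self):
        assert hard_labels(np.array([0.2, 0.4, 0.4]))[0] == 1
        assert hard_labels(np.array([0.4, 0.4, 0.2]))[0] == 0


class TestThresholdReport:
    def test_zero_threshold_flags_everyone(self):
        probs = np.array([0.2, 0.6, 0.9])
        labels = np.array([0, 1, 1])
        row = threshold_report(probs, labels, [0.0]).iloc[0]
        assert row["recall"] == 1.0
        assert row["flagged"] == 3

    def test_threshold_above_max_reports_absent_precision(self):
        probs = np.array([0.2, 0.6])
        report = threshold_report(probs, np.array([0, 1]), [0.95])
        assert report.iloc[0]["flagged"] == 0
        assert np.isnan(report.iloc[0]["precision"])

    def test_flagged_and_recall_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        probs = rng.uniform(size=300)
        labels = rng.integers(0, 2, size=300)
        rep = threshold_report(probs, labels, np.linspace(0, 1, 21))
        assert (np.diff(rep["flagged"]) <= 0).all()
        assert (np.diff(rep["recall"]) <= 1e-12).all()

    def test_empty_threshold_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_report(np.array([0.5]), np.array([1]), [])

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            threshold_report(np.array([1.5]), np.array([1]), [0.5])
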