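"""Teacher pretraining, adaptive temperature, InfoNCE and learner training."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phenoview as pv
from phenoview.contrastive import (
    TAU_MIN,
    ContrastiveConfig,
    batch_temperature,
    infonce_loss,
    multiview_loss,
    pretrain_teacher,
    train_learners,
)

AE_FAST = ContrastiveConfig(dim=8, hidden=16, teacher_epochs=40, batch_size=64, seed=0)


class TestPretrainTeacher:
    def test_deterministic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(120, 10))
        t1 = pretrain_teacher(x, AE_FAST)
        t2 = pretrain_teacher(x, AE_FAST)
        assert np.array_equal(t1.encode(x), t2.encode(x))

    def test_reconstruction_error_decreases(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(500, 12))
        teacher = pretrain_teacher(x, AE_FAST)
        assert teacher.loss_history[-1] < teacher.loss_history[0]

    def test_linear_rank_limit_recovers_low_rank_input(self):
        # with linear activations and d_z >= rank, the autoencoder can reach
        # (near) zero reconstruction error, like PCA
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 2)) @ rng.normal(size=(2, 6))
        cfg = ContrastiveConfig(
            dim=4, hidden=8, teacher_epochs=500, batch_size=100,
            lr=1e-2, teacher_activation="linear", seed=0,
        )
        teacher = pretrain_teacher(x, cfg)
        mse = float(np.mean((teacher.reconstruct(x) - x) ** 2))
        assert mse < 1e-3 * x.var()

    def test_incomplete_input_rejected(self):
        x = np.ones((10, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            pretrain_teacher(x, AE_FAST)


class TestBatchTemperature:
    def test_zero_weights_give_softplus_zero_plus_floor(self):
        z = np.random.default_rng(0).normal(size=(16, 5))
        tau = batch_temperature(z, np.zeros(5))
        assert tau == pytest.approx(np.log(2.0) + TAU_MIN)
        assert tau == pytest.approx(0.7431, abs=1e-4)

    @given(st.integers(0, 2**32 - 1))
    def test_always_strictly_positive(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(8, 6)) * 10
        w = rng.normal(size=6) * 10
        assert batch_temperature(z, w) > 0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(32, 4))
        w = rng.normal(size=4)
        perm = rng.permutation(32)
        assert batch_temperature(z, w) == pytest.approx(batch_temperature(z[perm], w))


class TestInfoNCE:
    def test_uniform_batch_gives_log_n(self):
        for n in (2, 5, 17):
            z = np.tile([1.0, 2.0, 3.0], (n, 1))
            assert infonce_loss(z, z, tau=0.3) == pytest.approx(np.log(n))

    def test_single_row_gives_zero(self):
        z = np.array([[1.0, 0.0]])
        assert infonce_loss(z, z, tau=1.0) == pytest.approx(0.0)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_independent_softmax_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        za, zb = rng.normal(size=(2, 8, 4))
        tau = float(rng.uniform(0.1, 2.0))
        sims = np.zeros((8, 8))
        for i in range(8):
            for k in range(8):
                sims[i, k] = za[i] @ zb[k] / (
                    np.linalg.norm(za[i]) * np.linalg.norm(zb[k])
                )
        expected = np.mean(
            [
                -np.log(
                    np.exp(sims[i, i] / tau) / np.exp(sims[i] / tau).sum()
                )
                for i in range(8)
            ]
        )
        assert infonce_loss(za, zb, tau) == pytest.approx(expected)

    def test_zero_norm_row_rejected(self):
        z = np.ones((3, 2))
        z[1] = 0.0
        with pytest.raises(ValueError, match="zero-norm"):
            infonce_loss(z, np.ones((3, 2)), tau=1.0)

    def test_nonnegative_and_decreasing_in_positive_similarity(self):
        rng = np.random.default_rng(5)
        za, zb = rng.normal(size=(2, 6, 4))
        base = infonce_loss(za, zb, tau=0.5)
        assert base >= 0
        za_better = za + 0.5 * (zb - za)  # move positives closer
        assert infonce_loss(za_better, zb, tau=0.5) < base


class TestMultiviewLoss:
    def test_identical_learners_double_single_term(self):
        rng = np.random.default_rng(6)
        za, zb = rng.normal(size=(2, 7, 3))
        assert multiview_loss(za, zb, za, tau=0.7) == pytest.approx(
            2 * infonce_loss(za, zb, tau=0.7)
        )

    def test_all_views_identical_gives_two_log_n(self):
        z = np.tile([0.5, -1.0], (9, 1))
        assert multiview_loss(z, z, z, tau=1.0) == pytest.approx(2 * np.log(9))

    def test_additivity(self):
        rng = np.random.default_rng(7)
        za, zb, zc = rng.normal(size=(3, 10, 4))
        assert multiview_loss(za, zb, zc, tau=0.4) == pytest.approx(
            infonce_loss(za, zb, 0.4) + infonce_loss(zc, zb, 0.4)
        )


LEARN_FAST = ContrastiveConfig(
    dim=8, hidden=16, teacher_epochs=30, learner_epochs=30, batch_size=64, seed=0
)


def _fixture_views(rho, n=200, seed=9):
    table, _ = pv.generate_cohort(pv.SyntheticConfig(n=n, seed=seed, rho=rho))
    st_ = pv.fit_preprocessor(table)
    x = pv.transform(st_, table)
    cols = []
    for f in table.schema.features:
        if table.schema.group_of(f.name) == "C":
            lo, hi = st_.blocks[f.name]
            cols.extend(range(lo, hi))
    clinical = x[:, cols]
    cfg = pv.TripletConfig(dim=8, epochs=15, seed=0)
    a_lif = pv.train_graph_encoder(pv.build_graph(table, "S_lif"), cfg)
    a_gen = pv.train_graph_encoder(pv.build_graph(table, "S_gen"), cfg)
    return a_lif, a_gen, clinical


def _mean_positive_cosine(za, zb):
    ua = za / np.linalg.norm(za, axis=1, keepdims=True)
    ub = zb / np.linalg.norm(zb, axis=1, keepdims=True)
    return float(np.mean(np.sum(ua * ub, axis=1)))


class TestTrainLearners:
    def test_deterministic(self):
        a_lif, a_gen, clinical = _fixture_views(rho=0.8)
        _, v1 = train_learners(a_lif, a_gen, clinical, LEARN_FAST)
        _, v2 = train_learners(a_lif, a_gen, clinical, LEARN_FAST)
        assert np.array_equal(v1.z_lifestyle, v2.z_lifestyle)
        assert np.array_equal(v1.z_genetics, v2.z_genetics)

    def test_alignment_improves_under_full_coupling(self):
        from dataclasses import replace

        a_lif, a_gen, clinical = _fixture_views(rho=1.0)
        _, before = train_learners(
            a_lif, a_gen, clinical, replace(LEARN_FAST, learner_epochs=0)
        )
        _, after = train_learners(a_lif, a_gen, clinical, LEARN_FAST)
        assert _mean_positive_cosine(
            after.z_lifestyle, after.z_clinical
        ) > _mean_positive_cosine(before.z_lifestyle, before.z_clinical)

    def test_no_heldout_alignment_without_coupling(self):
        # with rho=0 the survey graphs carry nothing about the clinical view,
        # so on held-out persons the positive-pair advantage is ~0
        a_lif, a_gen, clinical = _fixture_views(rho=0.0, n=400)
        train, test = np.arange(200), np.arange(200, 400)
        stack, _ = train_learners(
            a_lif[train], a_gen[train], clinical[train], LEARN_FAST
        )
        views = stack.embed(a_lif[test], clinical[test], a_gen[test])
        rng = np.random.default_rng(0)
        adv = _mean_positive_cosine(
            views.z_lifestyle, views.z_clinical
        ) - _mean_positive_cosine(
            views.z_lifestyle, views.z_clinical[rng.permutation(200)]
        )
        assert abs(adv) < 0.1

    def test_teacher_frozen_during_learner_training(self):
        a_lif, a_gen, clinical = _fixture_views(rho=0.8)
        teacher = pretrain_teacher(clinical, LEARN_FAST)
        z_before = teacher.encode(clinical)
        stack, views = train_learners(
            a_lif, a_gen, clinical, LEARN_FAST, teacher=teacher
        )
        assert np.array_equal(teacher.encode(clinical), z_before)
        assert np.array_equal(views.z_clinical, z_before)

    def test_misaligned_rows_rejected(self):
        a_lif, a_gen, clinical = _fixture_views(rho=0.5)
        with pytest.raises(ValueError, match="row-aligned"):
            train_learners(a_lif[:-1], a_gen, clinical, LEARN_FAST)
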