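"""Pseudo-labeling, rebalancing, the student/teacher updates, and the loop."""

import dataclasses

import numpy as np
import pytest
from helpers_toy import QuadraticModule, ScalarNet, meta_objective, soft_student_update

from conftest import TINY_SCALE, make_items
from ipb.models import ArchConfig, build_model
from ipb.nn import SGD
from ipb.patches import PatchDataset
from ipb.synth import CLASS_NAMES
from ipb.training import (
    EmptyEpochError,
    PseudoLabeledSet,
    StaleStudentError,
    StudentStepInfo,
    TrainConfig,
    assign_pseudo_labels,
    balanced_resample,
    consistency_loss_and_grad,
    estimate_distribution,
    meta_gradient,
    pretrain_teacher,
    run_ipb,
    student_step,
    teacher_step,
)

ARCH = ArchConfig("tiny_test")


def _ps(hard, kept=None, m=4):
    hard = np.asarray(hard)
    probs = np.eye(m)[hard] * 0.9 + 0.025
    conf = probs.max(axis=1)
    kept = np.ones(len(hard), bool) if kept is None else np.asarray(kept, bool)
    return PseudoLabeledSet(probs, hard, conf, kept, tau=0.65)


class _FixedProbModel:
    """Teacher stub emitting predetermined probability rows."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)
        self.replicate_input = False
        self.streams = [None]

    def predict_probs(self, x):
        return self.probs


class TestTrainConfig:
    def test_defaults_match_reference_hyperparameters(self):
        cfg = TrainConfig()
        assert cfg.eta_s == cfg.eta_t == 0.005
        assert cfg.momentum == 0.9
        assert cfg.weight_decay == 1e-4
        assert cfg.batch_size == 32
        assert cfg.pretrain_epochs == cfg.ipb_epochs == 200
        assert cfg.warmup_epochs == 10
        assert cfg.tau == 0.65

    @pytest.mark.parametrize("bad", [dict(tau=0.0), dict(tau=1.0), dict(eta_s=0.0),
                                     dict(batch_size=0), dict(consistency_weight=-1.0)])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            TrainConfig(**bad)


class TestAssignPseudoLabels:
    def test_confident_item_kept(self):
        teacher = _FixedProbModel([[0.7, 0.1, 0.1, 0.1]])
        ps = assign_pseudo_labels(teacher, np.zeros((1, 1, 8, 8)), tau=0.65)
        assert ps.hard[0] == 0 and ps.kept[0]

    def test_below_threshold_dropped(self):
        teacher = _FixedProbModel([[0.6, 0.2, 0.1, 0.1]])
        ps = assign_pseudo_labels(teacher, np.zeros((1, 1, 8, 8)), tau=0.65)
        assert ps.hard[0] == 0 and not ps.kept[0]

    def test_tie_breaks_to_lowest_index(self):
        teacher = _FixedProbModel([[0.25, 0.25, 0.25, 0.25]])
        ps = assign_pseudo_labels(teacher, np.zeros((1, 1, 8, 8)), tau=0.65)
        assert ps.hard[0] == 0 and not ps.kept[0]


class TestEstimateDistribution:
    def test_four_items_three_zero_classes(self):
        dist = estimate_distribution(_ps([0, 0, 0, 1]), m=4)
        np.testing.assert_allclose(dist.p, [0.75, 0.25, 0.0, 0.0])
        np.testing.assert_array_equal(dist.floored, [3, 1, 1, 1])
        assert np.isfinite(dist.class_weights).all()

    def test_reference_counts_minimum_is_diff(self):
        # single-class breakdown: debris 3587, dense 3934, diff 656, spread 10506
        hard = np.repeat([0, 1, 2, 3], [3587, 3934, 656, 10506])
        dist = estimate_distribution(_ps(hard), m=4)
        assert dist.p.argmin() == CLASS_NAMES.index("diff")
        assert dist.class_weights.argmax() == CLASS_NAMES.index("diff")

    def test_uniform_counts_uniform_weights(self):
        dist = estimate_distribution(_ps([0, 1, 2, 3] * 5), m=4)
        np.testing.assert_allclose(dist.p, 0.25)
        np.testing.assert_allclose(dist.class_weights, 1.0)

    def test_empty_kept_raises(self):
        with pytest.raises(EmptyEpochError):
            estimate_distribution(_ps([0, 1], kept=[False, False]), m=4)

    def test_counts_exclude_unkept(self):
        dist = estimate_distribution(_ps([0, 0, 1], kept=[True, False, True]), m=4)
        np.testing.assert_array_equal(dist.counts, [1, 1, 0, 0])


class TestBalancedResample:
    def test_two_class_imbalance_rebalanced(self):
        hard = np.array([0] * 100 + [1] * 10)
        ps = _ps(hard, m=2)
        dist = estimate_distribution(ps, m=2)
        idx = balanced_resample(ps, dist, 10_000, rng=0)
        share0 = (hard[idx] == 0).mean()
        assert abs(share0 - 0.5) < 0.02

    def test_single_kept_class_only_source(self):
        ps = _ps([2, 2, 2], m=4)
        dist = estimate_distribution(ps, m=4)
        idx = balanced_resample(ps, dist, 500, rng=1)
        assert set(ps.hard[idx]) == {2}

    def test_equal_counts_uniform_over_items(self):
        hard = np.repeat([0, 1, 2, 3], 50)
        ps = _ps(hard)
        dist = estimate_distribution(ps, m=4)
        idx = balanced_resample(ps, dist, 20_000, rng=2)
        counts = np.bincount(idx, minlength=200)
        # each item expected 100 draws; loose 5-sigma binomial bound
        assert np.all(np.abs(counts - 100) < 5 * np.sqrt(100))

    def test_expected_shares_uniform_when_all_present(self):
        hard = np.repeat([0, 1, 2, 3], [70, 20, 8, 2])
        ps = _ps(hard)
        dist = estimate_distribution(ps, m=4)
        idx = balanced_resample(ps, dist, 40_000, rng=3)
        shares = np.bincount(hard[idx], minlength=4) / 40_000
        np.testing.assert_allclose(shares, 0.25, atol=3 * np.sqrt(0.25 * 0.75 / 40_000) + 1e-3)


class TestStudentStep:
    def test_plain_step_on_quadratic(self):
        module = QuadraticModule(1.0)
        opt = SGD(lr=0.1, momentum=0.0, weight_decay=0.0)
        student_step(module, None, None, 0.1, opt)
        assert module.theta == pytest.approx(1.2)

    def test_zero_lr_is_noop(self):
        module = QuadraticModule(1.0)
        student_step(module, None, None, 0.0, SGD(0.0, 0.0, 0.0))
        assert module.theta == 1.0

    def test_descent_on_fixed_tiny_batch(self):
        model = build_model(ARCH, rng=0)
        rng = np.random.default_rng(0)
        x = (rng.uniform(size=(8, 1, 32, 32)), rng.uniform(size=(8, 1, 16, 16)))
        y = rng.integers(0, 4, 8)
        loss0, _ = model.loss_and_grad(x, y)
        student_step(model, x, y, 1e-3, SGD(1e-3, 0.0, 0.0))
        loss1, _ = model.loss_and_grad(x, y)
        assert loss1 < loss0

    def test_nonfinite_gradient_reported(self):
        class BadModule(QuadraticModule):
            def loss_and_grad(self, x=None, targets=None):
                return np.inf, np.array([np.nan])

        with pytest.raises(FloatingPointError, match="non-finite"):
            student_step(BadModule(0.0), None, None, 0.1, SGD(0.1))


class TestTeacherStep:
    def _toy_setup(self, seed=0):
        rng = np.random.default_rng(seed)
        xu = rng.normal(size=8)
        xl = rng.normal(size=6)
        yl = rng.integers(0, 2, 6)
        return xu, xl, yl

    def test_stale_student_rejected(self):
        xu, xl, yl = self._toy_setup()
        with pytest.raises(StaleStudentError):
            teacher_step(ScalarNet(0.1), xl, yl, ScalarNet(0.2), None, 0.1, SGD(0.1))

    def test_zero_rate_zero_consistency_noop(self):
        xu, xl, yl = self._toy_setup()
        teacher = ScalarNet(0.7)
        info = StudentStepInfo(np.array([0.3]), 0.1, xu, 0.0)
        teacher_step(teacher, xl, yl, ScalarNet(0.25), info, 0.0,
                     SGD(0.0, 0.0, 0.0), consistency_weight=0.0)
        assert teacher.theta == 0.7

    def test_consistency_zero_on_identical_views(self, trained_tiny_model):
        rng = np.random.default_rng(0)
        x = (rng.uniform(size=(4, 1, 32, 32)), rng.uniform(size=(4, 1, 16, 16)))
        loss, grad = consistency_loss_and_grad(trained_tiny_model, x, x, tau=0.1)
        assert loss == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)

    def test_meta_gradient_matches_finite_difference(self):
        xu, xl, yl = self._toy_setup(3)
        theta_t, theta_s, eta = 0.7, -0.3, 0.1
        teacher = ScalarNet(theta_t)
        student_after = ScalarNet(soft_student_update(theta_t, theta_s, xu, eta))
        info = StudentStepInfo(np.array([theta_s]), eta, xu, 0.0)
        _, grad = meta_gradient(teacher, xl, yl, student_after, info)
        eps = 1e-5
        fd = (
            meta_objective(theta_t + eps, theta_s, xu, xl, yl, eta)
            - meta_objective(theta_t - eps, theta_s, xu, xl, yl, eta)
        ) / (2 * eps)
        assert abs(grad[0] - fd) / abs(fd) < 1e-4

    def test_meta_gradient_network_level_finite_difference(self):
        # same check through the full layer stack (soft surrogate chain)
        rng = np.random.default_rng(0)
        teacher = build_model(ARCH, rng=1)
        student = build_model(ARCH, rng=2)
        xu = (rng.uniform(size=(5, 1, 32, 32)), rng.uniform(size=(5, 1, 16, 16)))
        xl = (rng.uniform(size=(4, 1, 32, 32)), rng.uniform(size=(4, 1, 16, 16)))
        yl = rng.integers(0, 4, 4)
        eta = 0.05
        theta_s = student.get_param_vector()

        def objective(teacher_vec):
            teacher.set_param_vector(teacher_vec)
            student.set_param_vector(theta_s)
            from ipb.nn.network import softmax

            p = softmax(teacher.forward_logits(xu, train=True))
            _, g = student.loss_and_grad(xu, p)
            student.set_param_vector(theta_s - eta * g)
            loss, _ = student.loss_and_grad(xl, yl)
            return loss

        t0 = teacher.get_param_vector()
        base = objective(t0)  # also fixes the student_after parameters
        student_after = student  # currently holds theta'
        info = StudentStepInfo(theta_s, eta, xu, 0.0)
        teacher.set_param_vector(t0)
        _, grad = meta_gradient(teacher, xl, yl, student_after, info)

        eps = 1e-5
        check = np.random.default_rng(9).choice(t0.size, 8, replace=False)
        for i in check:
            hi = t0.copy(); hi[i] += eps
            lo = t0.copy(); lo[i] -= eps
            fd = (objective(hi) - objective(lo)) / (2 * eps)
            teacher.set_param_vector(t0)
            assert abs(fd - grad[i]) <= 1e-4 * max(1e-3, abs(fd))


class TestPretrain:
    def test_reaches_training_accuracy(self, labeled_tiny_dataset):
        cfg = TrainConfig(eta_s=0.02, pretrain_epochs=30, ipb_epochs=0, seed=0)
        teacher = pretrain_teacher(labeled_tiny_dataset, cfg, ARCH, 0)
        weak, _ = labeled_tiny_dataset.sample_views(0, augment=False)
        logits = teacher.forward_logits(weak, train=True)
        acc = (logits.argmax(1) == labeled_tiny_dataset.labels).mean()
        assert acc > 0.95

    def test_zero_epochs_returns_initialization(self, labeled_tiny_dataset):
        cfg = TrainConfig(pretrain_epochs=0, ipb_epochs=0, seed=0)
        teacher = pretrain_teacher(labeled_tiny_dataset, cfg, ARCH, 7)
        fresh = build_model(ARCH, rng=7)
        np.testing.assert_array_equal(teacher.get_param_vector(), fresh.get_param_vector())

    def test_single_class_rejected(self):
        ds = PatchDataset(make_items({"dense": 4}, 0), TINY_SCALE)
        with pytest.raises(ValueError, match="every class"):
            pretrain_teacher(ds, TrainConfig(pretrain_epochs=1, ipb_epochs=0), ARCH, 0)

    def test_unlabeled_rejected(self):
        ds = PatchDataset(make_items({"dense": 2}, 0, labeled=False), TINY_SCALE)
        with pytest.raises(ValueError, match="unlabeled"):
            pretrain_teacher(ds, TrainConfig(pretrain_epochs=1, ipb_epochs=0), ARCH, 0)


@pytest.fixture(scope="module")
def small_sets():
    unlabeled = PatchDataset(
        make_items({"spread": 12, "dense": 6, "debris": 6, "diff": 2}, 42, labeled=False),
        TINY_SCALE,
    )
    labeled = PatchDataset(make_items({c: 4 for c in CLASS_NAMES}, 43), TINY_SCALE)
    return unlabeled, labeled


class TestRunIpb:
    def test_zero_epochs_returns_pretrained_teacher_fresh_student(self, small_sets):
        unlabeled, labeled = small_sets
        cfg = TrainConfig(eta_s=0.02, pretrain_epochs=2, ipb_epochs=0, seed=0)
        state = run_ipb(unlabeled, labeled, cfg, ARCH)
        assert state.epoch == 0
        assert state.best_student_params is None
        assert state.student_loss_trace == []

    def test_determinism(self, small_sets):
        unlabeled, labeled = small_sets
        cfg = TrainConfig(
            eta_s=0.02, pretrain_epochs=2, ipb_epochs=2, warmup_epochs=1,
            consistency_weight=0.0, seed=11,
        )
        s1 = run_ipb(unlabeled, labeled, cfg, ARCH)
        s2 = run_ipb(unlabeled, labeled, cfg, ARCH)
        np.testing.assert_array_equal(
            s1.student.get_param_vector(), s2.student.get_param_vector()
        )
        np.testing.assert_array_equal(
            s1.teacher.get_param_vector(), s2.teacher.get_param_vector()
        )
        assert s1.student_loss_trace == s2.student_loss_trace
        assert s1.selection_acc_trace == s2.selection_acc_trace

    def test_empty_epoch_fallback(self, small_sets, caplog):
        import logging

        unlabeled, labeled = small_sets
        # untrained teacher -> near-uniform confidences, all below tau=0.99
        cfg = TrainConfig(
            eta_s=0.02, pretrain_epochs=0, ipb_epochs=1, tau=0.99,
            consistency_weight=0.0, seed=0,
        )
        with caplog.at_level(logging.WARNING, logger="ipb.training"):
            state = run_ipb(unlabeled, labeled, cfg, ARCH)
        assert state.empty_epochs >= 1
        assert any("soft-label fallback" in rec.message for rec in caplog.records)
        assert np.isnan(state.p_hat_trace[0]).all()

    def test_traces_and_best_student_tracked(self, small_sets):
        unlabeled, labeled = small_sets
        cfg = TrainConfig(
            eta_s=0.02, pretrain_epochs=4, ipb_epochs=3, warmup_epochs=2,
            consistency_weight=0.0, seed=5,
        )
        state = run_ipb(unlabeled, labeled, cfg, ARCH)
        assert state.epoch == 3
        assert len(state.student_loss_trace) == 3
        assert len(state.p_hat_trace) == 3
        assert state.best_accuracy == max(state.selection_acc_trace)
        assert state.best_student_params is not None
        best = state.best_student()
        assert best.num_params == state.student.num_params

    def test_low_tau_unbalanced_reduces_to_plain_mpl(self, small_sets):
        # with tau ~ 0 and balancing off, every item is kept and sampling is
        # uniform: the loop must run through without the balancing machinery
        unlabeled, labeled = small_sets
        cfg = TrainConfig(
            eta_s=0.02, pretrain_epochs=2, ipb_epochs=1, tau=1e-9,
            consistency_weight=0.0, balance=False, seed=3,
        )
        state = run_ipb(unlabeled, labeled, cfg, ARCH)
        assert state.empty_epochs == 0
        # every pseudo-label was kept: estimated p over all |U| items
        assert np.isclose(state.p_hat_trace[0].sum(), 1.0)
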