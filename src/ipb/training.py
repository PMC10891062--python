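"""The iterative pseudo-balancing training loop.

Per epoch: the teacher pseudo-labels one random in-mask patch per unlabeled
image; labels below the confidence threshold are dropped; the kept labels
give estimated class proportions ``p_i`` whose inverses weight a multinomial
resampling (with replacement) of the patch pool; the student takes a
cross-entropy step on each resampled batch (student update) and the teacher
is then updated through the exact meta-gradient of the updated student's
labeled-set loss with respect to the teacher parameters (teacher update),
optionally plus a confidence-masked weak/strong consistency term.  The
student learning rate ramps linearly over the warm-up epochs and the
best-scoring student over training is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ipb._rng import as_generator, substream
from ipb.models import ArchConfig, build_model, forward_probs
from ipb.nn import SGD, Classifier, softmax
from ipb.patches import PatchDataset

__all__ = [
    "TrainConfig",
    "PseudoLabeledSet",
    "ClassDistribution",
    "TrainState",
    "StudentStepInfo",
    "EmptyEpochError",
    "StaleStudentError",
    "pretrain_teacher",
    "assign_pseudo_labels",
    "estimate_distribution",
    "balanced_resample",
    "student_step",
    "meta_gradient",
    "teacher_step",
    "consistency_loss_and_grad",
    "run_ipb",
]

logger = logging.getLogger("ipb.training")


def _stats_guard(model):
    """``model.frozen_stats()`` when available, else a no-op context."""
    from contextlib import nullcontext

    return model.frozen_stats() if hasattr(model, "frozen_stats") else nullcontext()


class EmptyEpochError(RuntimeError):
    """No pseudo-label survived the confidence filter this epoch."""


class StaleStudentError(RuntimeError):
    """teacher_step called without a fresh student update (ordering contract)."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of pre-training and the pseudo-balancing loop."""

    eta_s: float = 0.005
    eta_t: float = 0.005
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 32
    pretrain_epochs: int = 200
    ipb_epochs: int = 200
    warmup_epochs: int = 10
    tau: float = 0.65
    consistency_weight: float = 1.0
    balance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError("confidence threshold tau must lie strictly in (0, 1)")
        if self.eta_s <= 0 or self.eta_t <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if min(self.pretrain_epochs, self.ipb_epochs, self.warmup_epochs) < 0:
            raise ValueError("epoch counts must be nonnegative")
        if self.consistency_weight < 0:
            raise ValueError("consistency weight must be nonnegative")


@dataclass
class PseudoLabeledSet:
    """Teacher soft probabilities plus hard labels / keep flags per item."""

    probs: np.ndarray  # (N, m) soft pseudo-labels
    hard: np.ndarray  # (N,) argmax labels, lowest-index tie-break
    confidence: np.ndarray  # (N,) max soft probability
    kept: np.ndarray  # (N,) bool, confidence >= tau
    tau: float

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kept)


@dataclass
class ClassDistribution:
    """Kept pseudo-counts, proportions and inverse-proportion class weights."""

    m: int
    counts: np.ndarray  # kept pseudo-count per class (may contain zeros)
    p: np.ndarray  # counts / counts.sum()
    floored: np.ndarray  # counts with zero classes floored to 1 (weighting)
    class_weights: np.ndarray  # w_c = 1 / (m * floored_proportion_c)

    def instance_weights(self, hard_labels: np.ndarray) -> np.ndarray:
        return self.class_weights[hard_labels]


@dataclass
class StudentStepInfo:
    """Evidence of one completed student update, consumed by teacher_step."""

    theta_before: np.ndarray
    eta: float
    batch: object  # the unlabeled batch the student was updated on
    loss: float


@dataclass
class TrainState:
    teacher: Classifier
    student: Classifier
    epoch: int = 0
    student_loss_trace: list = field(default_factory=list)
    teacher_loss_trace: list = field(default_factory=list)
    selection_acc_trace: list = field(default_factory=list)
    p_hat_trace: list = field(default_factory=list)  # per-epoch p_i over kept items
    p_hat_all_trace: list = field(default_factory=list)  # p_i over all pseudo-labels
    kept_trace: list = field(default_factory=list)  # per-epoch kept pseudo-labels
    best_student_params: Optional[np.ndarray] = None
    best_student_buffers: Optional[list] = None
    best_accuracy: float = -1.0
    empty_epochs: int = 0

    def best_student(self) -> Classifier:
        """The highest-selection-accuracy student (params + batch-norm stats)."""
        model = self.student.copy()
        if self.best_student_params is not None:
            model.set_param_vector(self.best_student_params)
            for buf, saved in zip(model.buffer_arrays(), self.best_student_buffers):
                buf[...] = saved
        return model


# ---------------------------------------------------------------------------
# Individual operations
# ---------------------------------------------------------------------------


def pretrain_teacher(
    labeled: PatchDataset,
    cfg: TrainConfig,
    arch: ArchConfig,
    rng: int | np.random.Generator | None = None,
    model: Classifier | None = None,
) -> Classifier:
    """Fully supervised teacher pre-training on the balanced labeled subset.

    Every class must be represented in ``labeled``.  Runs
    ``cfg.pretrain_epochs`` epochs of SGD (momentum, weight decay) over one
    augmented in-mask patch per image per epoch; zero epochs returns the
    initialization unchanged.
    """
    rng = as_generator(rng)
    labels = labeled.labels
    if np.any(labels < 0):
        raise ValueError("labeled set contains unlabeled records")
    present = np.unique(labels)
    if present.size < arch.n_classes:
        raise ValueError(
            f"labeled set must contain every class: found {present.size} of {arch.n_classes}"
        )
    teacher = model if model is not None else build_model(arch, rng)
    opt = SGD(cfg.eta_s, cfg.momentum, cfg.weight_decay)
    for _ in range(cfg.pretrain_epochs):
        _, strong = labeled.sample_views(rng, augment=True)
        order = rng.permutation(len(labeled))
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grad = teacher.loss_and_grad(_index_batch(strong, idx), labels[idx])
            opt.step(teacher, grad)
    return teacher


def assign_pseudo_labels(teacher: Classifier, patches, tau: float) -> PseudoLabeledSet:
    """Teacher soft probabilities, argmax hard labels, and the kept mask."""
    probs = forward_probs(teacher, patches if isinstance(patches, tuple) else (patches,))
    hard = probs.argmax(axis=1)  # np.argmax: lowest index wins ties
    confidence = probs.max(axis=1)
    return PseudoLabeledSet(probs, hard, confidence, confidence >= tau, tau)


def estimate_distribution(ps: PseudoLabeledSet, m: int) -> ClassDistribution:
    """Class counts/proportions over *kept* items, with the floor rule.

    Classes with zero kept count get pseudo-count 1 for weighting so their
    sampling weight stays finite.  Raises :class:`EmptyEpochError` when no
    item was kept (callers fall back to a soft-label epoch).
    """
    kept_hard = ps.hard[ps.kept]
    if kept_hard.size == 0:
        raise EmptyEpochError("no pseudo-labels above the confidence threshold")
    counts = np.bincount(kept_hard, minlength=m).astype(float)
    p = counts / counts.sum()
    floored = np.maximum(counts, 1.0)
    p_floored = floored / floored.sum()
    class_weights = 1.0 / (m * p_floored)
    return ClassDistribution(m, counts, p, floored, class_weights)


def balanced_resample(
    ps: PseudoLabeledSet,
    dist: ClassDistribution,
    n_draws: int,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Multinomial resampling with replacement over kept items.

    Item ``j`` is drawn with probability proportional to the inverse
    proportion of its pseudo-class, so the expected per-class share is
    ``1/m`` for every class with kept items.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = as_generator(rng)
    kept = ps.kept_indices
    w = dist.instance_weights(ps.hard[kept])
    return rng.choice(kept, size=n_draws, replace=True, p=w / w.sum())


def student_step(student, batch, targets, lr: float, opt: SGD) -> StudentStepInfo:
    """One student SGD step on (pseudo-)labeled patches.

    ``targets`` are hard labels or soft rows.  Returns the step evidence
    that :func:`teacher_step` requires.
    """
    theta_before = student.get_param_vector()
    try:
        loss, grad = student.loss_and_grad(batch, targets)
        opt.step(student, grad, lr)
    except FloatingPointError as err:
        raise FloatingPointError(
            f"non-finite student gradient (lr={lr}, batch={_batch_size(batch)})"
        ) from err
    return StudentStepInfo(theta_before, lr, batch, loss)


def consistency_loss_and_grad(
    teacher, weak_batch, strong_batch, tau: float
) -> tuple[float, np.ndarray]:
    """Confidence-masked KL(stop-grad weak || strong) and its teacher gradient."""
    p_weak = teacher.predict_probs(weak_batch)  # eval mode, stop-gradient
    mask = p_weak.max(axis=1) >= tau
    n = int(mask.sum())
    zeros = np.zeros(teacher.get_param_vector().size)
    if n == 0:
        return 0.0, zeros
    # evaluation-mode statistics on the strong view as well, so identical
    # views give exactly zero divergence; the gradient still flows through
    # every parameter
    logits = teacher.forward_logits(strong_batch, train=False)
    q = softmax(logits)
    eps = 1e-12
    kl = (p_weak * (np.log(p_weak + eps) - np.log(q + eps))).sum(axis=1)
    loss = float((kl * mask).sum() / n)
    dz = (q - p_weak) * mask[:, None] / n
    return loss, teacher.backward_from_logit_grad(dz)


def meta_gradient(
    teacher,
    labeled_batch,
    labeled_targets: np.ndarray,
    student_after,
    info: Optional[StudentStepInfo],
) -> tuple[float, np.ndarray]:
    """Exact gradient of the updated student's labeled loss w.r.t. the teacher.

    The chain runs through the soft pseudo-labels: for a plain student step
    ``theta' = theta - eta * grad CE(p, q)`` the labeled loss is
    differentiable in the teacher's soft output ``p``, with sensitivity
    ``dL/dp[u, k] = -eta/B * (q[u]·r[u] - r[u, k])`` where ``v`` is the
    labeled-loss gradient at ``theta'`` and ``r`` the directional
    derivative of the pre-step student logits along ``v``.  That
    sensitivity is pushed through the teacher's softmax and backpropagated.
    Returns ``(labeled_loss, gradient)``.
    """
    if info is None:
        raise StaleStudentError(
            "teacher meta-update requires the StudentStepInfo from a completed student_step"
        )
    # These forwards are gradient probes, not training passes: batch-norm
    # running statistics must stay untouched or the teacher's evaluation
    # behavior would drift with every meta-update.
    with _stats_guard(student_after):
        # v: gradient of the labeled loss at the *updated* student.
        labeled_loss, v = student_after.loss_and_grad(labeled_batch, labeled_targets)

        # q and r at the pre-step student parameters.
        theta_after = student_after.get_param_vector()
        student_after.set_param_vector(info.theta_before)
        try:
            logits_u, r = student_after.jvp_logits(info.batch, v)
        finally:
            student_after.set_param_vector(theta_after)
    q = softmax(logits_u)
    B = q.shape[0]
    a = (q * r).sum(axis=1, keepdims=True) - r
    dL_dp = -(info.eta / B) * a

    # Push through the teacher's softmax: dz_j = p_j (g_j - sum_k p_k g_k).
    with _stats_guard(teacher):
        logits_t = teacher.forward_logits(info.batch, train=True)
        p = softmax(logits_t)
        dz = p * (dL_dp - (p * dL_dp).sum(axis=1, keepdims=True))
        return labeled_loss, teacher.backward_from_logit_grad(dz)


def teacher_step(
    teacher,
    labeled_batch,
    labeled_targets: np.ndarray,
    student_after,
    info: Optional[StudentStepInfo],
    lr: float,
    opt: SGD,
    consistency_weight: float = 0.0,
    weak_batch=None,
    strong_batch=None,
    tau: float = 0.65,
) -> float:
    """Meta-update of the teacher from the updated student's labeled loss.

    The teacher's objective is the labeled cross-entropy of the student
    *after* its step; the dependency flows through the soft pseudo-labels
    the teacher produced on the unlabeled batch.  The gradient is computed
    exactly: with ``v`` the labeled-loss gradient at the updated student
    and ``r`` the directional derivative of the old student's logits along
    ``v``, the sensitivity to the teacher's soft label ``p[u, k]`` is
    ``-eta_S/B * (q[u]·r[u] - r[u, k])``, which is pushed through the
    teacher's softmax and backpropagated.  An optional confidence-masked
    weak/strong consistency term is added with weight
    ``consistency_weight``.  Returns the labeled loss (the teacher's
    objective value).
    """
    labeled_loss, grad = meta_gradient(
        teacher, labeled_batch, labeled_targets, student_after, info
    )
    if consistency_weight > 0 and weak_batch is not None:
        _, cgrad = consistency_loss_and_grad(teacher, weak_batch, strong_batch, tau)
        grad = grad + consistency_weight * cgrad

    opt.step(teacher, grad, lr)
    return labeled_loss


# ---------------------------------------------------------------------------
# The full loop
# ---------------------------------------------------------------------------


def _batch_size(batch) -> int:
    arr = batch[0] if isinstance(batch, (tuple, list)) else batch
    return int(arr.shape[0]) if hasattr(arr, "shape") else -1


def _index_batch(batch, idx):
    if isinstance(batch, (tuple, list)):
        return tuple(b[idx] for b in batch)
    return batch[idx]


def _accuracy(model, batch, labels: np.ndarray) -> float:
    preds = forward_probs(model, batch if isinstance(batch, tuple) else (batch,)).argmax(1)
    return float((preds == labels).mean())


def run_ipb(
    unlabeled: PatchDataset,
    labeled: PatchDataset,
    cfg: TrainConfig,
    arch: ArchConfig,
    teacher: Classifier | None = None,
) -> TrainState:
    """Pre-train the teacher, then run the pseudo-balancing loop.

    One epoch draws one patch per unlabeled image, pseudo-labels and
    rebalances them, and consumes ``len(unlabeled)`` resampled draws in
    minibatches, pairing every student update with a teacher meta-update.
    Reproducible bit-for-bit for a fixed ``cfg.seed``.
    """
    init_rng = substream(cfg.seed, "init")
    pre_rng = substream(cfg.seed, "pretrain")
    epoch_rng = substream(cfg.seed, "epochs")
    eval_rng_seed = int(substream(cfg.seed, "eval").integers(2**31))

    if teacher is None:
        teacher = build_model(arch, init_rng)
        teacher = pretrain_teacher(labeled, cfg, arch, pre_rng, model=teacher)
    student = build_model(arch, init_rng)
    state = TrainState(teacher=teacher, student=student)
    if cfg.ipb_epochs == 0:
        return state

    labels_l = labeled.labels
    student_opt = SGD(cfg.eta_s, cfg.momentum, cfg.weight_decay)
    teacher_opt = SGD(cfg.eta_t, cfg.momentum, cfg.weight_decay)
    m = arch.n_classes
    n_draws = len(unlabeled)

    # fixed evaluation patches for best-student selection on L
    eval_weak, _ = labeled.sample_views(eval_rng_seed, augment=False)

    for epoch in range(cfg.ipb_epochs):
        warm = min(1.0, (epoch + 1) / cfg.warmup_epochs) if cfg.warmup_epochs else 1.0
        lr_s = cfg.eta_s * warm

        weak_u, strong_u = unlabeled.sample_views(epoch_rng, augment=True)
        ps = assign_pseudo_labels(teacher, weak_u, cfg.tau)
        state.kept_trace.append(int(ps.kept.sum()))
        # the teacher's estimated class distribution over the whole unlabeled
        # pool (every pseudo-label, confident or not)
        state.p_hat_all_trace.append(np.bincount(ps.hard, minlength=m) / len(ps.hard))
        try:
            dist = estimate_distribution(ps, m)
            state.p_hat_trace.append(dist.p.copy())
            if cfg.balance:
                draws = balanced_resample(ps, dist, n_draws, epoch_rng)
            else:
                draws = epoch_rng.choice(ps.kept_indices, size=n_draws, replace=True)
            targets = ps.hard
            soft_epoch = False
        except EmptyEpochError:
            logger.warning("epoch %d: empty pseudo-label set; soft-label fallback", epoch)
            state.empty_epochs += 1
            state.p_hat_trace.append(np.full(m, np.nan))
            draws = epoch_rng.permutation(len(unlabeled))
            soft_epoch = True

        # labeled patches for the teacher update, one per image, re-drawn
        # every epoch; batches cycle through them
        _, labeled_strong = labeled.sample_views(epoch_rng, augment=True)
        l_order = epoch_rng.permutation(len(labeled))

        s_losses, t_losses = [], []
        l_pos = 0
        for start in range(0, n_draws, cfg.batch_size):
            idx = draws[start : start + cfg.batch_size]
            batch = _index_batch(strong_u, idx)
            batch_targets = ps.probs[idx] if soft_epoch else ps.hard[idx]
            info = student_step(student, batch, batch_targets, lr_s, student_opt)

            take = np.array(
                [l_order[(l_pos + k) % len(labeled)] for k in range(cfg.batch_size)]
            )
            l_pos += cfg.batch_size
            t_loss = teacher_step(
                teacher,
                _index_batch(labeled_strong, take),
                labels_l[take],
                student,
                info,
                cfg.eta_t,
                teacher_opt,
                consistency_weight=cfg.consistency_weight,
                weak_batch=_index_batch(weak_u, idx),
                strong_batch=batch,
                tau=cfg.tau,
            )
            s_losses.append(info.loss)
            t_losses.append(t_loss)

        acc = _accuracy(student, eval_weak, labels_l)
        state.student_loss_trace.append(float(np.mean(s_losses)))
        state.teacher_loss_trace.append(float(np.mean(t_losses)))
        state.selection_acc_trace.append(acc)
        if acc > state.best_accuracy:
            state.best_accuracy = acc
            state.best_student_params = student.get_param_vector()
            state.best_student_buffers = [b.copy() for b in student.buffer_arrays()]
        state.epoch = epoch + 1
    return state
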