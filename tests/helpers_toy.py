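"""Scalar toy networks implementing the classifier interface for oracle tests."""

from __future__ import annotations

import numpy as np

from ipb.nn.network import cross_entropy, one_hot, softmax


class ScalarNet:
    """One-parameter two-class net: logits ``[theta * x, 0]``.

    Implements exactly the interface the teacher/student steps rely on,
    with hand-derived gradients, so meta-gradient tests have an oracle
    that shares no code with the layer stack.
    """

    def __init__(self, theta: float):
        self.theta = float(theta)
        self._x: np.ndarray | None = None

    # parameter-vector interface -------------------------------------------
    def get_param_vector(self) -> np.ndarray:
        return np.array([self.theta])

    def set_param_vector(self, vec: np.ndarray) -> None:
        self.theta = float(vec[0])

    # computation ----------------------------------------------------------
    def forward_logits(self, x, train: bool) -> np.ndarray:
        self._x = np.asarray(x, dtype=float)
        z = np.zeros((len(self._x), 2))
        z[:, 0] = self.theta * self._x
        return z

    def predict_probs(self, x) -> np.ndarray:
        return softmax(self.forward_logits(x, train=False))

    def backward_from_logit_grad(self, dz: np.ndarray) -> np.ndarray:
        return np.array([float((dz[:, 0] * self._x).sum())])

    def loss_and_grad(self, x, targets):
        z = self.forward_logits(x, train=True)
        q = softmax(z)
        t = np.asarray(targets)
        if t.ndim == 1:
            t = one_hot(t, 2)
        loss = cross_entropy(q, t)
        dz = (q - t) / len(self._x)
        return loss, self.backward_from_logit_grad(dz)

    def jvp_logits(self, x, v: np.ndarray):
        x = np.asarray(x, dtype=float)
        z = np.zeros((len(x), 2))
        z[:, 0] = self.theta * x
        dz = np.zeros((len(x), 2))
        dz[:, 0] = v[0] * x
        return z, dz


def soft_student_update(theta_t: float, theta_s: float, xu: np.ndarray, eta: float) -> float:
    """Plain SGD step of the scalar student on soft-teacher cross-entropy."""
    p = softmax(ScalarNet(theta_t).forward_logits(xu, True))
    q = softmax(ScalarNet(theta_s).forward_logits(xu, True))
    return theta_s - eta * float(((q - p)[:, 0] * xu).mean())


def meta_objective(
    theta_t: float, theta_s: float, xu: np.ndarray, xl: np.ndarray, yl: np.ndarray, eta: float
) -> float:
    """Labeled loss of the soft-updated student, as a function of the teacher."""
    student = ScalarNet(soft_student_update(theta_t, theta_s, xu, eta))
    return cross_entropy(softmax(student.forward_logits(xl, True)), one_hot(yl, 2))


class QuadraticModule:
    """``L = (theta - 2)^2`` with hand gradient; for plain-step contracts."""

    def __init__(self, theta: float):
        self.theta = float(theta)

    def get_param_vector(self) -> np.ndarray:
        return np.array([self.theta])

    def set_param_vector(self, vec: np.ndarray) -> None:
        self.theta = float(vec[0])

    def loss_and_grad(self, x=None, targets=None):
        return (self.theta - 2.0) ** 2, np.array([2.0 * (self.theta - 2.0)])
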