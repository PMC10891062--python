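"""SGD with momentum and decoupled-from-nothing L2 weight decay.

Operates on flat parameter vectors: ``v <- mu*v + g + wd*p``,
``p <- p - lr*v``.  With zero momentum and decay this reduces to the plain
step ``p - lr*g``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "sgd_step"]


def sgd_step(
    params: np.ndarray,
    grad: np.ndarray,
    lr: float,
    velocity: np.ndarray | None = None,
    momentum: float = 0.0,
    weight_decay: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One SGD update; returns ``(new_params, new_velocity)``."""
    g = grad + weight_decay * params
    if velocity is None:
        velocity = np.zeros_like(params)
    velocity = momentum * velocity + g
    return params - lr * velocity, velocity


class SGD:
    """Stateful wrapper around :func:`sgd_step` for one network."""

    def __init__(self, lr: float, momentum: float = 0.9, weight_decay: float = 1e-4):
        if lr < 0:
            raise ValueError("learning rate must be nonnegative")
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity: np.ndarray | None = None

    def step(self, model, grad: np.ndarray, lr: float | None = None) -> None:
        """Update ``model`` (a :class:`~ipb.nn.network.Classifier`) in place."""
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite gradient encountered")
        params = model.get_param_vector()
        new, self.velocity = sgd_step(
            params,
            grad,
            self.lr if lr is None else lr,
            self.velocity,
            self.momentum,
            self.weight_decay,
        )
        model.set_param_vector(new)
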