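"""Network containers, softmax/cross-entropy, flat parameter-vector utils."""

from __future__ import annotations

import copy
from contextlib import contextmanager
from typing import Sequence

import numpy as np

from ipb.nn.layers import Layer

__all__ = ["Sequential", "Classifier", "softmax", "one_hot", "cross_entropy"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.shape[0], n_classes))
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def cross_entropy(probs: np.ndarray, targets: np.ndarray, eps: float = 1e-12) -> float:
    """Mean cross-entropy between row-stochastic ``targets`` and ``probs``."""
    return float(-(targets * np.log(probs + eps)).sum(axis=1).mean())


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def forward_jvp(self, x, dx, dparams_iter):
        for layer in self.layers:
            dp = [next(dparams_iter) for _ in layer.params()]
            x, dx = layer.forward_jvp(x, dx, dp)
        return x, dx

    def all_layers(self) -> list[Layer]:
        return self.layers


class Classifier:
    """One or more convolutional streams fused before a shared head.

    Each stream maps ``(N, C, H, W)`` to a feature vector (ending in global
    average pooling); stream features are concatenated and passed through
    the head, which emits logits over ``n_classes``.  Inputs are a single
    array for one stream or a tuple of arrays (coarse, fine) for two.
    """

    def __init__(
        self,
        streams: Sequence[Sequential],
        head: Sequential,
        arch_tag: str,
        n_classes: int,
        stream_widths: Sequence[int],
    ):
        self.streams = list(streams)
        self.head = head
        self.arch_tag = arch_tag
        self.n_classes = n_classes
        self.stream_widths = list(stream_widths)
        #: feed the same single input to every stream (parallel-resolution
        #: branches) instead of expecting one input per stream
        self.replicate_input = False

    # -- structure ---------------------------------------------------------

    def _modules(self) -> list[Sequential]:
        return [*self.streams, self.head]

    def layers(self) -> list[Layer]:
        return [layer for mod in self._modules() for layer in mod.all_layers()]

    def param_arrays(self) -> list[np.ndarray]:
        return [p for layer in self.layers() for p in layer.params()]

    def grad_arrays(self) -> list[np.ndarray]:
        return [g for layer in self.layers() for g in layer.grads()]

    def buffer_arrays(self) -> list[np.ndarray]:
        return [b for layer in self.layers() for b in layer.buffers()]

    @property
    def num_params(self) -> int:
        return sum(p.size for p in self.param_arrays())

    def get_param_vector(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.param_arrays()])

    def set_param_vector(self, vec: np.ndarray) -> None:
        i = 0
        for p in self.param_arrays():
            p[...] = vec[i : i + p.size].reshape(p.shape)
            i += p.size
        if i != vec.size:
            raise ValueError(f"parameter vector length {vec.size}, expected {i}")

    def get_grad_vector(self) -> np.ndarray:
        return np.concatenate([g.ravel() for g in self.grad_arrays()])

    def zero_grads(self) -> None:
        for layer in self.layers():
            layer.zero_grads()

    def unflatten(self, vec: np.ndarray) -> list[np.ndarray]:
        out, i = [], 0
        for p in self.param_arrays():
            out.append(vec[i : i + p.size].reshape(p.shape))
            i += p.size
        return out

    def copy(self) -> "Classifier":
        return copy.deepcopy(self)

    @contextmanager
    def frozen_stats(self):
        """Train-mode forwards inside this context leave BN running stats alone."""
        bns = [l for l in self.layers() if hasattr(l, "freeze_stats")]
        previous = [l.freeze_stats for l in bns]
        for l in bns:
            l.freeze_stats = True
        try:
            yield self
        finally:
            for l, prev in zip(bns, previous):
                l.freeze_stats = prev

    # -- computation -------------------------------------------------------

    def _as_streams(self, x) -> list[np.ndarray]:
        xs = list(x) if isinstance(x, (tuple, list)) else [x]
        if self.replicate_input and len(xs) == 1:
            xs = xs * len(self.streams)
        if len(xs) != len(self.streams):
            raise ValueError(f"expected {len(self.streams)} input stream(s), got {len(xs)}")
        return [np.asarray(xi, dtype=np.float64) for xi in xs]

    def forward_logits(self, x, train: bool) -> np.ndarray:
        feats = [s.forward(xi, train) for s, xi in zip(self.streams, self._as_streams(x))]
        return self.head.forward(np.concatenate(feats, axis=1), train)

    def backward_from_logit_grad(self, dz: np.ndarray) -> np.ndarray:
        """Backprop ``dz`` (gradient at logits) after a ``forward_logits`` call."""
        self.zero_grads()
        dfeat = self.head.backward(dz)
        off = 0
        for s, width in zip(self.streams, self.stream_widths):
            s.backward(dfeat[:, off : off + width])
            off += width
        return self.get_grad_vector()

    def jvp_logits(self, x, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Logits and their directional derivative w.r.t. parameters along ``v``.

        Exact forward-mode pass with train-mode batch statistics; running
        statistics are not modified.  Returns ``(logits, jvp)``.
        """
        tangents = iter(self.unflatten(v))
        feats, dfeats = [], []
        for s, xi in zip(self.streams, self._as_streams(x)):
            f, df = s.forward_jvp(xi, None, tangents)
            feats.append(f)
            dfeats.append(df)
        z, dz = self.head.forward_jvp(
            np.concatenate(feats, axis=1), np.concatenate(dfeats, axis=1), tangents
        )
        return z, dz

    def predict_probs(self, x) -> np.ndarray:
        """Evaluation-mode class probabilities (deterministic)."""
        return softmax(self.forward_logits(x, train=False))

    def loss_and_grad(self, x, targets: np.ndarray) -> tuple[float, np.ndarray]:
        """Mean softmax cross-entropy and its parameter gradient (train mode).

        ``targets`` may be integer hard labels ``(N,)`` or row-stochastic
        soft labels ``(N, n_classes)``.
        """
        targets = np.asarray(targets)
        if targets.ndim == 1:
            targets = one_hot(targets, self.n_classes)
        logits = self.forward_logits(x, train=True)
        probs = softmax(logits)
        loss = cross_entropy(probs, targets)
        dz = (probs - targets) / probs.shape[0]
        return loss, self.backward_from_logit_grad(dz)
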