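"""Layers with reverse-mode backprop and forward-mode parameter JVPs.

Every layer exposes:

``forward(x, train)``
    compute the output, caching whatever backward needs;
``backward(dy)``
    accumulate parameter gradients and return the input gradient;
``forward_jvp(x, dx, dparams)``
    joint forward pass propagating an input tangent ``dx`` and parameter
    tangents ``dparams`` (same structure as ``params()``), returning
    ``(y, dy)``.  JVPs never touch batch-norm running statistics.

Arrays are ``float64`` throughout; convolutions are 3x3 with padding 1 and
stride 1 or 2 (the only shapes the architectures use), implemented via
im2col.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv2d", "BatchNorm", "ReLU", "GlobalAvgPool", "Linear"]


class Layer:
    """Base class; parameter-free layers inherit the empty defaults."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        return []

    def zero_grads(self) -> None:
        for g in self.grads():
            g[...] = 0.0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def forward_jvp(self, x, dx, dparams):  # pragma: no cover
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """3x3 convolution, padding 1, stride 1 or 2, Kaiming-initialized."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1, *, rng: np.random.Generator):
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride
        self.W = _kaiming(rng, (out_ch, in_ch, 3, 3), fan_in=in_ch * 9)
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        n, c, h, w = x.shape
        s = self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (n,c,h,w,3,3)
        win = win[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * 9)
        return cols, (n, c, h, w, ho, wo)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, geom = self._im2col(x)
        n, c, h, w, ho, wo = geom
        wmat = self.W.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.b
        self._cache = (cols, geom)
        return y.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, geom = self._cache
        n, c, h, w, ho, wo = geom
        s = self.stride
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        wmat = self.W.reshape(self.out_ch, -1)
        self.dW += (dyf.T @ cols).reshape(self.W.shape)
        self.db += dyf.sum(axis=0)
        dcols = (dyf @ wmat).reshape(n, ho, wo, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2))
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]

    def forward_jvp(self, x, dx, dparams):
        dWt, dbt = dparams
        cols, geom = self._im2col(x)
        n, c, h, w, ho, wo = geom
        wmat = self.W.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.b
        dy = cols @ dWt.reshape(self.out_ch, -1).T + dbt
        if dx is not None:
            dcols, _ = self._im2col(dx)
            dy = dy + dcols @ wmat.T
        shape = (n, ho, wo, self.out_ch)
        return (
            y.reshape(shape).transpose(0, 3, 1, 2),
            dy.reshape(shape).transpose(0, 3, 1, 2),
        )


class BatchNorm(Layer):
    """Batch normalization over 4-D ``(N,C,H,W)`` or 2-D ``(N,C)`` inputs."""

    def __init__(self, num_features: int, ndim: int = 4, momentum: float = 0.1, eps: float = 1e-5):
        if ndim not in (2, 4):
            raise ValueError("BatchNorm supports 2-D or 4-D inputs")
        self.ndim = ndim
        shape = (1, num_features) if ndim == 2 else (1, num_features, 1, 1)
        self._axes = (0,) if ndim == 2 else (0, 2, 3)
        self.gamma = np.ones(shape)
        self.beta = np.zeros(shape)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(shape)
        self.running_var = np.ones(shape)
        self.momentum = momentum
        self.eps = eps
        self._cache = None
        #: when true, train-mode forwards use batch statistics but leave the
        #: running statistics untouched (gradient probes, meta-updates)
        self.freeze_stats = False

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def _stats(self, x):
        mu = x.mean(axis=self._axes, keepdims=True)
        var = x.var(axis=self._axes, keepdims=True)
        return mu, var

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu, var = self._stats(x)
            if not self.freeze_stats:
                self.running_mean[...] = (1 - self.momentum) * self.running_mean + self.momentum * mu
                self.running_var[...] = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * invstd
        self._cache = (x, mu, invstd, xhat, train)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, mu, invstd, xhat, train = self._cache
        self.dgamma += (dy * xhat).sum(axis=self._axes, keepdims=True)
        self.dbeta += dy.sum(axis=self._axes, keepdims=True)
        dxhat = dy * self.gamma
        if not train:
            return dxhat * invstd
        m = float(np.prod([x.shape[a] for a in self._axes]))
        dvar = (dxhat * (x - mu) * (-0.5) * invstd**3).sum(axis=self._axes, keepdims=True)
        dmu = (-dxhat * invstd).sum(axis=self._axes, keepdims=True) + dvar * (
            -2.0 * (x - mu)
        ).mean(axis=self._axes, keepdims=True)
        return dxhat * invstd + dvar * 2.0 * (x - mu) / m + dmu / m

    def forward_jvp(self, x, dx, dparams):
        dgt, dbt = dparams
        # train-mode statistics, but running stats are left untouched
        mu, var = self._stats(x)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * invstd
        y = self.gamma * xhat + self.beta
        if dx is None:
            dxhat = np.zeros_like(x)
        else:
            dmu = dx.mean(axis=self._axes, keepdims=True)
            dvar = (2.0 * (x - mu) * dx).mean(axis=self._axes, keepdims=True)
            dinvstd = -0.5 * invstd**3 * dvar
            dxhat = (dx - dmu) * invstd + (x - mu) * dinvstd
        dy = dgt * xhat + self.gamma * dxhat + dbt
        return y, dy


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def forward_jvp(self, x, dx, dparams):
        mask = x > 0
        return x * mask, (dx * mask if dx is not None else np.zeros_like(x))


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean; makes patch sizes configurable."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)

    def forward_jvp(self, x, dx, dparams):
        return x.mean(axis=(2, 3)), (
            dx.mean(axis=(2, 3)) if dx is not None else np.zeros(x.shape[:2])
        )


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator):
        self.W = _kaiming(rng, (out_features, in_features), fan_in=in_features)
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += dy.T @ self._x
        self.db += dy.sum(axis=0)
        return dy @ self.W

    def forward_jvp(self, x, dx, dparams):
        dWt, dbt = dparams
        y = x @ self.W.T + self.b
        dy = x @ dWt.T + dbt
        if dx is not None:
            dy = dy + dx @ self.W.T
        return y, dy
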