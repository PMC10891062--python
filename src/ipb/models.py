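"""Classifier architectures: dual-stream VGG-style, compact high-resolution
network, and a tiny test-scale variant.

All variants share the same building blocks: 3x3 convolutions (stride 1,
padding 1), stride-2 3x3 downsampling convolutions, batch normalization and
ReLU after every convolution, global average pooling per stream, feature
concatenation with batch normalization, and a fully connected head.  All
weights are Kaiming-initialized with zero biases.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from ipb._rng import as_generator
from ipb.nn import BatchNorm, Classifier, Conv2d, GlobalAvgPool, Linear, ReLU, Sequential
from ipb.patches import DUAL224_112, SINGLE128, ScaleMode

__all__ = [
    "ArchConfig",
    "build_model",
    "forward_probs",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = 1

_ARCHS = ("dual_stream_vgg", "compact_hires", "tiny_test")


@dataclass(frozen=True)
class ArchConfig:
    """Architecture selection plus the few knobs the variants expose.

    ``stream_channels`` is the per-convolution channel progression of one
    stream; when given, its last entry must equal ``stream_width``.
    """

    arch: str = "tiny_test"
    in_channels: int = 1
    n_classes: int = 4
    stream_width: Optional[int] = None
    stream_channels: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.arch not in _ARCHS:
            raise ValueError(f"unknown architecture {self.arch!r}; expected one of {_ARCHS}")
        if self.n_classes < 2 or self.in_channels < 1:
            raise ValueError("need n_classes >= 2 and in_channels >= 1")
        if (
            self.stream_channels is not None
            and self.stream_width is not None
            and self.stream_channels[-1] != self.stream_width
        ):
            raise ValueError(
                "inconsistent widths: stream_channels[-1] "
                f"{self.stream_channels[-1]} != stream_width {self.stream_width}"
            )

    @property
    def scale_mode(self) -> ScaleMode:
        if self.arch == "dual_stream_vgg":
            return DUAL224_112
        if self.arch == "compact_hires":
            return SINGLE128
        return ScaleMode("dual", 32)

    @property
    def width(self) -> int:
        if self.stream_width is not None:
            return self.stream_width
        if self.stream_channels is not None:
            return self.stream_channels[-1]
        return {"dual_stream_vgg": 512, "compact_hires": 256, "tiny_test": 16}[self.arch]


def _conv_block(in_ch: int, out_ch: int, stride: int, rng) -> list:
    return [Conv2d(in_ch, out_ch, stride, rng=rng), BatchNorm(out_ch, ndim=4), ReLU()]


def _stream(channels: tuple[int, ...], strides: tuple[int, ...], in_ch: int, rng) -> Sequential:
    layers: list = []
    prev = in_ch
    for ch, s in zip(channels, strides):
        layers += _conv_block(prev, ch, s, rng)
        prev = ch
    layers.append(GlobalAvgPool())
    return Sequential(layers)


def _head(widths: tuple[int, ...], n_classes: int, rng) -> Sequential:
    # BN after the feature concatenation, then the fully connected stack.
    layers: list = [BatchNorm(widths[0], ndim=2)]
    for a, b in zip(widths[:-1], widths[1:]):
        layers += [Linear(a, b, rng=rng), ReLU()]
    layers.append(Linear(widths[-1], n_classes, rng=rng))
    return Sequential(layers)


def build_model(cfg: ArchConfig, rng: int | np.random.Generator | None = 0) -> Classifier:
    """Instantiate a Kaiming-initialized classifier for ``cfg``.

    Deterministic for a fixed seed.
    """
    rng = as_generator(rng)
    ic, m = cfg.in_channels, cfg.n_classes

    if cfg.arch == "tiny_test":
        # Two streams (coarse 32, fine 16), two convolutions each.
        ch = cfg.stream_channels or (cfg.width, cfg.width)
        streams = [_stream(ch, (1, 2), ic, rng) for _ in range(2)]
        w = ch[-1]
        head = _head((2 * w, w), m, rng)
        model = Classifier(streams, head, cfg.arch, m, [w, w])
    elif cfg.arch == "dual_stream_vgg":
        # VGG-style streams on the 224 and 112 patches; features of
        # stream_width each are concatenated before the head.
        ch = cfg.stream_channels or (64, 64, 128, 128, 256, 256, 512, cfg.width)
        strides = tuple(1 if i % 2 == 0 else 2 for i in range(len(ch)))
        streams = [_stream(ch, strides, ic, rng) for _ in range(2)]
        w = ch[-1]
        head = _head((2 * w, w), m, rng)
        model = Classifier(streams, head, cfg.arch, m, [w, w])
    else:  # compact_hires
        # Two parallel-resolution branches over the same input: the second
        # branch downsamples immediately, conserving a coarse-resolution
        # path alongside the full-resolution one.  5 convolutions per
        # branch (10 total) and 5 fully connected layers (15 layers).
        ch = cfg.stream_channels or (64, 64, 128, 128, cfg.width)
        hi = _stream(ch, (1, 2, 1, 2, 1), ic, rng)
        lo = _stream(ch, (2, 1, 2, 1, 2), ic, rng)
        w = ch[-1]
        head = _head((2 * w, w, w // 2, w // 4, w // 8), m, rng)
        model = Classifier([hi, lo], head, cfg.arch, m, [w, w])
        model.replicate_input = True
    for p in model.param_arrays():
        if not np.all(np.isfinite(p)):  # pragma: no cover - defensive
            raise FloatingPointError("non-finite initialization")
    return model


def forward_probs(model: Classifier, batch) -> np.ndarray:
    """Evaluation-mode class probabilities for a batch of patches.

    ``batch`` is one 4-D array ``(N, C, H, W)`` or a tuple of them (coarse,
    fine) for dual-stream models.  Rows are softmax-normalized.
    """
    xs = batch if isinstance(batch, (tuple, list)) else (batch,)
    for x in xs:
        x = np.asarray(x)
        if x.ndim != 4:
            raise ValueError(f"expected 4-D (N,C,H,W) batch, got ndim={x.ndim}")
    if getattr(model, "replicate_input", False) and len(xs) == 1:
        xs = tuple(xs) * len(model.streams)
    return model.predict_probs(xs if len(xs) > 1 else xs[0])


def save_checkpoint(model: Classifier, cfg: ArchConfig, path) -> None:
    """Versioned checkpoint: architecture tag/config plus parameter blobs."""
    import json

    arrays = {f"param_{i}": p for i, p in enumerate(model.param_arrays())}
    arrays.update({f"buffer_{i}": b for i, b in enumerate(model.buffer_arrays())})
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": asdict(cfg)})
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[Classifier, ArchConfig]:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg_dict = meta["config"]
        if cfg_dict.get("stream_channels") is not None:
            cfg_dict["stream_channels"] = tuple(cfg_dict["stream_channels"])
        cfg = ArchConfig(**cfg_dict)
        model = build_model(cfg, rng=0)
        for i, p in enumerate(model.param_arrays()):
            p[...] = data[f"param_{i}"]
        for i, b in enumerate(model.buffer_arrays()):
            b[...] = data[f"buffer_{i}"]
    return model, cfg
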