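"""Shared fixtures: small synthetic scenes, datasets, and a trained tiny model."""

from __future__ import annotations

import numpy as np
import pytest

from ipb.patches import PatchDataset, ScaleMode
from ipb.synth import CLASS_NAMES, ColonySpec, SceneSpec, gen_scene

TINY_SCALE = ScaleMode("dual", 32)


def make_items(counts: dict[str, int], rng, size: int = 64, labeled: bool = True):
    """Single-colony scene items ``(id, image, mask, label)`` per class count."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    items = []
    i = 0
    for ci, cls in enumerate(CLASS_NAMES):
        for _ in range(counts.get(cls, 0)):
            spec = SceneSpec(
                (size, size),
                (ColonySpec(cls, (size // 2, size // 2), int(0.42 * size)),),
            )
            image, mask = gen_scene(spec, rng)
            items.append((f"{cls}_{i}", image, mask > 0, ci if labeled else None))
            i += 1
    return items


@pytest.fixture(scope="session")
def labeled_tiny_dataset() -> PatchDataset:
    """Balanced labeled set: 8 images per class, 64 px, ground-truth masks."""
    return PatchDataset(make_items({c: 8 for c in CLASS_NAMES}, 0), TINY_SCALE)


@pytest.fixture(scope="session")
def test_tiny_dataset() -> PatchDataset:
    """Balanced held-out set: 10 images per class (independent draws)."""
    return PatchDataset(make_items({c: 10 for c in CLASS_NAMES}, 999), TINY_SCALE)


@pytest.fixture(scope="session")
def trained_tiny_model(labeled_tiny_dataset):
    """A tiny classifier pre-trained to high accuracy on the separable task."""
    from ipb.models import ArchConfig
    from ipb.training import TrainConfig, pretrain_teacher

    cfg = TrainConfig(eta_s=0.02, pretrain_epochs=60, ipb_epochs=0, seed=0)
    return pretrain_teacher(labeled_tiny_dataset, cfg, ArchConfig("tiny_test"), 0)
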