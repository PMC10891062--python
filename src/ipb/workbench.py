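"""Run configuration, seeding, manifest I/O and the end-to-end experiment.

A single YAML file (all keys optional, defaults = the reference
hyperparameters) drives: synthetic data generation or manifest loading,
colony segmentation, splitting, teacher pre-training, the pseudo-balancing
loop, and evaluation.  One global seed fans out into named substreams so
toggling one stage's stochasticity does not shift the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import typing
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from ipb._rng import substream
from ipb.evaluation import make_splits, predict_images, score
from ipb.models import ArchConfig, save_checkpoint
from ipb.patches import AugmentParams, PatchDataset, ScaleMode
from ipb.segmentation import SegParams, binarize_colonies
from ipb.synth import CLASS_NAMES, MULTILABEL, DatasetManifest, gen_dataset, load_manifest
from ipb.training import TrainConfig, run_ipb

__all__ = ["RunConfig", "SchemaError", "load_config", "save_config", "run_experiment"]

logger = logging.getLogger("ipb.workbench")


class SchemaError(ValueError):
    """Configuration does not match the schema; message lists offending keys."""


@dataclass(frozen=True)
class SynthSpec:
    """Synthetic dataset request used when no manifest is supplied."""

    # roughly 1/100 of the reference class breakdown, with the rarest class
    # floored at 10 so every class survives a 10-fold split
    debris: int = 36
    dense: int = 39
    diff: int = 10
    spread: int = 105
    multilabel: int = 27
    max_side: int = 256  # cap on generated image size for desk-scale runs

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            "debris": self.debris,
            "dense": self.dense,
            "diff": self.diff,
            "spread": self.spread,
        }


@dataclass(frozen=True)
class DataConfig:
    manifest: str | None = None
    include_multilabel: bool = True
    synth: SynthSpec = field(default_factory=SynthSpec)


@dataclass(frozen=True)
class PatchConfig:
    scale_kind: str = "dual"
    coarse: int = 0  # 0 = derive the patch geometry from the model
    min_coverage: float = 0.5

    def scale_mode(self, model: ArchConfig) -> ScaleMode:
        if self.coarse == 0:
            return model.scale_mode
        return ScaleMode(self.scale_kind, self.coarse)


@dataclass(frozen=True)
class SplitConfig:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    fold: int = 0


@dataclass(frozen=True)
class RunConfig:
    data: DataConfig = field(default_factory=DataConfig)
    seg: SegParams = field(default_factory=SegParams)
    patch: PatchConfig = field(default_factory=PatchConfig)
    augment: AugmentParams = field(default_factory=AugmentParams)
    model: ArchConfig = field(default_factory=ArchConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    seed: int = 0
    outdir: str = "runs/run0"


def _coerce(ftype, value, path):
    origin = typing.get_origin(ftype)
    if origin is typing.Union:
        args = [a for a in typing.get_args(ftype) if a is not type(None)]
        if value is None:
            return None
        return _coerce(args[0], value, path)
    if dataclasses.is_dataclass(ftype):
        if not isinstance(value, dict):
            raise SchemaError(f"{path}: expected a mapping")
        return _build(ftype, value, path)
    if origin is tuple:
        if not isinstance(value, (list, tuple)):
            raise SchemaError(f"{path}: expected a sequence")
        return tuple(value)
    if ftype in (int,):
        if isinstance(value, bool) or not isinstance(value, int):
            raise SchemaError(f"{path}: expected an integer, got {value!r}")
        return value
    if ftype is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise SchemaError(f"{path}: expected a number, got {value!r}")
        return float(value)
    if ftype is bool:
        if not isinstance(value, bool):
            raise SchemaError(f"{path}: expected a boolean, got {value!r}")
        return value
    if ftype is str:
        if not isinstance(value, str):
            raise SchemaError(f"{path}: expected a string, got {value!r}")
        return value
    return value


def _build(dc_type, data: dict, path: str = ""):
    names = {f.name: f for f in dataclasses.fields(dc_type)}
    unknown = sorted(set(data) - set(names))
    if unknown:
        raise SchemaError(f"unknown key(s) at {path or 'top level'}: {', '.join(unknown)}")
    hints = typing.get_type_hints(dc_type)
    kwargs = {}
    for key, value in data.items():
        kwargs[key] = _coerce(hints[names[key].name], value, f"{path}{key}")
    try:
        return dc_type(**kwargs)
    except ValueError as err:
        raise SchemaError(f"{path or 'config'}: {err}") from err


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration (empty file = defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise SchemaError("top level must be a mapping")
    return _build(RunConfig, data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(clean(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------


def _load_gray(path: str) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def _items_for(
    manifest: DatasetManifest, ids: set[str], cfg: RunConfig, labeled: bool
) -> list[tuple[str, np.ndarray, np.ndarray, int | None]]:
    items = []
    for rec in manifest.records:
        if rec.image_id not in ids:
            continue
        image = _load_gray(rec.path)
        mask = binarize_colonies(image, cfg.seg)
        label = None
        if labeled and rec.label != MULTILABEL:
            label = CLASS_NAMES.index(rec.label)
        items.append((rec.image_id, image, mask, label))
    return items


def run_experiment(cfg: RunConfig) -> Path:
    """Execute split -> pre-train -> pseudo-balancing -> evaluation.

    Writes the config snapshot, input content hash, loss and p_i traces,
    the best-student checkpoint and the metrics report into ``cfg.outdir``;
    re-running with the same seed reproduces the metrics exactly.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / "config.yaml")

    if cfg.data.manifest:
        manifest = load_manifest(cfg.data.manifest)
    else:
        synth = cfg.data.synth
        data_dir = outdir / "data"
        manifest = gen_dataset(
            synth.class_counts,
            synth.multilabel,
            data_dir,
            rng=substream(cfg.seed, "synth"),
            min_shape=(55, 85),
            max_shape=(synth.max_side, synth.max_side),
        )

    digest = hashlib.sha256()
    for rec in manifest.records:
        digest.update(rec.image_id.encode())
        digest.update(Path(rec.path).read_bytes())
    (outdir / "run_meta.json").write_text(
        json.dumps({"input_sha256": digest.hexdigest(), "n_records": manifest.total})
    )

    split = make_splits(manifest, cfg.split.fractions, cfg.split.fold, cfg.seed)
    u_ids = set(split.unlabeled)
    if not cfg.data.include_multilabel:
        ml = {r.image_id for r in manifest.records if r.label == MULTILABEL}
        u_ids -= ml

    scale, mcov, aug = cfg.patch.scale_mode(cfg.model), cfg.patch.min_coverage, cfg.augment
    ds_u = PatchDataset(_items_for(manifest, u_ids, cfg, False), scale, mcov, aug)
    ds_l = PatchDataset(_items_for(manifest, set(split.labeled), cfg, True), scale, mcov, aug)
    ds_t = PatchDataset(_items_for(manifest, set(split.test), cfg, True), scale, mcov, aug)

    train_cfg = dataclasses.replace(cfg.train, seed=cfg.seed)
    state = run_ipb(ds_u, ds_l, train_cfg, cfg.model)

    with open(outdir / "loss_traces.csv", "w") as fh:
        fh.write("epoch,student_loss,teacher_loss,selection_accuracy\n")
        for e, (ls, lt, acc) in enumerate(
            zip(state.student_loss_trace, state.teacher_loss_trace, state.selection_acc_trace)
        ):
            fh.write(f"{e},{ls},{lt},{acc}\n")
    with open(outdir / "p_hat.csv", "w") as fh:
        kept_cols = ",".join(f"kept_{c}" for c in CLASS_NAMES)
        all_cols = ",".join(f"all_{c}" for c in CLASS_NAMES)
        fh.write(f"epoch,{kept_cols},{all_cols}\n")
        for e, (pk, pa) in enumerate(zip(state.p_hat_trace, state.p_hat_all_trace)):
            row = ",".join(f"{v}" for v in (*pk, *pa))
            fh.write(f"{e},{row}\n")

    best = state.best_student()
    save_checkpoint(best, cfg.model, outdir / "student_best.npz")

    preds = predict_images(best, ds_t, substream(cfg.seed, "test_patches"))
    labels = ds_t.labels
    report = score([p for _, p in preds], labels, cfg.model.n_classes)
    (outdir / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
    with open(outdir / "metrics.csv", "w") as fh:
        fh.write("class,tpr,f1\n")
        for i, cls in enumerate(CLASS_NAMES):
            fh.write(f"{cls},{report.tpr[i]},{report.f1[i]}\n")
    logger.info("run complete: accuracy %.4f", report.accuracy)
    return outdir


# ---------------------------------------------------------------------------
# Desk-scale paired contrast: balancing on vs off
# ---------------------------------------------------------------------------


def _synthetic_items(counts: dict[str, int], rng, size: int = 64, noise_sigma: float = 0.0):
    """Single-colony scenes with ground-truth masks, one item per image.

    ``noise_sigma`` adds pixel noise on top of the rendered scene, which
    makes the classification task require more training samples (useful for
    contrasts that would otherwise saturate).
    """
    from ipb.synth import ColonySpec, SceneSpec, gen_scene

    items = []
    i = 0
    for ci, cls in enumerate(CLASS_NAMES):
        for _ in range(counts.get(cls, 0)):
            spec = SceneSpec(
                (size, size), (ColonySpec(cls, (size // 2, size // 2), int(0.42 * size)),)
            )
            image, mask = gen_scene(spec, rng)
            if noise_sigma > 0:
                image = np.clip(image + rng.normal(0.0, noise_sigma, image.shape), 0, 1)
            items.append((f"{cls}_{i}", image, mask > 0, ci))
            i += 1
    return items


def run_balance_contrast(
    seed: int,
    unlabeled_counts: dict[str, int] | None = None,
    n_labeled_per_class: int = 8,
    n_test_per_class: int = 20,
    train_cfg: TrainConfig | None = None,
    arch: ArchConfig | None = None,
    image_size: int = 64,
    noise_sigma: float = 0.04,
    arms: tuple[bool, ...] = (True, False),
) -> dict:
    """Train twice on the same imbalanced synthetic task: balancing on vs off.

    Ground-truth masks stand in for the segmentation stage so the contrast
    isolates the resampling scheme.  Returns per-class test TPRs of the two
    best students, the balanced run's per-epoch estimated class proportions,
    and the true unlabeled-pool proportions.
    """
    import dataclasses as _dc

    from ipb._rng import substream as _sub
    from ipb.evaluation import score as _score
    from ipb.models import forward_probs as _fwd

    # 30:10:10:1 imbalance; "spread" is the minority because its texture is
    # the most confusable with the majority ("dense"), so under-sampling it
    # actually costs accuracy.  The teacher learning rate is kept low and
    # the consistency term off so the paired contrast isolates resampling.
    unlabeled_counts = unlabeled_counts or {
        "dense": 60, "debris": 20, "diff": 20, "spread": 2,
    }
    arch = arch or ArchConfig("tiny_test")
    train_cfg = train_cfg or TrainConfig(
        eta_s=0.02,
        eta_t=0.005,
        pretrain_epochs=30,
        ipb_epochs=40,
        consistency_weight=0.0,
        seed=seed,
    )
    scale = arch.scale_mode
    data_rng = _sub(seed, "contrast_data")
    ds_u = PatchDataset(
        _synthetic_items(unlabeled_counts, data_rng, image_size, noise_sigma), scale
    )
    labeled_counts = {c: n_labeled_per_class for c in CLASS_NAMES}
    ds_l = PatchDataset(
        _synthetic_items(labeled_counts, data_rng, image_size, noise_sigma), scale
    )
    test_counts = {c: n_test_per_class for c in CLASS_NAMES}
    ds_t = PatchDataset(
        _synthetic_items(test_counts, data_rng, image_size, noise_sigma), scale
    )

    u_labels = np.array(
        [CLASS_NAMES.index(it.image_id.rsplit("_", 1)[0]) for it in ds_u.items]
    )
    true_p = np.bincount(u_labels, minlength=len(CLASS_NAMES)) / len(u_labels)

    out: dict = {"true_proportions": true_p}
    test_weak, _ = ds_t.sample_views(_sub(seed, "contrast_test"), augment=False)
    for balanced in arms:
        cfg_arm = _dc.replace(train_cfg, balance=balanced, seed=seed)
        state = run_ipb(ds_u, ds_l, cfg_arm, arch)
        best = state.best_student()
        preds = _fwd(best, test_weak if isinstance(test_weak, tuple) else (test_weak,)).argmax(1)
        report = _score(preds, ds_t.labels, arch.n_classes)
        key = "balanced" if balanced else "imbalanced"
        out[f"tpr_{key}"] = report.tpr
        out[f"report_{key}"] = report
        if balanced:
            out["p_hat_trace"] = np.array(state.p_hat_trace)
            out["p_hat_all_trace"] = np.array(state.p_hat_all_trace)
    return out
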