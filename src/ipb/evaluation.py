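"""Splitting, prediction, confusion-matrix metrics and cross-fold comparison.

Splits are stratified 80:10:10 (unlabeled : labeled : test) per class with
fold rotation; multi-label records always go to the unlabeled pool.  Metrics
are per-class true positive rate ``TP/(TP+FN)`` and F1 ``2TP/(2TP+FP+FN)``
from a confusion matrix indexed ``[predicted][actual]``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ipb._rng import as_generator
from ipb.models import Classifier, forward_probs
from ipb.patches import PatchDataset
from ipb.synth import CLASS_NAMES, MULTILABEL, DatasetManifest

__all__ = [
    "SplitSpec",
    "MetricsReport",
    "make_splits",
    "labeled_budget",
    "predict_images",
    "score",
    "compare_folds",
]

logger = logging.getLogger("ipb.evaluation")


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint unlabeled / labeled / test id sets for one fold."""

    unlabeled: tuple[str, ...]
    labeled: tuple[str, ...]
    test: tuple[str, ...]
    fractions: tuple[float, float, float]
    fold: int
    seed: int

    def __post_init__(self) -> None:
        u, l, t = set(self.unlabeled), set(self.labeled), set(self.test)
        if (u & l) or (u & t) or (l & t):
            raise ValueError("split sets must be pairwise disjoint")


def make_splits(
    manifest: DatasetManifest,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    fold: int = 0,
    seed: int = 0,
) -> SplitSpec:
    """Stratified U:L:T split with fold rotation.

    Per class, a seed-fixed permutation is cut into ``n_folds`` blocks
    (``n_folds = round(1 / test_fraction)``); fold ``k`` takes block ``k``
    as test and the next block as labeled, the rest joining the unlabeled
    pool.  Multi-label records are always unlabeled.  A class with fewer
    records than folds is an error.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    n_folds = int(round(1.0 / fractions[2]))
    rng = as_generator(seed)
    by_class: dict[str, list[str]] = {c: [] for c in CLASS_NAMES}
    unlabeled: list[str] = []
    for rec in manifest.records:
        if rec.label == MULTILABEL:
            unlabeled.append(rec.image_id)
        else:
            by_class[rec.label].append(rec.image_id)
    labeled: list[str] = []
    test: list[str] = []
    for cls in CLASS_NAMES:
        ids = by_class[cls]
        if len(ids) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(ids)} records, fewer than {n_folds} folds"
            )
        perm = [ids[i] for i in rng.permutation(len(ids))]
        blocks = [list(b) for b in np.array_split(perm, n_folds)]
        k = fold % n_folds
        test.extend(blocks[k])
        # labeled fraction expressed in blocks (10% -> one block)
        n_lab_blocks = max(1, int(round(fractions[1] * n_folds)))
        for j in range(n_lab_blocks):
            labeled.extend(blocks[(k + 1 + j) % n_folds])
        used = {k} | {(k + 1 + j) % n_folds for j in range(n_lab_blocks)}
        for j in range(n_folds):
            if j not in used:
                unlabeled.extend(blocks[j])
    return SplitSpec(
        tuple(unlabeled), tuple(labeled), tuple(test), tuple(fractions), fold, seed
    )


def labeled_budget(fraction: float, n_single_class: int) -> int:
    """Number of labeled images at a given labeled-data fraction (floor)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    return int(math.floor(fraction * n_single_class))


def predict_images(
    student: Classifier,
    test: PatchDataset,
    rng: int | np.random.Generator | None = None,
) -> list[tuple[str, int]]:
    """One un-augmented in-mask patch per test image; argmax prediction.

    Ties break to the lowest class index.  Items whose mask was empty fall
    back to a full-frame (center-reachable) patch at dataset construction,
    which is logged there.
    """
    rng = as_generator(rng)
    weak, _ = test.sample_views(rng, augment=False)
    preds = forward_probs(student, weak if isinstance(weak, tuple) else (weak,)).argmax(1)
    return [(item.image_id, int(p)) for item, p in zip(test.items, preds)]


@dataclass
class MetricsReport:
    """Confusion matrix ``C[predicted][actual]`` and derived per-class metrics."""

    confusion: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES
    tp: np.ndarray = field(init=False)
    fp: np.ndarray = field(init=False)
    fn: np.ndarray = field(init=False)
    tpr: np.ndarray = field(init=False)
    f1: np.ndarray = field(init=False)
    undefined: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        C = np.asarray(self.confusion, dtype=np.int64)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("confusion matrix must be square")
        self.confusion = C
        m = C.shape[0]
        self.tp = np.diag(C).astype(float)
        self.fp = C.sum(axis=1) - self.tp  # same predicted row, other actual
        self.fn = C.sum(axis=0) - self.tp  # same actual column, other predicted
        with np.errstate(divide="ignore", invalid="ignore"):
            self.tpr = self.tp / (self.tp + self.fn)
            self.f1 = 2 * self.tp / (2 * self.tp + self.fp + self.fn)
        # a class absent from the actuals has undefined TPR/F1
        self.undefined = (self.tp + self.fn) == 0

    @property
    def macro_tpr(self) -> float:
        return float(np.nanmean(np.where(self.undefined, np.nan, self.tpr)))

    @property
    def macro_f1(self) -> float:
        return float(np.nanmean(np.where(self.undefined, np.nan, self.f1)))

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_names": list(self.class_names),
            "tpr": [None if u else float(v) for v, u in zip(self.tpr, self.undefined)],
            "f1": [None if u else float(v) for v, u in zip(self.f1, self.undefined)],
            "macro_tpr": self.macro_tpr,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
        }


def score(
    preds: list[int] | np.ndarray,
    labels: list[int] | np.ndarray,
    n_classes: int = len(CLASS_NAMES),
    class_names: tuple[str, ...] = CLASS_NAMES,
) -> MetricsReport:
    """Confusion matrix (rows = predicted, columns = actual) and metrics."""
    preds = np.asarray(preds, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if preds.shape != labels.shape:
        raise ValueError("prediction/label lists must align")
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError("label outside class range")
    if preds.size and (preds.min() < 0 or preds.max() >= n_classes):
        raise ValueError("prediction outside class range")
    C = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(C, (preds, labels), 1)
    return MetricsReport(C, class_names)


def compare_folds(
    metrics_a: list[float] | np.ndarray, metrics_b: list[float] | np.ndarray
) -> dict:
    """Two-sample Student t comparison of per-fold metric lists (95% level).

    Equal fold counts (>= 2 per arm) are required.  Degenerate zero-variance
    inputs are flagged: identical lists give ``t = 0, p = 1``; a constant
    shift with zero variance is reported with infinite ``t``.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length fold lists with >= 2 folds each")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    var_a, var_b = float(a.var(ddof=1)), float(b.var(ddof=1))
    n = a.size
    result = {
        "mean_a": mean_a,
        "mean_b": mean_b,
        "std_a": math.sqrt(var_a),
        "std_b": math.sqrt(var_b),
        "n": n,
        "degenerate": False,
    }
    if var_a == 0.0 and var_b == 0.0:
        result["degenerate"] = True
        if mean_a == mean_b:
            result.update(t=0.0, p=1.0, significant_95=False)
        else:
            result.update(t=math.inf if mean_a > mean_b else -math.inf, p=0.0,
                          significant_95=True)
        return result
    from scipy import stats

    t, p = stats.ttest_ind(a, b, equal_var=True)
    result.update(t=float(t), p=float(p), significant_95=bool(p < 0.05))
    return result
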