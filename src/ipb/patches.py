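"""In-mask patch sampling, multi-scale extraction and stochastic augmentation.

Patches are drawn inside colony foreground maps (rejection sampling on a
coverage constraint with a bounded retry count and a max-coverage fallback),
extracted either as a single patch or as a coarse patch plus its exact
center crop at half size, and augmented by five independent transforms each
applied with probability 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize as sk_resize
from skimage.transform import rotate as sk_rotate

from ipb._rng import as_generator
from ipb.segmentation import ColonyROI

__all__ = [
    "DegenerateInputError",
    "ScaleMode",
    "SINGLE128",
    "DUAL224_112",
    "AugmentParams",
    "TRANSFORM_NAMES",
    "MultiScalePatch",
    "PIXEL_SIZE_UM",
    "physical_extent",
    "sample_patch_location",
    "extract_multiscale",
    "augment_patch",
    "normalize_resize",
]

logger = logging.getLogger("ipb.patches")

#: Physical pixel size of the source optics, micrometers per pixel.
PIXEL_SIZE_UM = 0.8


class DegenerateInputError(ValueError):
    """Raised when an input is too small/empty for the requested operation."""


@dataclass(frozen=True)
class ScaleMode:
    """Patch geometry: single-scale or coarse + half-size center crop."""

    kind: str  # "single" | "dual"
    coarse: int  # side length of the (only or coarse) patch

    def __post_init__(self) -> None:
        if self.kind not in ("single", "dual"):
            raise ValueError(f"unknown scale mode kind {self.kind!r}")
        if self.coarse < 4 or (self.kind == "dual" and self.coarse % 4 != 0):
            raise ValueError("coarse side must be >= 4 (and divisible by 4 in dual mode)")

    @property
    def fine(self) -> Optional[int]:
        return self.coarse // 2 if self.kind == "dual" else None

    @property
    def name(self) -> str:
        if self.kind == "single":
            return f"single{self.coarse}"
        return f"dual{self.coarse}_{self.fine}"


SINGLE128 = ScaleMode("single", 128)
DUAL224_112 = ScaleMode("dual", 224)


@dataclass(frozen=True)
class MultiScalePatch:
    """A sampled patch: coarse array plus optional exact center crop."""

    image_id: str
    anchor: tuple[int, int]  # top-left (row, col) of the coarse window
    coarse: np.ndarray
    fine: Optional[np.ndarray]
    scale_mode: ScaleMode


def physical_extent(pixels: int, pixel_size_um: float = PIXEL_SIZE_UM) -> float:
    """Physical length in micrometers spanned by ``pixels`` at the given pixel size."""
    return float(pixels) * float(pixel_size_um)


def _coverage_table(binary_map: np.ndarray, patch: int) -> np.ndarray:
    """Foreground coverage of every valid ``patch``-sized window (integral image)."""
    h, w = binary_map.shape
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(binary_map.astype(np.int64), axis=0), axis=1)
    s = (
        ii[patch:, patch:]
        - ii[:-patch, patch:]
        - ii[patch:, :-patch]
        + ii[:-patch, :-patch]
    )
    return s / float(patch * patch)


def sample_patch_location(
    roi: ColonyROI,
    patch_size: int,
    min_coverage: float = 0.5,
    rng: int | np.random.Generator | None = None,
    max_trials: int = 50,
) -> tuple[int, int]:
    """Sample the top-left anchor of a patch window inside an ROI.

    Rejection-samples anchors until the window's foreground coverage reaches
    ``min_coverage``; after ``max_trials`` failures the best window seen is
    returned and the fallback is logged.

    Raises
    ------
    DegenerateInputError
        If the ROI is empty or the image is smaller than the patch.
    """
    rng = as_generator(rng)
    if roi.area == 0:
        raise DegenerateInputError("empty ROI")
    h, w = roi.binary_map.shape
    if h < patch_size or w < patch_size:
        raise DegenerateInputError(
            f"image {h}x{w} smaller than patch {patch_size}; resize first"
        )
    r0, c0, r1, c1 = roi.bbox
    # Restrict anchors to windows intersecting the bbox.
    rlo = max(0, r0 - patch_size + 1)
    rhi = min(h - patch_size, r1 - 1)
    clo = max(0, c0 - patch_size + 1)
    chi = min(w - patch_size, c1 - 1)
    best: tuple[float, int, int] = (-1.0, rlo, clo)
    for _ in range(max_trials):
        r = int(rng.integers(rlo, rhi + 1))
        c = int(rng.integers(clo, chi + 1))
        cov = float(
            roi.binary_map[r : r + patch_size, c : c + patch_size].mean()
        )
        if cov >= min_coverage:
            return r, c
        if cov > best[0]:
            best = (cov, r, c)
    logger.warning(
        "coverage fallback: best window coverage %.3f < %.3f after %d trials",
        best[0],
        min_coverage,
        max_trials,
    )
    return best[1], best[2]


def extract_multiscale(
    image: np.ndarray,
    anchor: tuple[int, int],
    scale_mode: ScaleMode,
    image_id: str = "",
) -> MultiScalePatch:
    """Cut the patch at ``anchor``; in dual mode also its exact center crop."""
    image = np.asarray(image)
    r, c = anchor
    size = scale_mode.coarse
    h, w = image.shape
    if r < 0 or c < 0 or r + size > h or c + size > w:
        raise ValueError(f"anchor {anchor} with patch {size} out of bounds for {h}x{w}")
    coarse = image[r : r + size, c : c + size].copy()
    fine = None
    if scale_mode.kind == "dual":
        q = size // 4
        fine = coarse[q : q + size // 2, q : q + size // 2].copy()
    return MultiScalePatch(image_id, (r, c), coarse, fine, scale_mode)


@dataclass(frozen=True)
class AugmentParams:
    """Probability and magnitude ranges of the five stochastic transforms."""

    prob: float = 0.25
    rotation_range: tuple[float, float] = (0.0, 180.0)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    brightness_range: tuple[float, float] = (0.8, 1.2)
    blur_sigma_range: tuple[float, float] = (0.3, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob <= 1.0):
            raise ValueError("augmentation probability must lie in [0, 1]")


#: Order of the five independent transforms.
TRANSFORM_NAMES = ("hflip", "vflip", "rotate", "contrast_brightness", "blur")


def _augment_array(
    arr: np.ndarray, rng: np.random.Generator, params: AugmentParams
) -> tuple[np.ndarray, np.ndarray]:
    apply = rng.uniform(size=5) < params.prob
    out = arr
    if apply[0]:  # horizontal flip
        out = out[:, ::-1]
    if apply[1]:  # vertical flip
        out = out[::-1, :]
    if apply[2]:  # rotation
        angle = rng.uniform(*params.rotation_range)
        out = sk_rotate(
            np.ascontiguousarray(out), angle, order=1, mode="edge", preserve_range=True
        )
    if apply[3]:  # joint contrast (about the patch mean) + brightness jitter
        fc = rng.uniform(*params.contrast_range)
        fb = rng.uniform(*params.brightness_range)
        m = out.mean()
        out = (m + fc * (out - m)) * fb
    if apply[4]:  # gaussian blur
        sigma = rng.uniform(*params.blur_sigma_range)
        out = gaussian_filter(np.asarray(out, dtype=np.float64), sigma=sigma)
    if not apply.any():
        return arr.copy(), apply
    return np.clip(out, 0.0, 1.0), apply


def augment_patch(
    patch: MultiScalePatch,
    rng: int | np.random.Generator | None = None,
    params: AugmentParams | None = None,
    flags_out: list | None = None,
) -> MultiScalePatch:
    """Apply the five-transform stochastic stack to a patch.

    Each transform (hflip, vflip, rotation, contrast+brightness jitter,
    gaussian blur) fires independently with probability ``params.prob``;
    magnitudes are consumed from the stream only when the transform fires.
    All transforms act on the coarse array; in dual mode the fine patch is
    re-cut as the exact center crop of the augmented coarse patch, so the
    dual-scale consistency invariant survives augmentation.  When
    ``flags_out`` is given, the boolean applied-transform vector (in
    ``TRANSFORM_NAMES`` order) is appended to it.
    """
    rng = as_generator(rng)
    params = params or AugmentParams()
    out, applied = _augment_array(patch.coarse, rng, params)
    if flags_out is not None:
        flags_out.append(applied)
    fine = None
    if patch.scale_mode.kind == "dual":
        size = patch.scale_mode.coarse
        q = size // 4
        fine = out[q : q + size // 2, q : q + size // 2].copy()
    return replace(patch, coarse=out, fine=fine)


def normalize_resize(image: np.ndarray, target_min_side: int) -> np.ndarray:
    """Upscale so the short side reaches ``target_min_side`` (aspect kept).

    Images already at least that large are returned unchanged.  The long
    side is rounded half-up.  Bilinear interpolation.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape
    short = min(h, w)
    if short >= target_min_side:
        return image
    scale = target_min_side / short
    new_h = target_min_side if h == short else int(np.floor(h * scale + 0.5))
    new_w = target_min_side if w == short else int(np.floor(w * scale + 0.5))
    return sk_resize(
        image.astype(np.float64),
        (new_h, new_w),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


# ---------------------------------------------------------------------------
# Batch-level helpers used by the training and evaluation loops
# ---------------------------------------------------------------------------


def roi_from_mask(mask: np.ndarray) -> ColonyROI:
    """Wrap a boolean foreground mask as a single ROI (tight bbox)."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return ColonyROI(binary_map=mask, bbox=(0, 0, 0, 0), area=0)
    bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
    return ColonyROI(binary_map=mask, bbox=bbox, area=int(mask.sum()))


def stack_patches(patch_list: list[MultiScalePatch]):
    """Stack patches into network batch arrays ``(N,1,H,W)`` (tuple in dual mode)."""
    coarse = np.stack([p.coarse for p in patch_list])[:, None, :, :]
    if patch_list[0].scale_mode.kind == "dual":
        fine = np.stack([p.fine for p in patch_list])[:, None, :, :]
        return coarse, fine
    return coarse


@dataclass
class DatasetItem:
    """One single-colony image ready for patch sampling."""

    image_id: str
    image: np.ndarray
    mask: np.ndarray
    label: Optional[int]  # canonical class index; None for unlabeled/multi-label
    roi: ColonyROI


class PatchDataset:
    """A collection of colony images exposing per-epoch patch batches.

    Images whose short side is below the coarse patch size are upscaled once
    (:func:`normalize_resize`, masks nearest-neighbor) at construction.
    ``sample_views`` draws one in-mask patch per item and returns the clean
    ("weak") and augmented ("strong") views as stacked batch arrays.
    """

    def __init__(
        self,
        items: list[tuple[str, np.ndarray, np.ndarray, Optional[int]]],
        scale_mode: ScaleMode,
        min_coverage: float = 0.5,
        augment_params: AugmentParams | None = None,
    ):
        self.scale_mode = scale_mode
        self.min_coverage = min_coverage
        self.augment_params = augment_params or AugmentParams()
        self.items: list[DatasetItem] = []
        target = scale_mode.coarse
        for image_id, image, mask, label in items:
            image = np.asarray(image, dtype=np.float64)
            mask = np.asarray(mask, dtype=bool)
            if min(image.shape) < target:
                image = normalize_resize(image, target)
                mask = (
                    sk_resize(
                        mask.astype(np.float64),
                        image.shape,
                        order=0,
                        mode="edge",
                        anti_aliasing=False,
                        preserve_range=True,
                    )
                    > 0.5
                )
            roi = roi_from_mask(mask)
            if roi.area == 0:
                # unsegmentable item: fall back to a full-frame ROI so the
                # center patch remains reachable (callers log this)
                logger.warning("empty mask for %s; using full-frame ROI", image_id)
                roi = roi_from_mask(np.ones_like(mask, dtype=bool))
            self.items.append(DatasetItem(image_id, image, mask, label, roi))

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([-1 if it.label is None else it.label for it in self.items])

    def sample_views(
        self,
        rng: int | np.random.Generator | None,
        augment: bool = True,
    ):
        """One patch per item: returns ``(weak_batch, strong_batch)``.

        ``strong`` equals ``weak`` when ``augment`` is false.  Batches are
        single arrays in single-scale mode, (coarse, fine) tuples in dual.
        """
        rng = as_generator(rng)
        weak, strong = [], []
        for it in self.items:
            anchor = sample_patch_location(
                it.roi, self.scale_mode.coarse, self.min_coverage, rng
            )
            patch = extract_multiscale(it.image, anchor, self.scale_mode, it.image_id)
            weak.append(patch)
            strong.append(
                augment_patch(patch, rng, self.augment_params) if augment else patch
            )
        return stack_patches(weak), stack_patches(strong)
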