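"""Morphological colony detection and ROI extraction.

The binarization pipeline runs six steps in fixed order: 3x3 Gaussian blur,
local entropy filtering (disk radius 3), global Otsu thresholding on the
rescaled entropy map, morphological opening (disk radius 3), binary hole
filling, and removal of objects smaller than a minimum area (default
2000 px).  Connected foreground components become :class:`ColonyROI`
objects used both for cropping colonies and for constraining patch
sampling to foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.filters.rank import entropy as rank_entropy
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, opening

__all__ = ["SegParams", "ColonyROI", "binarize_colonies", "extract_rois", "segment"]


@dataclass(frozen=True)
class SegParams:
    """Parameters of the six-step binarization pipeline."""

    blur_sigma: float = 0.8  # 3x3 Gaussian kernel (radius-1 support)
    entropy_radius: int = 3
    opening_radius: int = 3
    min_area: int = 2000

    def __post_init__(self) -> None:
        if self.min_area < 0 or self.entropy_radius < 1 or self.opening_radius < 1:
            raise ValueError("invalid segmentation parameters")


@dataclass(frozen=True)
class ColonyROI:
    """One connected foreground component.

    ``binary_map`` covers the full image frame; ``bbox`` is the tight
    0-based half-open bounding box ``(row0, col0, row1, col1)`` of the
    component and ``area`` its pixel count.
    """

    binary_map: np.ndarray
    bbox: tuple[int, int, int, int]
    area: int

    def crop(self, image: np.ndarray) -> np.ndarray:
        r0, c0, r1, c1 = self.bbox
        return image[r0:r1, c0:c1]

    def crop_mask(self) -> np.ndarray:
        r0, c0, r1, c1 = self.bbox
        return self.binary_map[r0:r1, c0:c1]


def _to_uint8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi > lo:
        image = (image - lo) / (hi - lo)
    else:
        image = np.zeros_like(image)
    return (image * 255).astype(np.uint8)


def binarize_colonies(
    image: np.ndarray, params: SegParams | None = None
) -> np.ndarray:
    """Run the six-step pipeline and return the boolean foreground map.

    Degenerate inputs (constant image, or an entropy map with a
    single-valued histogram) yield an all-false map rather than
    all-foreground.
    """
    params = params or SegParams()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={image.ndim}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")

    from scipy.ndimage import gaussian_filter

    # (1) 3x3 Gaussian blur: sigma with radius-1 support.
    blurred = gaussian_filter(image.astype(np.float64), sigma=params.blur_sigma, radius=1)
    # (2) local entropy over a disk; rank filters need uint8.
    ent = rank_entropy(_to_uint8(blurred), disk(params.entropy_radius))
    # Rescale entropy to [0, 1] before thresholding.
    emax = ent.max()
    if emax <= 0:
        return np.zeros(image.shape, dtype=bool)
    ent = ent / emax
    # (3) global Otsu threshold; a single-valued histogram means no texture
    # contrast anywhere -> empty foreground.
    if np.all(ent == ent.flat[0]):
        return np.zeros(image.shape, dtype=bool)
    thresh = threshold_otsu(ent)
    binary = ent > thresh
    # (4) morphological opening.
    binary = opening(binary, disk(params.opening_radius))
    # (5) hole filling.
    binary = binary_fill_holes(binary)
    # (6) small-object removal: keep components with area >= min_area.
    labeled = cc_label(binary, connectivity=2)
    if labeled.max() > 0:
        areas = np.bincount(labeled.ravel())
        small = np.flatnonzero(areas < params.min_area)
        binary = binary & ~np.isin(labeled, small[small > 0])
    return binary


def extract_rois(binary_map: np.ndarray, image: np.ndarray) -> list[ColonyROI]:
    """Split the foreground map into per-component ROIs.

    Components are 8-connected and the returned list is sorted by
    ``(row0, col0)`` for determinism.
    """
    binary_map = np.asarray(binary_map, dtype=bool)
    image = np.asarray(image)
    if binary_map.shape != image.shape:
        raise ValueError(
            f"shape mismatch: map {binary_map.shape} vs image {image.shape}"
        )
    labeled = cc_label(binary_map, connectivity=2)
    rois = []
    for prop in regionprops(labeled):
        comp = labeled == prop.label
        r0, c0, r1, c1 = prop.bbox
        rois.append(
            ColonyROI(binary_map=comp, bbox=(r0, c0, r1, c1), area=int(prop.area))
        )
    rois.sort(key=lambda roi: (roi.bbox[0], roi.bbox[1]))
    return rois


def segment(
    image: np.ndarray, params: SegParams | None = None
) -> tuple[np.ndarray, list[ColonyROI]]:
    """Convenience wrapper: binarize then extract ROIs."""
    binary = binarize_colonies(image, params)
    return binary, extract_rois(binary, image)
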