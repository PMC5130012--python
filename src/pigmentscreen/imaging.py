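"""Melanocyte-burden quantification from grayscale images.

Melanocytes appear as dark pigment on a lighter larva; a binary mask
(foreground = intensity below threshold) deliberately discards intensity
information so that differences in melanin level per cell cannot bias the
area readout.  Measurements are restricted to a standard region of interest
(default 1000x500 px) anchored at a user-supplied anatomical landmark (the
yolk-sac extension).  Coordinates are pixels, top-left origin; rectangles
are half-open (left, top, width, height).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import DataError

__all__ = [
    "ImageQuantResult",
    "SpheroidResult",
    "quantify_stripe",
    "count_melanocytes",
    "spheroid_fold_change",
]

DEFAULT_ROI_SIZE = (1000, 500)
DEFAULT_THRESHOLD = 128
DEFAULT_MIN_SPOT_PX = 4


@dataclass(frozen=True)
class ImageQuantResult:
    image_id: str
    roi: tuple[int, int, int, int]
    threshold_used: float
    pigmented_area_px: int
    area_fraction: float
    n_components: int


@dataclass(frozen=True)
class SpheroidResult:
    image_id: str
    core_area_t0_px: int
    core_area_t72_px: int
    fold_change: float


def _check_grayscale(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise DataError(
            f"expected a 2-D grayscale image, got shape {image.shape}; "
            "convert color images explicitly first"
        )
    return image


def _crop_roi(image: np.ndarray, roi: tuple[int, int, int, int]) -> np.ndarray:
    left, top, w, h = roi
    if left < 0 or top < 0 or w <= 0 or h <= 0:
        raise DataError(f"invalid roi {roi}")
    if left + w > image.shape[1] or top + h > image.shape[0]:
        raise DataError(
            f"roi {roi} exceeds image bounds {image.shape[1]}x{image.shape[0]}"
        )
    return image[top : top + h, left : left + w]


def _binarize(
    roi_img: np.ndarray, threshold_mode: str | float, threshold: float
) -> tuple[np.ndarray, float]:
    if threshold_mode == "otsu":
        # skimage convention: the returned value belongs to the lower class
        t = float(threshold_otsu(roi_img))
        return roi_img <= t, t
    if threshold_mode == "fixed":
        t = float(threshold)
        return roi_img < t, t
    raise ValueError(f"unknown threshold_mode {threshold_mode!r}")


def _count_components(mask: np.ndarray, min_spot_px: int) -> int:
    labels = label(mask, connectivity=2)  # 8-connectivity
    if labels.max() == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int(np.count_nonzero(areas >= min_spot_px))


def quantify_stripe(
    image: np.ndarray,
    landmark: tuple[int, int],
    roi_size: tuple[int, int] = DEFAULT_ROI_SIZE,
    threshold_mode: str = "fixed",
    threshold: float = DEFAULT_THRESHOLD,
    min_spot_px: int = DEFAULT_MIN_SPOT_PX,
    image_id: str = "",
) -> ImageQuantResult:
    """Pigmented area and spot count in a landmark-anchored standard ROI.

    ``landmark`` is the (x, y) pixel of the yolk-sac extension origin; the
    ROI extends ``roi_size`` pixels right and down from it.
    """
    image = _check_grayscale(image)
    roi = (int(landmark[0]), int(landmark[1]), int(roi_size[0]), int(roi_size[1]))
    roi_img = _crop_roi(image, roi)
    mask, t = _binarize(roi_img, threshold_mode, threshold)
    area = int(mask.sum())
    return ImageQuantResult(
        image_id=image_id,
        roi=roi,
        threshold_used=t,
        pigmented_area_px=area,
        area_fraction=area / (roi[2] * roi[3]),
        n_components=_count_components(mask, min_spot_px),
    )


def count_melanocytes(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    threshold_mode: str = "fixed",
    threshold: float = DEFAULT_THRESHOLD,
    min_spot_px: int = DEFAULT_MIN_SPOT_PX,
) -> int:
    """Number of 8-connected dark spots of at least ``min_spot_px`` pixels."""
    image = _check_grayscale(image)
    mask, _ = _binarize(_crop_roi(image, roi), threshold_mode, threshold)
    return _count_components(mask, min_spot_px)


def spheroid_fold_change(
    image_t0: np.ndarray,
    image_t72: np.ndarray,
    threshold_mode: str = "fixed",
    threshold: float = DEFAULT_THRESHOLD,
    image_id: str = "",
) -> SpheroidResult:
    """Growth fold change of the spheroid core (largest dark component)."""
    areas = []
    for name, img in (("t0", image_t0), ("t72", image_t72)):
        img = _check_grayscale(img)
        mask, _ = _binarize(img, threshold_mode, threshold)
        labels = label(mask, connectivity=2)
        if labels.max() == 0:
            raise DataError(f"spheroid_fold_change: empty foreground at {name}")
        counts = np.bincount(labels.ravel())[1:]
        areas.append(int(counts.max()))
    return SpheroidResult(
        image_id=image_id,
        core_area_t0_px=areas[0],
        core_area_t72_px=areas[1],
        fold_change=areas[1] / areas[0],
    )
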