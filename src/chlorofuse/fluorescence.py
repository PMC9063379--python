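"""Fluorescence frames: grayscale conversion, threshold calibration,
segmentation and the specific fluorescence-intensity feature.

The camera's steady-state fluorescence frame is reduced to a grayscale
intensity in [0, 1]; a global threshold (default 0.13, or calibrated from
randomly sampled plant/background positions) separates plant pixels, and
the plant-level feature is the masked mean intensity averaged over views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, DomainError, EmptyPlantError, ShapeMismatchError
from .masks import (
    DEFAULT_MIN_OBJECT_PX,
    SegmentationMask,
    as_bool_array,
    remove_small_objects,
)

#: default plant/background intensity threshold
DEFAULT_FLUO_THRESHOLD = 0.13


def to_grayscale(img, weights=None) -> np.ndarray:
    """Reduce a colour fluorescence frame to grayscale intensity.

    Default is the unweighted channel mean; pass ``weights`` (length 3,
    e.g. luminance (0.299, 0.587, 0.114)) for a weighted conversion.
    2-D inputs are passed through unchanged.
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[2] == 3:
        w = np.full(3, 1.0 / 3.0) if weights is None else np.asarray(weights, dtype=float)
        if w.shape != (3,):
            raise DomainError("weights must have length 3")
        gray = arr @ (w / w.sum())
    else:
        raise DomainError("fluorescence frame must be 2-D or (rows, cols, 3)")
    if gray.min() < 0.0 or gray.max() > 1.0:
        raise DomainError("fluorescence intensity must lie in [0, 1]")
    return gray


@dataclass
class ThresholdCalibration:
    """Result of sampling plant/background positions to choose a threshold.

    ``chosen_threshold`` is the midpoint of [background_upper, plant_lower]
    when the two classes separate, otherwise None with ``overlap`` > 0
    giving the size of the violation.
    """

    background_samples: np.ndarray
    plant_samples: np.ndarray
    background_upper: float
    plant_lower: float
    chosen_threshold: float | None
    overlap: float

    @property
    def separable(self) -> bool:
        return self.chosen_threshold is not None


def calibrate_threshold(images, truth_masks, n_images: int = 50,
                        positions_per_image: int = 10, seed: int = 0) -> ThresholdCalibration:
    """Choose a grayscale threshold from randomly sampled pixel positions.

    ``n_images`` frames are sampled without replacement; from each, half of
    ``positions_per_image`` positions are drawn from plant pixels and half
    from background pixels (using the supplied masks). The threshold is
    placed midway between the background maximum and the plant minimum; if
    those overlap, the calibration reports non-separable.
    """
    if len(images) != len(truth_masks):
        raise ShapeMismatchError("images and masks must pair up")
    if len(images) < n_images:
        raise CalibrationError(
            f"need at least {n_images} images, got {len(images)}"
        )
    n_plant = positions_per_image // 2
    n_bg = positions_per_image - n_plant
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(images), size=n_images, replace=False)
    bg_vals, plant_vals = [], []
    for idx in chosen:
        gray = to_grayscale(images[idx])
        mask = as_bool_array(truth_masks[idx])
        if mask.shape != gray.shape:
            raise ShapeMismatchError("mask shape does not match image")
        plant_flat = np.flatnonzero(mask.ravel())
        bg_flat = np.flatnonzero(~mask.ravel())
        if plant_flat.size == 0 or bg_flat.size == 0:
            raise CalibrationError("each sampled image needs plant and background pixels")
        plant_pos = rng.choice(plant_flat, size=n_plant, replace=plant_flat.size < n_plant)
        bg_pos = rng.choice(bg_flat, size=n_bg, replace=bg_flat.size < n_bg)
        plant_vals.append(gray.ravel()[plant_pos])
        bg_vals.append(gray.ravel()[bg_pos])
    background = np.concatenate(bg_vals)
    plant = np.concatenate(plant_vals)
    background_upper = float(background.max())
    plant_lower = float(plant.min())
    if background_upper < plant_lower:
        threshold = 0.5 * (background_upper + plant_lower)
        overlap = 0.0
    else:
        threshold = None
        overlap = background_upper - plant_lower
    return ThresholdCalibration(
        background_samples=background, plant_samples=plant,
        background_upper=background_upper, plant_lower=plant_lower,
        chosen_threshold=threshold, overlap=overlap,
    )


def segment_fluorescence(img, threshold: float = DEFAULT_FLUO_THRESHOLD,
                         min_object_px: int = DEFAULT_MIN_OBJECT_PX) -> SegmentationMask:
    """Threshold the grayscale intensity, then apply the small-object rule."""
    gray = to_grayscale(img)
    mask = remove_small_objects(gray >= threshold, min_object_px)
    return SegmentationMask(mask, "fluo", {
        "threshold": threshold, "min_object_px": min_object_px,
    })


def fluorescence_feature(views) -> float:
    """Specific fluorescence intensity: masked mean per view, averaged.

    ``views`` is a sequence of ``(image, mask)`` pairs. Views with empty
    masks are skipped; all empty raises EmptyPlantError.
    """
    means = []
    for img, mask in views:
        gray = to_grayscale(img)
        m = as_bool_array(mask)
        if m.shape != gray.shape:
            raise ShapeMismatchError("mask shape does not match image")
        if not m.any():
            continue
        means.append(float(gray[m].mean()))
    if not means:
        raise EmptyPlantError("all views have empty masks")
    return float(np.mean(means))
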