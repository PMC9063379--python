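"""RGB side-view processing: HSI conversion, colour-index segmentation,
leaf banding, and specific-leaf-image colour features.

The segmentation chain is: per-pixel colour index 3S/(H+S+I) thresholded at
0.75, reference-frame (empty chamber) matching to remove fixed background
structure such as edge stripes, a 3x3 morphological opening, and removal of
8-connected components below 200 px. Features are masked channel means
("specific leaf image") over the 5-35 % plant-height band that contains
leaves 2-4, averaged over the rotational views; projected area is the
full-plant pixel count averaged over views.

All of H, S and I are normalized to [0, 1] (hue divided by 2*pi) before the
colour index, so the index is dimensionless and the 0.75 threshold applies
on a fixed scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import opening

from .errors import DomainError, EmptyPlantError, ShapeMismatchError
from .masks import (
    DEFAULT_MIN_OBJECT_PX,
    SegmentationMask,
    as_bool_array,
    remove_small_objects,
)

#: universal colour-index threshold for plant/background separation
DEFAULT_RGB_THRESHOLD = 0.75
#: leaf band limits as fractions of plant height measured from the top
DEFAULT_BAND = (0.05, 0.35)
#: per-channel absolute tolerance for matching a pixel to the reference frame
DEFAULT_REFERENCE_TOL = 0.02


def _check_rgb(img) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DomainError("RGB image must have shape (rows, cols, 3)")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise DomainError("RGB channel values must lie in [0, 1]")
    return arr


def rgb_to_hsi(img) -> np.ndarray:
    """Convert a normalized RGB image to HSI, all channels in [0, 1].

    Hue is the arccos of ((R-G)+(R-B))/2 over sqrt((R-G)^2 + (R-B)(G-B)),
    reflected to 2*pi - H where B > G, then divided by 2*pi. Saturation is
    1 - 3*min(R,G,B)/(R+G+B) and intensity (R+G+B)/3. Hue is set to 0
    wherever it is undefined (S = 0 or a zero arccos denominator).
    """
    arr = _check_rgb(img)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    total = r + g + b
    minimum = np.minimum(np.minimum(r, g), b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * minimum / np.where(total > 0, total, 1.0), 0.0)
    intensity = total / 3.0
    num = ((r - g) + (r - b)) / 2.0
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    valid = den > 0
    arg = np.zeros_like(num)
    np.divide(num, den, out=arg, where=valid)
    arg = np.clip(arg, -1.0, 1.0)
    h = np.arccos(arg)
    h = np.where(b > g, 2.0 * np.pi - h, h)
    h = np.where(valid & (s > 0), h / (2.0 * np.pi), 0.0)
    s = np.clip(s, 0.0, 1.0)
    return np.stack([h, s, intensity], axis=-1)


def color_index(hsi: np.ndarray) -> np.ndarray:
    """Per-pixel colour index 3S/(H+S+I); pixels with H+S+I = 0 map to 0."""
    hsi = np.asarray(hsi, dtype=float)
    h, s, intensity = hsi[..., 0], hsi[..., 1], hsi[..., 2]
    denom = h + s + intensity
    out = np.zeros_like(denom)
    np.divide(3.0 * s, denom, out=out, where=denom > 0)
    return out


def segment_rgb(img, reference, threshold: float = DEFAULT_RGB_THRESHOLD,
                min_object_px: int = DEFAULT_MIN_OBJECT_PX,
                reference_tol: float = DEFAULT_REFERENCE_TOL) -> SegmentationMask:
    """Segment plant pixels from one RGB frame.

    ``reference`` is an empty-chamber frame of the same shape; pixels whose
    per-channel absolute difference from it stays below ``reference_tol``
    are forced to background (this removes fixed chamber structure such as
    edge stripes that would otherwise pass the colour-index threshold).
    """
    arr = _check_rgb(img)
    ref = _check_rgb(reference)
    if arr.shape != ref.shape:
        raise ShapeMismatchError(
            f"image shape {arr.shape} does not match reference {ref.shape}"
        )
    index = color_index(rgb_to_hsi(arr))
    mask = index >= threshold
    matches_reference = np.all(np.abs(arr - ref) < reference_tol, axis=-1)
    mask &= ~matches_reference
    mask = opening(mask, footprint=np.ones((3, 3), dtype=bool))
    mask = remove_small_objects(mask, min_object_px)
    return SegmentationMask(mask, "rgb", {
        "threshold": threshold, "min_object_px": min_object_px,
        "reference_tol": reference_tol,
    })


def leaf_band(mask, upper_frac: float = DEFAULT_BAND[0],
              lower_frac: float = DEFAULT_BAND[1]) -> SegmentationMask:
    """Restrict a plant mask to the leaf-2/3/4 height band.

    Plant height is (lowest plant row - highest plant row + 1); the band
    keeps plant pixels whose row offset from the plant top lies in
    [round(upper_frac*height), round(lower_frac*height)], inclusive.
    """
    m = as_bool_array(mask)
    plant_rows = np.flatnonzero(m.any(axis=1))
    if plant_rows.size == 0:
        raise EmptyPlantError("cannot band an empty plant mask")
    top, bottom = int(plant_rows[0]), int(plant_rows[-1])
    height = bottom - top + 1
    lo = int(round(upper_frac * height))
    hi = int(round(lower_frac * height))
    offsets = np.arange(m.shape[0]) - top
    in_band = (offsets >= lo) & (offsets <= hi)
    banded = m & in_band[:, None]
    params = dict(getattr(mask, "params", {}) or {})
    params.update({"band": (upper_frac, lower_frac)})
    return SegmentationMask(banded, getattr(mask, "modality", "unknown"), params)


@dataclass
class ColorFeatureSet:
    """Specific-leaf-image colour features (masked means in [0, 1]) and
    projected area (mean full-plant pixel count over views)."""

    r: float
    g: float
    b: float
    h: float
    s: float
    i: float
    projected_area: float
    n_views: int

    def as_dict(self) -> dict:
        return {"R": self.r, "G": self.g, "B": self.b,
                "H": self.h, "S": self.s, "I": self.i,
                "ProjectedArea": self.projected_area}


def extract_color_features(views) -> ColorFeatureSet:
    """Per-channel masked means over the leaf band, averaged across views.

    ``views`` is a sequence of ``(rgb_image, plant_mask, band_mask)``
    triples; ``plant_mask`` is the full segmentation (used for projected
    area) and ``band_mask`` its leaf-band restriction (used for the colour
    features). Views whose band mask is empty are skipped; if all are
    empty an EmptyPlantError is raised.
    """
    if not views:
        raise EmptyPlantError("no views supplied")
    channel_sums = np.zeros(6)
    n_used = 0
    areas = []
    for rgb, plant_mask, band_mask in views:
        arr = _check_rgb(rgb)
        pm = as_bool_array(plant_mask)
        bm = as_bool_array(band_mask)
        if pm.shape != arr.shape[:2] or bm.shape != arr.shape[:2]:
            raise ShapeMismatchError("mask shape does not match image")
        areas.append(int(pm.sum()))
        if not bm.any():
            continue
        hsi = rgb_to_hsi(arr)
        means = np.concatenate([arr[bm].mean(axis=0), hsi[bm].mean(axis=0)])
        channel_sums += means  # order: R, G, B, H, S, I
        n_used += 1
    if n_used == 0:
        raise EmptyPlantError("all views have empty leaf-band masks")
    r, g, b, h, s, i = channel_sums / n_used
    return ColorFeatureSet(
        r=float(r), g=float(g), b=float(b), h=float(h), s=float(s), i=float(i),
        projected_area=float(np.mean(areas)), n_views=len(views),
    )
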