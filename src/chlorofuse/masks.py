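"""Binary plant/background masks and the shared post-processing rules.

All three segmenters (RGB color index, hyperspectral two-band score,
fluorescence intensity) produce a :class:`SegmentationMask` and share the
same small-object filter: connected components (8-connectivity) with fewer
than ``min_object_px`` pixels are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label

DEFAULT_MIN_OBJECT_PX = 200


@dataclass
class SegmentationMask:
    """Binary plant mask aligned to its source image.

    ``data`` is a boolean array of the source image's spatial shape;
    ``modality`` and ``params`` record how the mask was produced.
    """

    data: np.ndarray
    modality: str = "unknown"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    def __array__(self, dtype=None, copy=None):
        arr = self.data
        if dtype is not None:
            arr = arr.astype(dtype)
        return arr

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_pixels(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not bool(self.data.any())


def as_bool_array(mask) -> np.ndarray:
    """Accept a SegmentationMask or any array-like and return a bool array."""
    if isinstance(mask, SegmentationMask):
        return mask.data
    return np.asarray(mask, dtype=bool)


def remove_small_objects(mask, min_object_px: int = DEFAULT_MIN_OBJECT_PX) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_object_px`` pixels."""
    arr = as_bool_array(mask)
    if min_object_px <= 1 or not arr.any():
        return arr.copy()
    labels, n = label(arr, connectivity=2, return_num=True)
    if n == 0:
        return arr.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_object_px
    keep[0] = False
    return keep[labels]


def jaccard(mask_a, mask_b) -> float:
    """Intersection-over-union of two binary masks (1.0 if both empty)."""
    a = as_bool_array(mask_a)
    b = as_bool_array(mask_b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
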