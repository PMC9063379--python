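"""Hyperspectral cubes: BIL I/O, reflectance calibration, segmentation, indices.

A side-view line-scan camera stores cubes band-interleaved-by-line (BIL)
with an ENVI-style text header. Raw counts are calibrated to reflectance
with white/dark reference lines, plant pixels are segmented from the
two-band red-edge contrast (705 and 750 nm), and plant-level red-edge
vegetation indices are computed from the mean plant reflectance spectrum
(the "specific leaf image" convention: average reflectance first, then
apply the index formula):

    NDVI  = (R750 - R705) / (R750 + R705)
    RVI   =  R750 / R705
    MCARI = ((R750 - R705) - 0.2 (R750 - R550)) * (R750 / R705)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    ConfigError,
    CorruptFileError,
    DegenerateFrameError,
    EmptyPlantError,
    ShapeMismatchError,
    UndefinedIndexError,
    UnsupportedFormatError,
)
from .masks import DEFAULT_MIN_OBJECT_PX, SegmentationMask, as_bool_array, remove_small_objects

# ENVI numeric data-type codes
_ENVI_DTYPES = {
    1: np.dtype("u1"), 2: np.dtype("i2"), 3: np.dtype("i4"),
    4: np.dtype("f4"), 5: np.dtype("f8"), 12: np.dtype("u2"),
    13: np.dtype("u4"), 14: np.dtype("i8"), 15: np.dtype("u8"),
}
_ENVI_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperspectralCube:
    """Raw-count cube, shape (lines, samples, bands), with band wavelengths."""

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ShapeMismatchError("cube must be (lines, samples, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ShapeMismatchError(
                f"{self.data.shape[2]} bands but {self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise ConfigError("wavelengths must be strictly increasing")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReflectanceCube(HyperspectralCube):
    """Calibrated cube; values are unitless reflectance clipped to [0, 1.5]."""


# ---------------------------------------------------------------------------
# ENVI-style header + BIL payload I/O
# ---------------------------------------------------------------------------


def _parse_envi_header(text: str) -> dict:
    header: dict = {}
    # join { ... } blocks (possibly multi-line) before splitting into fields
    text = text.strip()
    if text.startswith("ENVI"):
        text = text[4:]
    pattern = re.compile(r"^\s*([^=\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for match in pattern.finditer(text):
        key = match.group(1).strip().lower()
        value = match.group(2).strip()
        if value.startswith("{"):
            value = value.strip("{}").replace("\n", " ")
            header[key] = [v.strip() for v in value.split(",") if v.strip()]
        else:
            header[key] = value
    return header


def write_bil(cube: HyperspectralCube, raw_path, header_path) -> None:
    """Write a cube as raw BIL payload plus an ENVI-style text header."""
    data = np.ascontiguousarray(np.transpose(cube.data, (0, 2, 1)))  # line, band, sample
    dtype = data.dtype
    if dtype not in _ENVI_CODES:
        data = data.astype(np.float32)
        dtype = data.dtype
    data.tofile(raw_path)
    wl = ", ".join(f"{w:.1f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cube.samples}\n"
        f"lines = {cube.lines}\n"
        f"bands = {cube.bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        "interleave = bil\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    Path(header_path).write_text(header)


def read_bil(raw_path, header_path) -> HyperspectralCube:
    """Read a BIL cube described by an ENVI-style header.

    The payload is stored line-major, band-middle, sample-minor; it is
    de-interleaved to (lines, samples, bands).
    """
    header = _parse_envi_header(Path(header_path).read_text())
    try:
        samples = int(header["samples"])
        lines = int(header["lines"])
        bands = int(header["bands"])
    except KeyError as exc:
        raise CorruptFileError(f"header missing field {exc}") from exc
    interleave = str(header.get("interleave", "")).lower()
    if interleave != "bil":
        raise UnsupportedFormatError(f"interleave {interleave!r} is not supported (bil only)")
    dtype_code = int(header.get("data type", 4))
    if dtype_code not in _ENVI_DTYPES:
        raise UnsupportedFormatError(f"ENVI data type {dtype_code} is not supported")
    dtype = _ENVI_DTYPES[dtype_code]
    if int(header.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(header.get("header offset", 0))
    payload = np.fromfile(raw_path, dtype=dtype, offset=offset)
    expected = lines * samples * bands
    if payload.size != expected:
        raise CorruptFileError(
            f"payload holds {payload.size} values, header implies {expected}"
        )
    data = payload.reshape(lines, bands, samples).transpose(0, 2, 1)
    wl = header.get("wavelength")
    if wl is None:
        raise CorruptFileError("header missing wavelength list")
    wavelengths = np.asarray([float(w) for w in wl], dtype=float)
    if wavelengths.size != bands:
        raise CorruptFileError("wavelength list length does not match band count")
    return HyperspectralCube(data, wavelengths)


# ---------------------------------------------------------------------------
# Calibration and band lookup
# ---------------------------------------------------------------------------


def calibrate_reflectance(cube: HyperspectralCube, white_ref: np.ndarray,
                          dark_ref: np.ndarray) -> ReflectanceCube:
    """Two-reference calibration: (raw - dark) / (white - dark), per band.

    ``white_ref``/``dark_ref`` are per-band reference lines of shape
    (samples, bands). Bands where white equals dark are mapped to 0.
    Reflectance is clipped to [0, 1.5] (modest sensor overshoot allowed).
    """
    white = np.asarray(white_ref, dtype=float)
    dark = np.asarray(dark_ref, dtype=float)
    expected = (cube.samples, cube.bands)
    if white.shape != expected or dark.shape != expected:
        raise ShapeMismatchError(
            f"reference shapes {white.shape}/{dark.shape} do not match (samples, bands)={expected}"
        )
    denom = white - dark
    safe = np.where(denom == 0, 1.0, denom)
    refl = (cube.data.astype(float) - dark[None, :, :]) / safe[None, :, :]
    refl = np.where(denom[None, :, :] == 0, 0.0, refl)
    refl = np.clip(refl, 0.0, 1.5)
    return ReflectanceCube(refl, cube.wavelengths)


def band_at(cube_or_wavelengths, wavelength_nm: float) -> int:
    """Index of the band nearest ``wavelength_nm`` (ties go to the lower index).

    Raises ConfigError if the query lies outside the sampled range.
    """
    if isinstance(cube_or_wavelengths, HyperspectralCube):
        wl = cube_or_wavelengths.wavelengths
    else:
        wl = np.asarray(cube_or_wavelengths, dtype=float)
    if wavelength_nm < wl[0] or wavelength_nm > wl[-1]:
        raise ConfigError(
            f"{wavelength_nm} nm outside sampled range [{wl[0]}, {wl[-1]}] nm"
        )
    dist = np.abs(wl - wavelength_nm)
    return int(np.argmin(dist))  # argmin returns the first (lower) index on ties


# ---------------------------------------------------------------------------
# Segmentation and features
# ---------------------------------------------------------------------------


def _minmax_normalize(band_img: np.ndarray) -> np.ndarray:
    lo = float(band_img.min())
    hi = float(band_img.max())
    if hi == lo:
        raise DegenerateFrameError("band image is constant; cannot normalize")
    return (band_img - lo) / (hi - lo)


def segment_cube(cube: ReflectanceCube, threshold: float = 0.89,
                 min_object_px: int = DEFAULT_MIN_OBJECT_PX,
                 combiner: str = "mean") -> SegmentationMask:
    """Segment plant pixels from the 705/750 nm red-edge contrast.

    Each of the two band images is min-max normalized over the frame; the
    per-pixel score is their mean (or sum, halved threshold semantics left
    to the caller, via ``combiner``). Pixels with score >= ``threshold``
    form the mask, then the shared small-object rule is applied.
    """
    b705 = cube.data[:, :, band_at(cube, 705.0)].astype(float)
    b750 = cube.data[:, :, band_at(cube, 750.0)].astype(float)
    n705 = _minmax_normalize(b705)
    n750 = _minmax_normalize(b750)
    if combiner == "mean":
        score = 0.5 * (n705 + n750)
    elif combiner == "sum":
        score = n705 + n750
    else:
        raise ConfigError(f"unknown combiner {combiner!r}")
    mask = remove_small_objects(score >= threshold, min_object_px)
    return SegmentationMask(mask, "hsi", {
        "threshold": threshold, "combiner": combiner, "min_object_px": min_object_px,
    })


@dataclass
class SpectralFeatureSet:
    """Mean plant reflectance spectrum and the three red-edge indices."""

    spectrum: np.ndarray
    wavelengths: np.ndarray
    r550: float
    r705: float
    r750: float
    ndvi: float
    rvi: float
    mcari: float
    n_pixels: int = 0

    def as_dict(self) -> dict:
        return {"NDVI": self.ndvi, "RVI": self.rvi, "MCARI": self.mcari}


def vegetation_indices(r550: float, r705: float, r750: float) -> tuple[float, float, float]:
    """NDVI, RVI, MCARI from the three mean reflectances."""
    if r750 + r705 == 0:
        raise UndefinedIndexError("R750 + R705 = 0; NDVI undefined")
    if r705 == 0:
        raise UndefinedIndexError("R705 = 0; RVI undefined")
    ndvi = (r750 - r705) / (r750 + r705)
    rvi = r750 / r705
    mcari = ((r750 - r705) - 0.2 * (r750 - r550)) * (r750 / r705)
    return float(ndvi), float(rvi), float(mcari)


def spectral_features(cube: ReflectanceCube, mask) -> SpectralFeatureSet:
    """Mean plant spectrum and indices over the masked pixels.

    Indices are computed from the averaged reflectance (not averaged
    per-pixel indices), matching the plant-level "specific leaf image"
    definition.
    """
    m = as_bool_array(mask)
    if m.shape != cube.data.shape[:2]:
        raise ShapeMismatchError("mask shape does not match cube frame")
    if not m.any():
        raise EmptyPlantError("no plant pixels in mask")
    spectrum = cube.data[m].mean(axis=0).astype(float)
    r550 = float(spectrum[band_at(cube, 550.0)])
    r705 = float(spectrum[band_at(cube, 705.0)])
    r750 = float(spectrum[band_at(cube, 750.0)])
    ndvi, rvi, mcari = vegetation_indices(r550, r705, r750)
    return SpectralFeatureSet(
        spectrum=spectrum, wavelengths=cube.wavelengths.copy(),
        r550=r550, r705=r705, r750=r750,
        ndvi=ndvi, rvi=rvi, mcari=mcari, n_pixels=int(m.sum()),
    )
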