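"""Synthetic greenhouse study: trait tables and rendered plant scenes.

Emulates a sorghum phenotyping experiment — 15 genotypes x 20 plants under a
2x2 water (drought D vs well-watered HW) by nutrient (high HN vs low LN)
design, five replicates per combination — and renders, per plant, rotational
side-view RGB frames, one hyperspectral cube (BIL layout with white/dark
reference lines) and one steady-state fluorescence frame, all with
ground-truth plant masks.

The rendering model is deliberately minimal but physiologically oriented:

* chlorophyll rises logistically with days-after-sowing (DAS) to a
  genotype-specific plateau, shifted down by drought and low nutrition;
* specific leaf weight (SLW) is elevated under drought (thicker leaves);
* the plant silhouette's colour saturation, red-edge reflectance contrast
  and fluorescence intensity are each strictly monotone in true chlorophyll,
  with channel-specific pixel noise plus a per-plant "signal jitter" that
  emulates plant-to-plant variation in the signal-chlorophyll link.

Every mapping used by the renderer is exported in closed form
(:func:`plant_rgb_color`, :func:`plant_saturation`, :func:`leaf_reflectance`,
:func:`fluorescence_intensity`) so downstream feature extractors can be
tested against exact expected values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import opening

from .errors import ConfigError, InvalidDesignError, RenderError
from .hyperspectral import HyperspectralCube
from .masks import SegmentationMask

# ---------------------------------------------------------------------------
# Closed-form signal models (chlorophyll in umol/m^2)
# ---------------------------------------------------------------------------

#: chlorophyll value at which the colour/fluorescence mappings saturate
CHL_SCALE_MAX = 650.0
#: chlorophyll-independent near-infrared reflectance plateau
NIR_REFLECTANCE = 0.55
#: flat background reflectance of the imaging chamber wall
BACKGROUND_REFLECTANCE = 0.05
#: flat grey RGB background of the imaging chamber
BACKGROUND_RGB = (0.20, 0.20, 0.20)
#: warm-tinted vertical edge stripes (exercises reference-frame removal)
STRIPE_RGB = (0.60, 0.45, 0.30)
#: fluorescence background intensity
FLUO_BACKGROUND = 0.04


def _chl_unit(chl) -> np.ndarray:
    return np.clip(np.asarray(chl, dtype=float) / CHL_SCALE_MAX, 0.0, 1.0)


def plant_rgb_color(chl):
    """RGB colour painted on plant pixels for true chlorophyll ``chl``.

    A green whose HSI saturation increases strictly with chlorophyll while
    overall brightness decreases (darker, more saturated leaves at high
    chlorophyll): R = B = g*(1-s), G = g with s in [0.55, 0.90] and
    g in [0.45, 0.39].
    """
    u = _chl_unit(chl)
    s = 0.55 + 0.35 * u
    g = 0.45 - 0.06 * u
    r = b = g * (1.0 - s)
    return np.stack(np.broadcast_arrays(r, g, b), axis=-1)


def plant_saturation(chl):
    """HSI saturation of :func:`plant_rgb_color` — s/(3-2s) in closed form."""
    s = 0.55 + 0.35 * _chl_unit(chl)
    return s / (3.0 - 2.0 * s)


def fluorescence_intensity(chl):
    """Noiseless plant-pixel fluorescence intensity, linear in chlorophyll."""
    return 0.25 + 0.50 * _chl_unit(chl)


def leaf_reflectance(wavelengths_nm, chl):
    """Parametric leaf reflectance spectrum.

    Visible plateau with Beer-Lambert-style chlorophyll absorption,
    R_vis = 0.08 + 0.42*exp(-chl/300), joined to the chlorophyll-independent
    NIR plateau by a sigmoidal red edge centred at 725 nm (width 8 nm):

        R(lambda) = R_vis + (R_NIR - R_vis) * sigmoid((lambda - 725)/8)

    NDVI/RVI/MCARI built from 550/705/750 nm are strictly monotone in chl.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    r_vis = 0.08 + 0.42 * np.exp(-np.asarray(chl, dtype=float) / 300.0)
    edge = 1.0 / (1.0 + np.exp(-(wl - 725.0) / 8.0))
    return r_vis + (NIR_REFLECTANCE - r_vis) * edge


def white_reference_counts(wavelengths_nm):
    """Per-band white-reference count level (halogen-like illumination)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return 1200.0 + 2800.0 * np.exp(-(((wl - 1000.0) / 700.0) ** 2))


#: flat dark-current count level
DARK_COUNTS = 100.0


# ---------------------------------------------------------------------------
# Study design and trait table
# ---------------------------------------------------------------------------

DEFAULT_TREATMENTS = (("D", "HN"), ("D", "LN"), ("HW", "HN"), ("HW", "LN"))
DEFAULT_DAS_SCHEDULE = (20, 30, 40, 50, 60)


@dataclass
class StudyDesign:
    """Factorial greenhouse design: genotypes x plants, water x nutrient."""

    n_genotypes: int = 15
    plants_per_genotype: int = 20
    treatments: tuple = DEFAULT_TREATMENTS
    das_schedule: tuple = DEFAULT_DAS_SCHEDULE
    rng_seed: int = 0
    # effect sizes (umol/m^2 for chlorophyll, g/cm^2 for SLW)
    asymptote_range: tuple = (380.0, 560.0)
    drought_chl_shift: float = -60.0
    lown_chl_shift: float = -50.0
    chl_noise_sd: float = 20.0
    slw_base: float = 0.0045
    slw_drought_shift: float = 0.0012
    slw_lown_shift: float = 0.0003
    slw_noise_sd: float = 0.0004
    meter_noise_sd: float = 15.0

    @property
    def n_plants(self) -> int:
        return self.n_genotypes * self.plants_per_genotype

    def validate(self) -> None:
        if self.n_genotypes <= 0 or self.plants_per_genotype <= 0:
            raise InvalidDesignError("genotype and plant counts must be positive")
        if not self.treatments:
            raise InvalidDesignError("at least one treatment combination required")
        if self.plants_per_genotype % len(self.treatments) != 0:
            raise InvalidDesignError(
                "plants_per_genotype must be divisible by the number of "
                f"treatment combinations ({len(self.treatments)})"
            )
        das = tuple(self.das_schedule)
        if not das or any(b <= a for a, b in zip(das, das[1:])):
            raise InvalidDesignError("das_schedule must be strictly increasing")


@dataclass
class TraitRecord:
    """Ground truth for one plant."""

    plant_id: str
    genotype: str
    water: str
    nutrient: str
    das: int
    slw: float
    chl_true: float
    chl_measured: float
    plant_height_px: int


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_trait_table(design: StudyDesign) -> list[TraitRecord]:
    """Generate one trait record per plant, deterministically for a seed.

    Chlorophyll follows A_g * logistic((DAS-25)/8) with genotype asymptote
    A_g, additive treatment shifts and plant-level noise; the meter reading
    is the average of nine noisy spot measurements of the true value.
    """
    design.validate()
    rng = np.random.default_rng(design.rng_seed)
    replicates = design.plants_per_genotype // len(design.treatments)
    das_schedule = tuple(design.das_schedule)
    records: list[TraitRecord] = []
    for g in range(design.n_genotypes):
        genotype = f"G{g + 1:02d}"
        asymptote = rng.uniform(*design.asymptote_range)
        for water, nutrient in design.treatments:
            for rep in range(replicates):
                das = das_schedule[rep % len(das_schedule)]
                chl = asymptote * float(_logistic((das - 25.0) / 8.0))
                if water == "D":
                    chl += design.drought_chl_shift
                if nutrient == "LN":
                    chl += design.lown_chl_shift
                chl += rng.normal(0.0, design.chl_noise_sd) if design.chl_noise_sd > 0 else 0.0
                chl = max(chl, 0.0)
                slw = design.slw_base
                if water == "D":
                    slw += design.slw_drought_shift
                if nutrient == "LN":
                    slw += design.slw_lown_shift
                if design.slw_noise_sd > 0:
                    slw += rng.normal(0.0, design.slw_noise_sd)
                slw = max(slw, 5e-4)
                if design.meter_noise_sd > 0:
                    spots = chl + rng.normal(0.0, design.meter_noise_sd, size=9)
                    chl_measured = max(float(spots.mean()), 0.0)
                else:
                    chl_measured = chl
                height = 256.0 * (0.55 + 0.35 * float(_logistic((das - 25.0) / 8.0)))
                height += rng.normal(0.0, 5.0)
                records.append(
                    TraitRecord(
                        plant_id=f"{genotype}_{water}{nutrient}_r{rep + 1}",
                        genotype=genotype,
                        water=water,
                        nutrient=nutrient,
                        das=int(das),
                        slw=float(slw),
                        chl_true=float(chl),
                        chl_measured=float(chl_measured),
                        plant_height_px=int(np.clip(round(height), 100, 245)),
                    )
                )
    return records


TRAIT_CSV_COLUMNS = [
    "plant_id", "genotype", "water", "nutrient",
    "das", "slw", "chl_true", "chl_measured",
]


def trait_table_to_frame(records: Sequence[TraitRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def write_trait_csv(records: Sequence[TraitRecord], path) -> None:
    trait_table_to_frame(records)[TRAIT_CSV_COLUMNS].to_csv(path, index=False)


def read_trait_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Render configuration and plant geometry
# ---------------------------------------------------------------------------


def default_band_wavelengths() -> tuple:
    """243 bands at 5 nm from 550 nm (covers 550/705/750 exactly)."""
    return tuple(float(w) for w in np.arange(243) * 5.0 + 550.0)


@dataclass
class RenderConfig:
    """Scene geometry, spectral sampling and per-modality noise levels.

    ``*_noise_sd`` is independent per-pixel Gaussian noise; ``*_jitter_sd``
    is a per-plant relative perturbation of the chlorophyll value driving
    that modality's signal (plant-to-plant variation of the signal link).
    """

    image_size: tuple = (256, 256)
    n_views: int = 10
    band_wavelengths: tuple = field(default_factory=default_band_wavelengths)
    background_model: str = "flat"
    stripe_period: int = 24
    stripe_width: int = 3
    rgb_noise_sd: float = 0.01
    hsi_noise_sd: float = 0.002
    fluo_noise_sd: float = 0.015
    rgb_jitter_sd: float = 0.10
    hsi_jitter_sd: float = 0.10
    fluo_jitter_sd: float = 0.10

    def validate(self) -> None:
        if self.n_views < 1:
            raise ConfigError("n_views must be >= 1")
        wl = np.asarray(self.band_wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ConfigError("band_wavelengths must be strictly increasing")
        for name in ("rgb_noise_sd", "hsi_noise_sd", "fluo_noise_sd",
                     "rgb_jitter_sd", "hsi_jitter_sd", "fluo_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.background_model not in ("flat", "striped"):
            raise ConfigError("background_model must be 'flat' or 'striped'")

    @classmethod
    def noiseless(cls, **overrides) -> "RenderConfig":
        """Configuration with all noise and jitter terms set to zero."""
        params = dict(
            rgb_noise_sd=0.0, hsi_noise_sd=0.0, fluo_noise_sd=0.0,
            rgb_jitter_sd=0.0, hsi_jitter_sd=0.0, fluo_jitter_sd=0.0,
        )
        params.update(overrides)
        return cls(**params)


def stable_seed(*parts) -> int:
    """Deterministic, process-independent seed from string parts (< 2^31)."""
    return zlib.crc32("/".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


# leaf number -> fractional distance of its insertion from the plant top;
# leaves 2-4 sit inside the 5-35 % height band used for feature extraction
_LEAF_FRACTIONS = ((1, 0.00), (2, 0.08), (3, 0.18), (4, 0.30), (5, 0.48), (6, 0.68))


def _geometry_params(record: TraitRecord) -> dict:
    rng = np.random.default_rng(stable_seed(record.plant_id, "geometry"))
    return {
        "flip": 1 if rng.random() < 0.5 else -1,
        "length_u": rng.uniform(0.8, 1.2, size=len(_LEAF_FRACTIONS)),
        "phase": rng.uniform(0.0, 2.0 * np.pi, size=len(_LEAF_FRACTIONS)),
    }


def render_silhouette(record: TraitRecord, config: RenderConfig, view: int = 0):
    """Boolean plant silhouette for one rotational view plus leaf centroids.

    The silhouette is morphologically open (a 3x3 opening is applied during
    construction, so downstream opening with the same element is the
    identity). Returns ``(mask, centroids)`` with ``centroids`` mapping leaf
    number -> (row, col) of the leaf's insertion point.
    """
    config.validate()
    rows, cols = config.image_size
    height = int(round(record.plant_height_px * rows / 256.0))
    base_row = rows - max(2, rows // 64)
    # tall plants are cropped to the frame, as by a real chamber camera
    height = min(height, base_row - max(3, round(0.035 * rows)) - 2)
    if height < 40 or cols < 48:
        raise RenderError(
            f"frame {config.image_size} too small for plant of height {height}px"
        )
    a_r_max = max(3, round(0.035 * height))
    params = _geometry_params(record)
    top_row = base_row - height + 1
    if top_row - a_r_max < 1:
        raise RenderError("plant silhouette does not fit vertically")
    mask = np.zeros((rows, cols), dtype=bool)
    cc = cols // 2
    stem_hw = max(1, round(cols / 100))
    mask[top_row:base_row + 1, cc - stem_hw:cc + stem_hw + 1] = True
    centroids: dict[int, tuple[int, int]] = {}
    angle = 2.0 * np.pi * view / config.n_views
    for i, (leaf, frac) in enumerate(_LEAF_FRACTIONS):
        r_c = top_row + int(round(frac * (height - 1)))
        view_scale = 0.55 + 0.45 * abs(np.cos(angle + params["phase"][i]))
        a_c = max(6, int(round(0.30 * cols * params["length_u"][i] * view_scale)))
        a_r = max(3, round(0.035 * height))
        side = params["flip"] * (1 if leaf % 2 else -1)
        c_c = int(np.clip(cc + side * int(round(0.75 * a_c)), a_r + 1, cols - a_r - 2))
        rr, cc_idx = draw_ellipse(r_c, c_c, a_r, a_c, shape=(rows, cols))
        mask[rr, cc_idx] = True
        centroids[leaf] = (r_c, c_c)
    mask = opening(mask, footprint=np.ones((3, 3), dtype=bool))
    return mask, centroids


def _background_rgb(config: RenderConfig) -> np.ndarray:
    rows, cols = config.image_size
    img = np.empty((rows, cols, 3), dtype=float)
    img[:] = BACKGROUND_RGB
    if config.background_model == "striped":
        phase = np.arange(cols) % config.stripe_period
        stripe_cols = phase < config.stripe_width
        img[:, stripe_cols, :] = STRIPE_RGB
    return img


# ---------------------------------------------------------------------------
# Renderers
# ---------------------------------------------------------------------------


def render_rgb_views(record: TraitRecord, config: RenderConfig, rng=None):
    """Render ``config.n_views`` rotational RGB side views with truth masks."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(stable_seed(record.plant_id, "rgb"))
    jitter = rng.normal(0.0, config.rgb_jitter_sd) if config.rgb_jitter_sd > 0 else 0.0
    chl_eff = max(record.chl_true * (1.0 + jitter), 0.0)
    color = plant_rgb_color(chl_eff)
    images, masks = [], []
    for view in range(config.n_views):
        mask, _ = render_silhouette(record, config, view)
        img = _background_rgb(config)
        img[mask] = color
        if config.rgb_noise_sd > 0:
            img = img + rng.normal(0.0, config.rgb_noise_sd, size=img.shape)
        images.append(np.clip(img, 0.0, 1.0))
        masks.append(SegmentationMask(mask, "rgb-truth", {"view": view}))
    return images, masks


def render_rgb_reference(config: RenderConfig, rng=None) -> np.ndarray:
    """Empty-chamber reference frame (same background model, no plant)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(stable_seed("reference", "rgb"))
    img = _background_rgb(config)
    if config.rgb_noise_sd > 0:
        img = img + rng.normal(0.0, config.rgb_noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def render_hyperspectral_cube(record: TraitRecord, config: RenderConfig, rng=None):
    """Render a raw-count hyperspectral cube plus truth mask and references.

    Returns ``(cube, mask, white, dark)`` where ``cube.data`` has shape
    (lines, samples, bands) in raw counts and ``white``/``dark`` are
    per-band reference lines of shape (samples, bands), as produced by a
    line-scan camera. Reflectance is recovered by the standard two-reference
    calibration.
    """
    config.validate()
    wl = np.asarray(config.band_wavelengths, dtype=float)
    for needed in (550.0, 705.0, 750.0):
        if needed < wl[0] or needed > wl[-1]:
            raise ConfigError(f"band_wavelengths must cover {needed} nm")
    if rng is None:
        rng = np.random.default_rng(stable_seed(record.plant_id, "hsi"))
    jitter = rng.normal(0.0, config.hsi_jitter_sd) if config.hsi_jitter_sd > 0 else 0.0
    chl_eff = max(record.chl_true * (1.0 + jitter), 0.0)
    mask, _ = render_silhouette(record, config, view=0)
    rows, cols = config.image_size
    refl = np.full((rows, cols, wl.size), BACKGROUND_REFLECTANCE, dtype=np.float32)
    refl[mask] = leaf_reflectance(wl, chl_eff).astype(np.float32)
    if config.hsi_noise_sd > 0:
        refl = refl + rng.normal(0.0, config.hsi_noise_sd, size=refl.shape).astype(np.float32)
    white_band = white_reference_counts(wl)
    white = np.tile(white_band, (cols, 1)).astype(np.float32)
    dark = np.full((cols, wl.size), DARK_COUNTS, dtype=np.float32)
    raw = DARK_COUNTS + refl * (white_band - DARK_COUNTS).astype(np.float32)
    cube = HyperspectralCube(raw.astype(np.float32), wl)
    return cube, SegmentationMask(mask, "hsi-truth", {}), white, dark


def render_fluorescence_image(record: TraitRecord, config: RenderConfig, rng=None):
    """Render one grayscale steady-state fluorescence frame with truth mask."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(stable_seed(record.plant_id, "fluo"))
    jitter = rng.normal(0.0, config.fluo_jitter_sd) if config.fluo_jitter_sd > 0 else 0.0
    chl_eff = max(record.chl_true * (1.0 + jitter), 0.0)
    mask, _ = render_silhouette(record, config, view=0)
    img = np.full(config.image_size, FLUO_BACKGROUND, dtype=float)
    img[mask] = float(fluorescence_intensity(chl_eff))
    if config.fluo_noise_sd > 0:
        img = img + rng.normal(0.0, config.fluo_noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), SegmentationMask(mask, "fluo-truth", {})


@dataclass
class PlantImageSet:
    """All rendered modalities for one plant plus ground-truth masks."""

    record: TraitRecord
    rgb_views: list
    rgb_masks: list
    cube: HyperspectralCube
    cube_mask: SegmentationMask
    white: np.ndarray
    dark: np.ndarray
    fluo: np.ndarray
    fluo_mask: SegmentationMask


def render_plant_set(record: TraitRecord, config: RenderConfig,
                     seed: int | None = None) -> PlantImageSet:
    """Render all three modalities for one plant.

    ``seed`` (if given) is mixed with the plant id so that the whole set is
    reproducible from a single run-level seed.
    """
    def _rng(modality):
        if seed is None:
            return None
        return np.random.default_rng(stable_seed(seed, record.plant_id, modality))

    rgb_views, rgb_masks = render_rgb_views(record, config, rng=_rng("rgb"))
    cube, cube_mask, white, dark = render_hyperspectral_cube(
        record, config, rng=_rng("hsi"))
    fluo, fluo_mask = render_fluorescence_image(record, config, rng=_rng("fluo"))
    return PlantImageSet(record, rgb_views, rgb_masks, cube, cube_mask,
                         white, dark, fluo, fluo_mask)


# ---------------------------------------------------------------------------
# Image writers (external interface; the pipeline works in memory)
# ---------------------------------------------------------------------------


def write_mask_png(mask, path) -> None:
    import imageio.v3 as iio

    from .masks import as_bool_array

    iio.imwrite(path, (as_bool_array(mask).astype(np.uint8) * 255))


def write_rgb_png(img: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.clip(np.asarray(img) * 255.0, 0, 255).astype(np.uint8))


def write_gray_png(img: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.clip(np.asarray(img) * 65535.0, 0, 65535).astype(np.uint16))
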