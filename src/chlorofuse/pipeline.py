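"""End-to-end run: synthetic study -> per-modality features -> fused models.

One seeded, configurable pass over the whole method: generate the trait
table, render each plant's RGB views / hyperspectral cube / fluorescence
frame, segment each modality with its threshold (colour index 0.75,
red-edge score 0.89, fluorescence intensity 0.13), extract the fused
feature table, then fit the per-feature MLR family (with/without SLW, AIC)
and the fused PLSR models (features only; +DAS; +DAS+SLW; each also with
hue dropped), reporting R^2/RMSE/RPD on the cross-validated calibration,
calibration, validation and entire sets.

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import color, fluorescence, hyperspectral, modeling, synthetic
from .errors import ChlorofuseError, EmptyPlantError
from .masks import jaccard

#: image features entering the per-feature MLR family and the fused PLSR
FEATURE_COLUMNS = ["R", "G", "B", "H", "S", "I", "NDVI", "RVI", "MCARI", "Fluo"]


class PipelineError(ChlorofuseError):
    """Stage failure, tagged with the stage name and plant id."""

    def __init__(self, stage: str, plant_id: str, cause: Exception):
        super().__init__(f"[{stage}] plant {plant_id}: {cause}")
        self.stage = stage
        self.plant_id = plant_id
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; defaults are the published
    operating points (thresholds 0.75 / 0.89 / 0.13, 5-35 % leaf band,
    200 px object filter, 80/20 split, fivefold CV)."""

    design: synthetic.StudyDesign = field(default_factory=synthetic.StudyDesign)
    render: synthetic.RenderConfig = field(default_factory=synthetic.RenderConfig)
    rgb_threshold: float = color.DEFAULT_RGB_THRESHOLD
    hsi_threshold: float = 0.89
    fluo_threshold: float = fluorescence.DEFAULT_FLUO_THRESHOLD
    band: tuple = color.DEFAULT_BAND
    min_object_px: int = 200
    reference_tol: float = color.DEFAULT_REFERENCE_TOL
    split_frac: float = modeling.DEFAULT_SPLIT_FRAC
    folds: int = modeling.DEFAULT_FOLDS
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        design = synthetic.StudyDesign(**d.pop("design", {}))
        render_kwargs = d.pop("render", {})
        if "image_size" in render_kwargs:
            render_kwargs["image_size"] = tuple(render_kwargs["image_size"])
        render = synthetic.RenderConfig(**render_kwargs)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(design=design, render=render, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def extract_plant_features(image_set: synthetic.PlantImageSet, config: RunConfig,
                           reference: np.ndarray) -> dict:
    """Segment all modalities of one plant and return its feature row.

    The row also carries the mean Jaccard overlap of each modality's mask
    with the renderer's ground truth, for the run report.
    """
    record = image_set.record
    pid = record.plant_id
    try:
        views = []
        rgb_jaccards = []
        for img, truth in zip(image_set.rgb_views, image_set.rgb_masks):
            mask = color.segment_rgb(img, reference, config.rgb_threshold,
                                     config.min_object_px, config.reference_tol)
            band = color.leaf_band(mask, *config.band)
            views.append((img, mask, band))
            rgb_jaccards.append(jaccard(mask, truth))
        cf = color.extract_color_features(views)
    except ChlorofuseError as exc:
        raise PipelineError("rgb", pid, exc) from exc
    try:
        refl = hyperspectral.calibrate_reflectance(
            image_set.cube, image_set.white, image_set.dark)
        hsi_mask = hyperspectral.segment_cube(
            refl, config.hsi_threshold, config.min_object_px)
        sf = hyperspectral.spectral_features(refl, hsi_mask)
        hsi_j = jaccard(hsi_mask, image_set.cube_mask)
    except ChlorofuseError as exc:
        raise PipelineError("hsi", pid, exc) from exc
    try:
        fl_mask = fluorescence.segment_fluorescence(
            image_set.fluo, config.fluo_threshold, config.min_object_px)
        fluo_feat = fluorescence.fluorescence_feature([(image_set.fluo, fl_mask)])
        fluo_j = jaccard(fl_mask, image_set.fluo_mask)
    except ChlorofuseError as exc:
        raise PipelineError("fluo", pid, exc) from exc
    return {
        "plant_id": pid, "genotype": record.genotype,
        "water": record.water, "nutrient": record.nutrient,
        "DAS": record.das, "SLW": record.slw,
        "Chl": record.chl_measured, "chl_true": record.chl_true,
        "R": cf.r, "G": cf.g, "B": cf.b, "H": cf.h, "S": cf.s, "I": cf.i,
        "NDVI": sf.ndvi, "RVI": sf.rvi, "MCARI": sf.mcari, "Fluo": fluo_feat,
        "ProjectedArea": cf.projected_area,
        "jaccard_rgb": float(np.mean(rgb_jaccards)),
        "jaccard_hsi": hsi_j, "jaccard_fluo": fluo_j,
    }


def build_feature_table(config: RunConfig) -> pd.DataFrame:
    """Render and process every plant of the configured design."""
    design = dataclasses.replace(config.design, rng_seed=config.seed)
    records = synthetic.generate_trait_table(design)
    reference = synthetic.render_rgb_reference(
        config.render,
        rng=np.random.default_rng(synthetic.stable_seed(config.seed, "reference")))
    rows = []
    for record in records:
        image_set = synthetic.render_plant_set(record, config.render, seed=config.seed)
        rows.append(extract_plant_features(image_set, config, reference))
    return pd.DataFrame(rows)


def _usable_features(table: pd.DataFrame) -> list:
    """Image features with non-zero variance in this table.

    In the exact zero-noise limit a channel can be constant across plants
    (e.g. hue of a fixed green); such columns cannot enter a standardized
    or least-squares fit and are dropped with a warning.
    """
    import warnings

    usable = []
    for feature in FEATURE_COLUMNS:
        col = table[feature].to_numpy(float)
        if col.std() > 1e-10 * (1.0 + np.abs(col).max()):
            usable.append(feature)
        else:
            warnings.warn(f"feature {feature!r} is constant; dropped from models",
                          stacklevel=3)
    return usable


def fit_mlr_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature MLR family: each image feature with DAS, then DAS + SLW."""
    rows = []
    for feature in _usable_features(table):
        for include_slw in (False, True):
            fit = modeling.fit_mlr(table, feature, include_slw=include_slw)
            rows.append({
                "predictor": feature, "formula": fit.formula,
                "terms": "+".join(fit.terms),
                "r2": fit.r2, "aic": fit.aic, "n": fit.n,
            })
    return pd.DataFrame(rows)


PLSR_MODELS = {
    "model1": FEATURE_COLUMNS,
    "model2": FEATURE_COLUMNS + ["DAS"],
    "model3": FEATURE_COLUMNS + ["DAS", "SLW"],
}


def _metrics_row(fit: modeling.PLSRFit, cal: pd.DataFrame, val: pd.DataFrame,
                 table: pd.DataFrame) -> dict:
    row = {"n_components": fit.n_components,
           "importance": ">".join(fit.importance)}
    row.update(fit.cv_metrics.as_dict("cv_"))
    row.update(modeling.evaluate(
        cal["Chl"].to_numpy(float), fit.predict(cal)).as_dict("cal_"))
    if len(val) >= 2:
        row.update(modeling.evaluate(
            val["Chl"].to_numpy(float), fit.predict(val)).as_dict("val_"))
    row.update(modeling.evaluate(
        table["Chl"].to_numpy(float), fit.predict(table)).as_dict("entire_"))
    return row


def fit_plsr_models(table: pd.DataFrame, config: RunConfig):
    """Fused PLSR models 1-3, each full and hue-reduced, on the 80/20 split."""
    cal, val = modeling.split_calibration_validation(
        table, config.split_frac, seed=config.seed)
    usable = set(_usable_features(table))
    rows = []
    fits = {}
    for name, all_predictors in PLSR_MODELS.items():
        predictors = [p for p in all_predictors
                      if p in usable or p not in FEATURE_COLUMNS]
        for variant, preds in (("full", predictors),
                               ("hue_reduced", [p for p in predictors if p != "H"])):
            fit = modeling.cross_validate_plsr(
                cal, preds, k_folds=config.folds, seed=config.seed)
            row = {"model": name, "feature_set": variant}
            row.update(_metrics_row(fit, cal, val, table))
            rows.append(row)
            fits[(name, variant)] = fit
    return pd.DataFrame(rows), fits, cal, val


def _json_safe(obj):
    """Make a report strictly JSON-serializable (inf/nan become strings)."""
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and optionally write) the run report."""
    table = build_feature_table(config)
    mlr = fit_mlr_table(table)
    plsr, fits, cal, val = fit_plsr_models(table, config)
    report = {
        "config": config.echo(),
        "n_plants": int(len(table)),
        "n_views": int(config.render.n_views),
        "n_calibration": int(len(cal)),
        "n_validation": int(len(val)),
        "mean_jaccard": {
            "rgb": float(table["jaccard_rgb"].mean()),
            "hsi": float(table["jaccard_hsi"].mean()),
            "fluo": float(table["jaccard_fluo"].mean()),
        },
        "mlr": mlr.to_dict(orient="records"),
        "plsr": plsr.to_dict(orient="records"),
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "features.csv", index=False)
        mlr.to_csv(out / "models_mlr.csv", index=False)
        plsr.to_csv(out / "models_plsr.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(_json_safe(report), fh, indent=2, default=str)
    report["_feature_table"] = table
    report["_plsr_fits"] = fits
    return report
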