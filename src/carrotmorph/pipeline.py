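"""Batch pipeline: per-image measurement, then model-based prediction.

Stage one (``run_measure``) processes each photograph independently —
segmentation, biomass profiles, classic morphometrics, width-descriptor
sampling — writing one JSON record per image, combined CSVs, QC overlays,
and a reason-coded failure log.  A failing image never aborts the batch.

Stage two (``run_predict``) fits the three petiole-trait models on a
ground-truth table, persists them as versioned JSON, and predicts traits
for every measured image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import trait_models
from .imaging import SegmentationError, qc_overlay, segment_image
from .morphometrics import Calibration, region_measurements, to_cm
from .profiles import (normalize_root_profile, root_biomass_profile,
                       shoot_biomass_profile)
from .trait_models import (PetioleLengthRegressor, PetioleWidthRegressor,
                           PlsTraitRegressor, petiole_count_feature)

__all__ = ["PipelineConfig", "run_measure", "run_predict"]

RECORD_SCHEMA_VERSION = 1
TRUTH_COLUMNS = ("image_id", "petiole_number", "petiole_length_cm",
                 "petiole_width_cm")


@dataclass
class PipelineConfig:
    """Knobs of the batch pipeline (see module docstrings for semantics)."""

    px_per_cm: float | None = None
    n_bins: int = 1000
    min_object_fraction: float = 1e-4
    band_half_height: int = 3
    border_policy: str = "error"
    darkness_margin: float = 0.2
    cv: str = "loo"
    seed: int = 0
    write_qc: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")


def _measure_one(image: np.ndarray, config: PipelineConfig) -> dict:
    segments = segment_image(
        image,
        min_object_fraction=config.min_object_fraction,
        band_half_height=config.band_half_height,
        border_policy=config.border_policy,
        darkness_margin=config.darkness_margin,
    )
    sbp = shoot_biomass_profile(segments.shoot_mask, segments.crown,
                                n=config.n_bins)
    root = root_biomass_profile(segments.root_mask, n=config.n_bins)
    root_norm = normalize_root_profile(root)
    shoot_m = region_measurements(segments.shoot_mask)
    root_m = region_measurements(segments.root_mask)
    edt_samples = trait_models.skeleton_edt_samples(segments.shoot_mask)

    record = {
        "schema_version": RECORD_SCHEMA_VERSION,
        "divider_row": segments.divider_row,
        "crown": list(segments.crown),
        "shoot": shoot_m.as_dict(),
        "root": root_m.as_dict(),
        "sbp": np.round(sbp.values, 6).tolist(),
        "root_profile": np.round(root.values, 6).tolist(),
        "root_profile_normalized": np.round(root_norm.values, 6).tolist(),
        "shoot_area_px": sbp.source_area_px,
        "root_area_px": root.source_area_px,
        "edt_samples": np.round(edt_samples, 4).tolist(),
    }
    if config.px_per_cm:
        cal = Calibration(config.px_per_cm)
        record["calibration_px_per_cm"] = config.px_per_cm
        record["shoot_cm"] = {
            "height_cm": to_cm(shoot_m.bbox_height_px, cal),
            "area_cm2": to_cm(shoot_m.area_px, cal, power=2),
        }
        record["root_cm"] = {
            "length_cm": to_cm(root_m.bbox_height_px, cal),
            "width_cm": to_cm(root_m.bbox_width_px, cal),
            "area_cm2": to_cm(root_m.area_px, cal, power=2),
        }
    return record, segments


_FAILURE_REASONS = {
    "no contrast": "no_contrast",
    "no plant detected": "no_plant",
    "divider not found": "no_divider",
    "plant overlaps image border": "border_overlap",
    "no shoot foreground above divider": "one_sided_mask",
    "no root foreground below divider": "one_sided_mask",
    "no root": "one_sided_mask",
}


def _reason_code(exc: Exception) -> str:
    return _FAILURE_REASONS.get(str(exc), "unknown")


def run_measure(inputs, out_dir, config: PipelineConfig | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure a batch of images.

    ``inputs`` is a directory/glob of TIF/PNG files, or a list of
    (image_id, HxWx3 array) pairs.  Writes ``records/<id>.json``,
    ``qc/<id>.png``, ``morphometrics.csv``, ``sbp.csv``,
    ``root_profile.csv`` and ``failures.csv`` under ``out_dir``.  Returns
    (measurements table, failure log).
    """
    config = config or PipelineConfig()
    items = _resolve_inputs(inputs)
    if not items:
        raise ValueError("empty input set")

    out_dir = Path(out_dir)
    (out_dir / "records").mkdir(parents=True, exist_ok=True)
    if config.write_qc:
        (out_dir / "qc").mkdir(exist_ok=True)

    rows, failures = [], []
    sbp_rows, root_rows = {}, {}
    for image_id, loader in items:
        try:
            image = loader()
            record, segments = _measure_one(image, config)
        except Exception as exc:  # per-image isolation: log and continue
            failures.append({"image_id": image_id, "reason": _reason_code(exc),
                             "detail": str(exc)})
            continue
        record["image_id"] = image_id
        with open(out_dir / "records" / f"{image_id}.json", "w") as fh:
            json.dump(record, fh)
        if config.write_qc:
            iio.imwrite(out_dir / "qc" / f"{image_id}.png",
                        qc_overlay(image, segments))
        flat = {"image_id": image_id,
                "divider_row": record["divider_row"],
                "crown_row": record["crown"][0],
                "crown_col": record["crown"][1],
                "shoot_area_px": record["shoot_area_px"],
                "root_area_px": record["root_area_px"]}
        flat.update({f"S_{k}": v for k, v in record["shoot"].items()})
        flat.update({f"R_{k}": v for k, v in record["root"].items()})
        rows.append(flat)
        sbp_rows[image_id] = record["sbp"]
        root_rows[image_id] = record["root_profile_normalized"]

    measurements = pd.DataFrame(rows)
    failure_log = pd.DataFrame(failures, columns=["image_id", "reason", "detail"])
    measurements.to_csv(out_dir / "morphometrics.csv", index=False)
    failure_log.to_csv(out_dir / "failures.csv", index=False)
    if sbp_rows:
        pd.DataFrame.from_dict(sbp_rows, orient="index").rename_axis(
            "image_id").to_csv(out_dir / "sbp.csv")
        pd.DataFrame.from_dict(root_rows, orient="index").rename_axis(
            "image_id").to_csv(out_dir / "root_profile.csv")
    return measurements, failure_log


def _resolve_inputs(inputs):
    if isinstance(inputs, (str, Path)):
        base = Path(inputs)
        paths = sorted(
            p for pat in ("*.tif", "*.tiff", "*.png")
            for p in base.glob(pat))
        return [(p.stem, (lambda q=p: np.asarray(iio.imread(q))[..., :3]))
                for p in paths]
    return [(image_id, (lambda arr=arr: np.asarray(arr)))
            for image_id, arr in inputs]


def _load_records(measurements_dir) -> dict[str, dict]:
    rec_dir = Path(measurements_dir) / "records"
    records = {}
    for path in sorted(rec_dir.glob("*.json")):
        with open(path) as fh:
            records[path.stem] = json.load(fh)
    if not records:
        raise ValueError(f"no measurement records under {rec_dir}")
    return records


def run_predict(measurements_dir, truth: pd.DataFrame | str | Path,
                out_dir, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Fit petiole width/count/length models on ground truth and predict.

    ``truth`` must provide columns image_id, petiole_number,
    petiole_length_cm, petiole_width_cm for at least 20 measured images.
    Models are persisted as JSON under ``out_dir/models``; the returned
    predictions table (also written as predictions.csv) has one row per
    measured image.
    """
    config = config or PipelineConfig()
    if isinstance(truth, (str, Path)):
        truth = pd.read_csv(truth)
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ValueError(f"ground-truth table missing columns: {missing}")
    records = _load_records(measurements_dir)
    truth = truth[truth["image_id"].astype(str).isin(records)].copy()
    if len(truth) < 20:
        raise ValueError("need ground truth for at least 20 measured images")
    px_per_cm = config.px_per_cm or next(
        iter(records.values())).get("calibration_px_per_cm")
    if not px_per_cm:
        raise ValueError("px_per_cm needed to relate pixel features to cm truth")

    train_ids = truth["image_id"].astype(str).tolist()
    if truth[["petiole_number", "petiole_length_cm",
              "petiole_width_cm"]].std().min() == 0:
        warnings.warn("constant ground-truth targets: predictions will be constant")

    # width: EDT histogram -> PLS
    edt_train = [np.asarray(records[i]["edt_samples"], dtype=float)
                 for i in train_ids]
    width_model = PetioleWidthRegressor(cv=config.cv, random_state=config.seed)
    width_model.fit(edt_train, truth["petiole_width_cm"].to_numpy(dtype=float))

    # count: (area / predicted width) ratio -> PLS
    def count_features(ids):
        feats = []
        for i in ids:
            area = float(records[i]["shoot_area_px"])
            w_cm = float(width_model.predict(
                [np.asarray(records[i]["edt_samples"], dtype=float)])[0])
            w_px = max(w_cm * px_per_cm, 1e-6)
            feats.append([area / w_px, area])
        return np.asarray(feats)

    count_model = PlsTraitRegressor(
        cv=config.cv, target_name="petiole_number", random_state=config.seed)
    count_model.fit(count_features(train_ids),
                    truth["petiole_number"].to_numpy(dtype=float))

    # length: SBP -> PCA -> network
    sbp_train = np.asarray([records[i]["sbp"] for i in train_ids], dtype=float)
    length_model = PetioleLengthRegressor(seed=config.seed)
    length_model.fit(sbp_train, truth["petiole_length_cm"].to_numpy(dtype=float))

    out_dir = Path(out_dir)
    models_dir = out_dir / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    trait_models.save_model_json(width_model, models_dir / "petiole_width.json")
    trait_models.save_model_json(count_model, models_dir / "petiole_number.json")
    trait_models.save_model_json(length_model, models_dir / "petiole_length.json")

    all_ids = sorted(records)
    width_pred = width_model.predict(
        [np.asarray(records[i]["edt_samples"], dtype=float) for i in all_ids])
    count_pred = count_model.predict(count_features(all_ids))
    length_pred = length_model.predict(
        np.asarray([records[i]["sbp"] for i in all_ids], dtype=float))
    predictions = pd.DataFrame({
        "image_id": all_ids,
        "petiole_width_cm": width_pred,
        "petiole_number": count_pred,
        "petiole_length_cm": length_pred,
    })
    predictions.to_csv(out_dir / "predictions.csv", index=False)
    cv_summary = {
        "petiole_width": {"n_components": width_model.n_components_,
                          "cv_rmse_by_k": width_model.to_json()["cv_rmse_by_k"]},
        "petiole_number": {"n_components": count_model.n_components_,
                           "cv_rmse_by_k": count_model.to_json()["cv_rmse_by_k"]},
        "petiole_length": {"n_pcs": length_model.n_pcs_,
                           "hidden_units": length_model.hidden_units,
                           "seed": length_model.seed},
        "n_train": len(train_ids),
    }
    with open(out_dir / "cv_summary.json", "w") as fh:
        json.dump(cv_summary, fh, indent=2)
    return predictions
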