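"""End-to-end analysis: segment -> detect -> crop -> classify -> measure.

:func:`analyze` runs the full flow on one photograph and returns a
JSON-serializable report with one record per retained wound detection.
Stages degrade gracefully: a missing fiducial marker drops the physical
size fields (with an explicit reason) but the rest of the analysis
proceeds; a failed segmentation aborts the downstream stages and is
reported as such.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .characterize import color_composition, detect_marker, pixel_to_metric, roughness, wound_size
from .classify import ClassifierModel, four_way_combine, predict_proba
from .detect import (
    Detection,
    ReferenceDetectorConfig,
    crop_wound,
    exclude_region,
    filter_detections_by_mask,
    reference_detector,
)
from .errors import MarkerNotFoundError, SegmentationError
from .features import FeatureConfig, extract_feature_vector
from .preprocess import min_max_normalize, skin_mask

__all__ = ["AnalysisConfig", "analyze", "validate_report"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the pipeline needs; embedded (hashed) in every report."""

    median_kernel: int = 5
    skin_polarity: str = "high"
    min_skin_fraction: float = 0.5
    pad_fraction: float = 0.1
    detector: ReferenceDetectorConfig = field(default_factory=ReferenceDetectorConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    marker_cm: float = 1.3
    color_seed: int = 0
    roughness_sigma: float = 2.0
    classify: bool = True
    measure: bool = True

    def config_hash(self) -> str:
        doc = json.dumps(asdict_safe(self), sort_keys=True)
        return hashlib.sha1(doc.encode()).hexdigest()[:12]


def asdict_safe(obj):
    out = asdict(obj)

    def conv(v):
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        return v

    return conv(out)


def analyze(
    img: np.ndarray,
    config: AnalysisConfig = AnalysisConfig(),
    infection_model: ClassifierModel | None = None,
    ischemia_model: ClassifierModel | None = None,
    detector=None,
) -> dict:
    """Analyze one wound photograph end to end.

    ``detector`` may be any callable ``(image, mask) -> list[Detection]``;
    the built-in chromatic anomaly detector is used when omitted.  Returns
    the analysis report as a plain dict (see ``report_schema.json``).
    """
    report: dict = {
        "wounds": [],
        "segmentation": None,
        "size_calibration": None,
        "provenance": {
            "woundkit_version": __version__,
            "config_hash": config.config_hash(),
            "config": asdict_safe(config),
        },
    }

    normalized = min_max_normalize(img)  # noqa: F841 - ensures input validity/contract
    try:
        mask = skin_mask(img, config.median_kernel, config.skin_polarity)
    except SegmentationError as exc:
        report["segmentation"] = {"ok": False, "reason": str(exc)}
        return report
    report["segmentation"] = {"ok": True, "skin_fraction": float(mask.mean())}

    # the marker is found before detection so its region (a known non-skin
    # object that reads as a chromatic anomaly) can be suppressed
    obs = None
    cm_per_px = None
    try:
        obs = detect_marker(img, config.marker_cm)
    except MarkerNotFoundError as exc:
        report["size_calibration"] = {"ok": False, "reason": str(exc)}
    if obs is not None:
        if config.measure:
            cm_per_px = pixel_to_metric(obs)
            report["size_calibration"] = {
                "ok": True,
                "marker_id": obs.marker_id,
                "marker_side_px": obs.side_length_px,
                "cm_per_px": cm_per_px,
            }
        else:
            report["size_calibration"] = {"ok": False, "reason": "size measurement disabled"}
        pad = max(6, int(round(obs.side_length_px * 0.15)))
        mask = exclude_region(mask, obs.corners, pad)

    detect_fn = detector or (lambda im, m: reference_detector(im, m, config.detector))
    raw = detect_fn(img, mask)
    kept = filter_detections_by_mask(raw, mask, config.min_skin_fraction)

    for det in kept:
        crop = crop_wound(img, det.box, config.pad_fraction)
        rec: dict = {
            "box": [det.box.x_min, det.box.y_min, det.box.x_max, det.box.y_max],
            "confidence": det.confidence,
        }
        if config.classify and infection_model is not None and ischemia_model is not None:
            fv = extract_feature_vector(crop, config.features)
            p_inf = float(predict_proba(infection_model, fv.values)[0])
            p_isch = float(predict_proba(ischemia_model, fv.values)[0])
            fw = four_way_combine(p_inf, p_isch)
            rec["classification"] = {"p_inf": p_inf, "p_isch": p_isch, **fw.to_dict()}
        else:
            rec["classification"] = None
        if cm_per_px is not None:
            rec["size"] = wound_size(det.box, cm_per_px).to_dict()
        else:
            rec["size"] = None
        rec["colors"] = color_composition(crop, seed=config.color_seed).to_dict()["colors"]
        rec["roughness"] = roughness(crop, gaussian_sigma=config.roughness_sigma).to_dict()
        report["wounds"].append(rec)
    return report


def feature_dataset(
    n: int,
    seed: int = 0,
    infected_frac: float = 0.4,
    ischemic_frac: float = 0.4,
    feature_config: FeatureConfig | None = None,
    pad_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labeled feature table from synthetic scenes.

    Generates ``n`` scenes, crops each ground-truth wound box (padded) and
    extracts the handcrafted feature vector.  Returns ``(X, y_infected,
    y_ischemic)``; infection and ischemia flags are assigned independently
    with exact per-flag counts.
    """
    from .synthdata import iter_scenes

    cfg = feature_config or FeatureConfig()
    X, y_inf, y_isch = [], [], []
    for _, img, gt, _spec in iter_scenes(n, infected_frac, ischemic_frac, seed, marker=False):
        crop = crop_wound(img, gt.wound_box, pad_fraction)
        X.append(extract_feature_vector(crop, cfg).values)
        y_inf.append(int(gt.infected))
        y_isch.append(int(gt.ischemic))
    return np.asarray(X), np.asarray(y_inf), np.asarray(y_isch)


# ---------------------------------------------------------------------------
# structural report validation (mirrors report_schema.json)

def validate_report(report: dict) -> None:
    """Raise ValueError when a report does not match the published schema."""

    def need(d, key, types):
        if key not in d:
            raise ValueError(f"report missing key {key!r}")
        if d[key] is not None and not isinstance(d[key], types):
            raise ValueError(f"report key {key!r} has type {type(d[key]).__name__}")

    need(report, "wounds", list)
    need(report, "segmentation", dict)
    need(report, "size_calibration", (dict, type(None)))
    need(report, "provenance", dict)
    prov = report["provenance"]
    for key in ("woundkit_version", "config_hash", "config"):
        if key not in prov:
            raise ValueError(f"provenance missing {key!r}")
    for rec in report["wounds"]:
        need(rec, "box", list)
        if len(rec["box"]) != 4:
            raise ValueError("wound box must have 4 coordinates")
        need(rec, "confidence", (int, float))
        need(rec, "classification", (dict, type(None)))
        need(rec, "size", (dict, type(None)))
        need(rec, "colors", list)
        if len(rec["colors"]) != 7:
            raise ValueError("color composition must have exactly 7 entries")
        need(rec, "roughness", dict)
        for key in ("ra", "rq"):
            if key not in rec["roughness"]:
                raise ValueError(f"roughness record missing {key!r}")
        if rec["classification"] is not None:
            for key in ("p_inf", "p_isch", "p_none", "p_inf_only", "p_isch_only",
                        "p_both", "label"):
                if key not in rec["classification"]:
                    raise ValueError(f"classification record missing {key!r}")
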