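"""Wound localization contract, mask-based false-positive filtering and
detection-evaluation metrics.

The detector itself is a pluggable interface: anything that maps an image to
a list of :class:`Detection` works, including an external object-detection
runtime.  :func:`reference_detector` is a deliberately simple chromatic
anomaly detector used for testing the rest of the pipeline; it is not a
clinical wound detector.

Boxes use a 0-based, half-open pixel convention ``[x_min, x_max) x
[y_min, y_max)``: the area of a box is ``(x_max - x_min) * (y_max - y_min)``.
Evaluation follows the COCO conventions: greedy matching in descending
confidence order, all-points interpolated average precision, and mAP
averaged over the 10 IoU thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, UndefinedMetricError
from .image import as_mask, as_rgb

__all__ = [
    "BoundingBox",
    "Detection",
    "MatchResult",
    "DetectionEvalReport",
    "iou",
    "filter_detections_by_mask",
    "match_detections",
    "average_precision",
    "mean_ap_50_95",
    "f1_score_detection",
    "evaluate_detections",
    "reference_detector",
    "crop_wound",
]

MAP_THRESHOLDS = tuple(np.round(np.linspace(0.50, 0.95, 10), 2))


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, half-open pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InvalidInputError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def clip(self, width: int, height: int) -> "BoundingBox":
        return BoundingBox(
            max(0.0, min(self.x_min, width - 1.0)),
            max(0.0, min(self.y_min, height - 1.0)),
            min(float(width), max(self.x_max, 1.0)),
            min(float(height), max(self.y_max, 1.0)),
        )


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    confidence: float = 1.0
    label: int = 0

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidInputError(f"confidence {self.confidence} outside [0, 1]")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def filter_detections_by_mask(
    detections: list[Detection],
    mask: np.ndarray,
    min_skin_fraction: float = 0.5,
) -> list[Detection]:
    """Drop detections whose box covers too little skin.

    A detection is kept when at least ``min_skin_fraction`` of the pixels
    inside its (image-clipped) box are foreground in ``mask``.  Order and
    confidences are preserved; ``min_skin_fraction=0`` is the identity.
    """
    mask = as_mask(mask)
    h, w = mask.shape
    kept = []
    for det in detections:
        b = det.box.clip(w, h)
        x0, y0 = int(np.floor(b.x_min)), int(np.floor(b.y_min))
        x1, y1 = int(np.ceil(b.x_max)), int(np.ceil(b.y_max))
        region = mask[y0:y1, x0:x1]
        frac = float(region.mean()) if region.size else 0.0
        if frac >= min_skin_fraction:
            kept.append(det)
    return kept


@dataclass
class MatchResult:
    """Outcome of matching detections to ground-truth boxes at one IoU level."""

    pairs: list[tuple[int, int]]  # (detection index, ground-truth index)
    unmatched_detections: list[int]
    unmatched_ground_truths: list[int]

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_detections)

    @property
    def fn(self) -> int:
        return len(self.unmatched_ground_truths)


def _confidence_order(detections: list[Detection]) -> list[int]:
    # stable sort: ties keep the caller's order
    return sorted(range(len(detections)), key=lambda i: -detections[i].confidence)


def match_detections(
    detections: list[Detection],
    ground_truths: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching in descending confidence order.

    Each detection, visited from highest confidence down, claims the still
    unmatched ground truth with which it has the highest IoU, provided that
    IoU reaches ``iou_threshold``.  Each ground truth is matched at most once.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise InvalidInputError(f"iou_threshold {iou_threshold} outside (0, 1]")
    taken = [False] * len(ground_truths)
    pairs: list[tuple[int, int]] = []
    unmatched_dets: list[int] = []
    for di in _confidence_order(detections):
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(ground_truths):
            if taken[j]:
                continue
            v = iou(detections[di].box, gt)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            pairs.append((di, best_j))
        else:
            unmatched_dets.append(di)
    unmatched_gts = [j for j, t in enumerate(taken) if not t]
    return MatchResult(pairs, unmatched_dets, unmatched_gts)


def average_precision(
    detections: list[Detection],
    ground_truths: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> float:
    """All-points interpolated AP from confidence-ranked detections."""
    if not ground_truths:
        raise UndefinedMetricError("average precision undefined with no ground truths")
    if not detections:
        return 0.0
    order = _confidence_order(detections)
    matched = match_detections(detections, ground_truths, iou_threshold)
    is_tp = {di for di, _ in matched.pairs}
    tps = np.array([1.0 if di in is_tp else 0.0 for di in order])
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(1.0 - tps)
    recall = cum_tp / len(ground_truths)
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope + area under the stepwise PR curve
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[1.0], precision])
    p = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def mean_ap_50_95(
    detections: list[Detection],
    ground_truths: list[BoundingBox],
) -> float:
    """Mean AP over IoU thresholds 0.50, 0.55, ..., 0.95."""
    if not ground_truths:
        raise UndefinedMetricError("mAP undefined with no ground truths")
    return float(np.mean([average_precision(detections, ground_truths, t) for t in MAP_THRESHOLDS]))


def f1_score_detection(
    detections: list[Detection],
    ground_truths: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> float:
    """F1 from TP/FP/FN at one IoU threshold, using all detections.

    No confidence cut is applied.  Returns 0 when precision + recall is 0.
    """
    m = match_detections(detections, ground_truths, iou_threshold)
    denom = 2 * m.tp + m.fp + m.fn
    if denom == 0:
        return 0.0
    return 2 * m.tp / denom


@dataclass
class DetectionEvalReport:
    f1: float
    map_50_95: float
    ap_per_threshold: dict[float, float]
    tp: int
    fp: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "f1": self.f1,
            "map_50_95": self.map_50_95,
            "ap_per_threshold": {f"{t:.2f}": v for t, v in self.ap_per_threshold.items()},
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


def evaluate_detections(
    detections: list[Detection],
    ground_truths: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> DetectionEvalReport:
    """Full evaluation report: F1 at ``iou_threshold``, AP per threshold, mAP."""
    m = match_detections(detections, ground_truths, iou_threshold)
    aps = {float(t): average_precision(detections, ground_truths, t) for t in MAP_THRESHOLDS}
    return DetectionEvalReport(
        f1=f1_score_detection(detections, ground_truths, iou_threshold),
        map_50_95=float(np.mean(list(aps.values()))),
        ap_per_threshold=aps,
        tp=m.tp,
        fp=m.fp,
        fn=m.fn,
    )


def evaluate_dataset(
    per_image: list[tuple[list[Detection], list[BoundingBox]]],
    iou_threshold: float = 0.5,
) -> DetectionEvalReport:
    """Pool detections over a dataset (confidence ranking is global, matching
    per image) and report aggregate F1/AP/mAP."""
    offset_x = 0.0
    dets_all: list[Detection] = []
    gts_all: list[BoundingBox] = []
    # place images side by side on a virtual canvas so per-image matching is
    # preserved while metrics are computed once, globally
    for dets, gts in per_image:
        extent = max(
            [d.box.x_max for d in dets] + [g.x_max for g in gts] + [1.0]
        )
        for d in dets:
            b = d.box
            dets_all.append(
                replace(d, box=BoundingBox(b.x_min + offset_x, b.y_min, b.x_max + offset_x, b.y_max))
            )
        for g in gts:
            gts_all.append(BoundingBox(g.x_min + offset_x, g.y_min, g.x_max + offset_x, g.y_max))
        offset_x += extent + 10.0
    return evaluate_detections(dets_all, gts_all, iou_threshold)


# ---------------------------------------------------------------------------
# reference detector


@dataclass(frozen=True)
class ReferenceDetectorConfig:
    """Sensitivity knobs for the chromatic anomaly detector."""

    z_threshold: float = 4.0  # robust z-score a pixel must exceed
    min_area: int = 40  # smallest component reported, pixels
    restrict_to_mask: bool = True  # only propose boxes inside the skin mask
    mask_erosion: int = 3  # shrink mask before candidate gating
    close_radius: int = 2  # morphological closing to fuse fragmented blobs


def reference_detector(
    img: np.ndarray,
    mask: np.ndarray,
    config: ReferenceDetectorConfig = ReferenceDetectorConfig(),
) -> list[Detection]:
    """Propose boxes around chromatically anomalous blobs on the skin.

    Skin statistics (median, MAD) are estimated per CIELAB channel over the
    mask; a pixel's anomaly score is its largest robust z-score across L*,
    a*, b*.  Pixels above ``z_threshold`` are grouped into connected
    components; components of at least ``min_area`` become detections whose
    confidence is a saturating transform of the component's mean score.
    """
    from skimage.color import rgb2lab

    from .image import to_unit

    img = as_rgb(img)
    mask = as_mask(mask, like=img)
    if not mask.any():
        return []
    lab = rgb2lab(to_unit(img))
    skin_px = lab[mask]
    med = np.median(skin_px, axis=0)
    mad = np.median(np.abs(skin_px - med), axis=0)
    mad = np.maximum(mad * 1.4826, 1.0)  # scale to sigma-equivalent, floor for stability
    z = np.abs(lab - med) / mad
    score = z.max(axis=2)
    cand = score > config.z_threshold
    if config.restrict_to_mask:
        gate = ndimage.binary_erosion(mask, iterations=config.mask_erosion)
        cand &= gate
    if config.close_radius > 0:
        cand = ndimage.binary_closing(cand, structure=np.ones((3, 3)), iterations=config.close_radius)
    labels, n = ndimage.label(cand)
    detections = []
    for sl in ndimage.find_objects(labels):
        comp = labels[sl] > 0
        area = int(comp.sum())
        if area < config.min_area:
            continue
        mean_z = float(score[sl][comp].mean())
        conf = float(1.0 - np.exp(-mean_z / (2.0 * config.z_threshold)))
        box = BoundingBox(
            float(sl[1].start), float(sl[0].start), float(sl[1].stop), float(sl[0].stop)
        )
        detections.append(Detection(box, conf))
    detections.sort(key=lambda d: -d.confidence)
    return detections


def exclude_region(mask: np.ndarray, corners: np.ndarray, pad_px: int = 6) -> np.ndarray:
    """Return a copy of ``mask`` with the bounding rectangle of a corner
    quadrilateral (plus ``pad_px``) set to background.

    Used to suppress the calibration marker from the skin mask before wound
    detection: the marker is a known non-skin object that would otherwise
    register as a chromatic anomaly.
    """
    mask = as_mask(mask).copy()
    corners = np.asarray(corners, dtype=np.float64)
    x0 = max(0, int(np.floor(corners[:, 0].min())) - pad_px)
    x1 = min(mask.shape[1], int(np.ceil(corners[:, 0].max())) + pad_px)
    y0 = max(0, int(np.floor(corners[:, 1].min())) - pad_px)
    y1 = min(mask.shape[0], int(np.ceil(corners[:, 1].max())) + pad_px)
    mask[y0:y1, x0:x1] = False
    return mask


def crop_wound(img: np.ndarray, box: BoundingBox, pad_fraction: float = 0.0) -> np.ndarray:
    """Extract the sub-image of ``box`` expanded by ``pad_fraction`` per side.

    The expanded box is clipped to the image bounds; coordinates are rounded
    outward so the crop always contains the full box.
    """
    img = np.asarray(img)
    if pad_fraction < 0:
        raise InvalidInputError("pad_fraction must be >= 0")
    h, w = img.shape[:2]
    px = box.width * pad_fraction
    py = box.height * pad_fraction
    x0 = max(0, int(np.floor(box.x_min - px)))
    y0 = max(0, int(np.floor(box.y_min - py)))
    x1 = min(w, int(np.ceil(box.x_max + px)))
    y1 = min(h, int(np.ceil(box.y_max + py)))
    if x1 <= x0 or y1 <= y0:
        raise InvalidInputError(f"box {box} does not intersect a {h}x{w} image")
    return img[y0:y1, x0:x1].copy()
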