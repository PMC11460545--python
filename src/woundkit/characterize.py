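"""Macroscopic wound characterization.

Three independent measurements of a localized wound:

* **Physical size.**  A square fiducial marker of known physical side
  length (1.3 cm by default) placed near the wound yields a pixel-to-metric
  ratio; the wound's bounding box, multiplied by that ratio, gives width and
  height in centimeters.  No perspective correction is applied — the capture
  protocol holds the camera parallel to the wound plane, and averaging the
  marker's four side lengths absorbs small tilt.
* **Color composition.**  k-means clustering (k = 7) of the crop's pixels
  in CIELAB coordinates, reporting each cluster's center (sRGB hex and
  CIELAB) and its share of the pixels as a percentage.  Clustering in a
  perceptually uniform space makes cluster distances track visual color
  difference.
* **Surface roughness.**  The L* lightness plane is treated as a height
  map, smoothed with a Gaussian filter to suppress sensor noise, and
  summarized by the standard profile-roughness statistics Ra (mean absolute
  deviation from the mean height) and Rq (RMS deviation); Rq is the
  headline number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import lab2rgb, rgb2lab

from .detect import BoundingBox
from .errors import InvalidInputError
from .fiducial import MarkerDictionary, MarkerObservation, default_dictionary, detect_markers
from .image import as_mask, as_rgb, to_unit

__all__ = [
    "MarkerObservation",
    "WoundMeasurement",
    "ColorEntry",
    "ColorComposition",
    "RoughnessResult",
    "detect_marker",
    "pixel_to_metric",
    "wound_size",
    "color_composition",
    "roughness",
]


def detect_marker(
    img: np.ndarray,
    physical_side_cm: float = 1.3,
    dictionary: MarkerDictionary | None = None,
) -> MarkerObservation:
    """Detect the calibration marker; the largest one wins if several are
    visible.  Raises :class:`MarkerNotFoundError` when none is found."""
    found = detect_markers(img, dictionary or default_dictionary(), physical_side_cm)
    return found[0]  # detect_markers sorts by descending side length


def pixel_to_metric(obs: MarkerObservation) -> float:
    """Centimeters per pixel from a marker observation."""
    if obs.side_length_px <= 0:
        raise InvalidInputError("marker side length must be positive")
    return obs.physical_side_cm / obs.side_length_px


@dataclass
class WoundMeasurement:
    """Physical extent of a wound box.  ``width_cm``/``height_cm`` keep full
    precision; ``rounded()`` reports them at the 0.1 cm granularity used in
    reports."""

    width_cm: float
    height_cm: float
    pixel_per_cm: float
    box: BoundingBox

    def __post_init__(self):
        if self.width_cm <= 0 or self.height_cm <= 0 or self.pixel_per_cm <= 0:
            raise InvalidInputError("wound measurement fields must be positive")

    def rounded(self) -> tuple[float, float]:
        return (round(self.width_cm, 1), round(self.height_cm, 1))

    def to_dict(self) -> dict:
        w, h = self.rounded()
        return {
            "width_cm": w,
            "height_cm": h,
            "width_cm_raw": self.width_cm,
            "height_cm_raw": self.height_cm,
            "pixel_per_cm": self.pixel_per_cm,
        }


def wound_size(box: BoundingBox, cm_per_px: float) -> WoundMeasurement:
    """Convert a wound bounding box to physical width/height."""
    if cm_per_px <= 0:
        raise InvalidInputError("cm_per_px must be positive")
    return WoundMeasurement(
        width_cm=box.width * cm_per_px,
        height_cm=box.height * cm_per_px,
        pixel_per_cm=1.0 / cm_per_px,
        box=box,
    )


# ---------------------------------------------------------------------------
# color composition

@dataclass
class ColorEntry:
    hex: str
    lab: tuple[float, float, float]
    percent: float


@dataclass
class ColorComposition:
    """Exactly seven color entries sorted by descending share; empty or
    duplicated clusters are padded at 0% so the schema is fixed."""

    entries: list[ColorEntry]

    def __post_init__(self):
        total = sum(e.percent for e in self.entries)
        if len(self.entries) != 7 or abs(total - 100.0) > 1e-6:
            raise InvalidInputError("composition needs exactly 7 entries summing to 100")

    def to_dict(self) -> dict:
        return {
            "colors": [
                {"hex": e.hex, "lab": [round(v, 4) for v in e.lab], "percent": round(e.percent, 4)}
                for e in self.entries
            ]
        }


def _lab_to_hex(lab: np.ndarray) -> str:
    rgb = lab2rgb(lab.reshape(1, 1, 3)).reshape(3)
    r, g, b = (int(round(float(v) * 255)) for v in np.clip(rgb, 0, 1))
    return f"#{r:02x}{g:02x}{b:02x}"


def color_composition(
    crop: np.ndarray,
    mask: np.ndarray | None = None,
    seed: int = 0,
    n_colors: int = 7,
) -> ColorComposition:
    """Dominant-color analysis of a wound crop.

    k-means (k-means++ initialization, 10 restarts, seeded) on the CIELAB
    coordinates of the in-scope pixels.  Fewer distinct colors than
    clusters simply leave the surplus entries at 0%.
    """
    crop = as_rgb(crop, min_side=1)
    lab = rgb2lab(to_unit(crop))
    if mask is not None:
        mask = as_mask(mask, like=crop)
        pixels = lab[mask]
    else:
        pixels = lab.reshape(-1, 3)
    if pixels.shape[0] < n_colors:
        raise InvalidInputError(f"need at least {n_colors} pixels, got {pixels.shape[0]}")

    import warnings

    from sklearn.cluster import KMeans

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points trigger convergence warnings
        km = KMeans(n_clusters=n_colors, init="k-means++", n_init=10, random_state=seed)
        assignments = km.fit_predict(pixels)
    counts = np.bincount(assignments, minlength=n_colors)
    percents = counts / counts.sum() * 100.0
    entries = [
        ColorEntry(
            hex=_lab_to_hex(km.cluster_centers_[i]),
            lab=tuple(float(v) for v in km.cluster_centers_[i]),
            percent=float(percents[i]),
        )
        for i in range(n_colors)
    ]
    entries.sort(key=lambda e: (-e.percent, e.hex))
    # pin the sum to exactly 100 against float accumulation error
    drift = 100.0 - sum(e.percent for e in entries)
    entries[0] = ColorEntry(entries[0].hex, entries[0].lab, entries[0].percent + drift)
    return ColorComposition(entries)


# ---------------------------------------------------------------------------
# roughness

@dataclass
class RoughnessResult:
    """Ra/Rq of the smoothed height map; Rq >= Ra always (RMS vs mean of
    absolute deviations)."""

    ra: float
    rq: float
    height_map: np.ndarray

    def to_dict(self) -> dict:
        return {"ra": self.ra, "rq": self.rq}


def roughness(
    crop: np.ndarray,
    mask: np.ndarray | None = None,
    gaussian_sigma: float = 2.0,
) -> RoughnessResult:
    """Surface-roughness statistics of a wound crop.

    The height map is the Gaussian-smoothed L* plane; Ra and Rq are computed
    over the in-mask pixels relative to their mean height.
    """
    crop = as_rgb(crop, min_side=8)
    if gaussian_sigma <= 0:
        raise InvalidInputError("gaussian_sigma must be positive")
    lum = rgb2lab(to_unit(crop))[:, :, 0]
    height = ndimage.gaussian_filter(lum, sigma=gaussian_sigma, mode="nearest")
    if mask is not None:
        mask = as_mask(mask, like=crop)
        if not mask.any():
            raise InvalidInputError("empty roughness mask")
        vals = height[mask]
    else:
        vals = height.reshape(-1)
    dev = vals - vals.mean()
    return RoughnessResult(
        ra=float(np.abs(dev).mean()),
        rq=float(np.sqrt((dev ** 2).mean())),
        height_map=height,
    )
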