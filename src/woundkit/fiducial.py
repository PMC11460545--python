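"""Square binary fiducial markers for pixel-to-metric calibration.

A marker is a 6x6 cell grid: a one-cell black border around a 4x4 payload
of black/white cells encoding one of 50 dictionary IDs.  The dictionary is
generated algorithmically from a fixed seed, rejecting codes that are
rotation-symmetric or too close (in Hamming distance, over all rotations)
to an already accepted code, so decoding is unambiguous under the four
square rotations.  The layout is structurally compatible with the classic
ArUco-style 4x4 markers used in wound photography.

Detection assumes a roughly frontal marker (the capture protocol holds the
camera parallel to the wound plane): dark connected components are tested
for squareness, their corner quadrilateral is estimated from the convex
hull, the 6x6 grid is sampled through a projective transform and the
payload is matched against the dictionary under all four rotations.

The reported ``side_length_px`` is the mean of the four side lengths of the
outer border quadrilateral, measured across pixel *edges* (an axis-aligned
marker spanning columns c0..c1 inclusive has side c1 - c0 + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, MarkerNotFoundError
from .image import as_rgb

__all__ = [
    "MarkerDictionary",
    "default_dictionary",
    "render_marker",
    "MarkerObservation",
    "detect_markers",
]

GRID = 6  # cells per side including the 1-cell border
PAYLOAD = 4  # payload cells per side
_DICTIONARY_SEED = 20240901  # fixed: the dictionary is part of the format


def _rotations(bits: np.ndarray) -> list[np.ndarray]:
    return [np.rot90(bits, k) for k in range(4)]


class MarkerDictionary:
    """Deterministically generated set of 4x4 payload patterns."""

    def __init__(self, n_markers: int = 50, min_distance: int = 4):
        rng = np.random.default_rng(_DICTIONARY_SEED)
        codes: list[np.ndarray] = []
        while len(codes) < n_markers:
            cand = rng.integers(0, 2, size=(PAYLOAD, PAYLOAD))
            # reject near rotation-symmetry (ambiguous orientation)
            if any(np.sum(cand != r) < 2 for r in _rotations(cand)[1:]):
                continue
            # reject codes too close to any rotation of an accepted code
            ok = True
            for code in codes:
                for r in _rotations(code):
                    if np.sum(cand != r) < min_distance:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                codes.append(cand)
        self.codes = codes

    def __len__(self) -> int:
        return len(self.codes)

    def match(self, payload: np.ndarray) -> tuple[int, int] | None:
        """Return (marker id, rotation count) of an exact match, else None."""
        for mid, code in enumerate(self.codes):
            for k, r in enumerate(_rotations(code)):
                if np.array_equal(payload, r):
                    return mid, k
        return None


_default_dict: MarkerDictionary | None = None


def default_dictionary() -> MarkerDictionary:
    global _default_dict
    if _default_dict is None:
        _default_dict = MarkerDictionary()
    return _default_dict


def render_marker(
    marker_id: int,
    side_px: int,
    dictionary: MarkerDictionary | None = None,
) -> np.ndarray:
    """Render a marker as a ``side_px`` x ``side_px`` uint8 grayscale image
    (0 = black cells, 255 = white cells)."""
    dictionary = dictionary or default_dictionary()
    if not 0 <= marker_id < len(dictionary):
        raise InvalidInputError(f"marker id {marker_id} outside dictionary")
    if side_px < GRID * 3:
        raise InvalidInputError(f"side_px {side_px} too small to render a {GRID}x{GRID} grid")
    cells = np.zeros((GRID, GRID), dtype=np.uint8)
    cells[1:-1, 1:-1] = dictionary.codes[marker_id]
    # cell boundaries spread over side_px pixels (handles non-divisible sides)
    edges = np.linspace(0, side_px, GRID + 1).round().astype(int)
    img = np.zeros((side_px, side_px), dtype=np.uint8)
    for i in range(GRID):
        for j in range(GRID):
            img[edges[i]:edges[i + 1], edges[j]:edges[j + 1]] = 255 * cells[i, j]
    return img


@dataclass
class MarkerObservation:
    """A detected marker: corner quadrilateral and derived side length."""

    corners: np.ndarray  # (4, 2) as (x, y), order TL, TR, BR, BL in pixel-edge coords
    side_length_px: float
    marker_id: int
    physical_side_cm: float = 1.3

    def __post_init__(self):
        if self.side_length_px <= 0:
            raise InvalidInputError("side_length_px must be positive")


def _corner_quad(coords_rc: np.ndarray) -> np.ndarray:
    """Estimate the 4 outer corners (x, y) of a roughly square component.

    Picks the component pixels extreme along the two diagonal directions,
    then pushes each corner outward by half a pixel per axis so that
    corners sit on pixel edges (axis-aligned side = extent in pixels).
    """
    ys = coords_rc[:, 0].astype(np.float64)
    xs = coords_rc[:, 1].astype(np.float64)
    tl = np.argmin(xs + ys)
    br = np.argmax(xs + ys)
    tr = np.argmax(xs - ys)
    bl = np.argmin(xs - ys)
    corners = np.array(
        [[xs[i], ys[i]] for i in (tl, tr, br, bl)], dtype=np.float64
    )
    center = corners.mean(axis=0)
    corners += 0.5 * np.sign(corners - center)
    return corners


def _sample_grid(gray: np.ndarray, corners: np.ndarray) -> np.ndarray | None:
    """Sample the 6x6 cell centers through a projective map; None if the
    quadrilateral maps outside the image."""
    from skimage.transform import ProjectiveTransform

    src = np.array([[0.0, 0.0], [GRID, 0.0], [GRID, GRID], [0.0, GRID]])
    try:
        tf = ProjectiveTransform.from_estimate(src, corners)
    except AttributeError:  # scikit-image < 0.26
        tf = ProjectiveTransform()
        if not tf.estimate(src, corners):
            return None
    if tf is None or not tf:
        return None
    ij = np.array([[(j + 0.5), (i + 0.5)] for i in range(GRID) for j in range(GRID)])
    pts = tf(ij)  # (x, y)
    xs = np.clip(np.rint(pts[:, 0] - 0.5).astype(int), 0, gray.shape[1] - 1)
    ys = np.clip(np.rint(pts[:, 1] - 0.5).astype(int), 0, gray.shape[0] - 1)
    return gray[ys, xs].reshape(GRID, GRID)


def detect_markers(
    img: np.ndarray,
    dictionary: MarkerDictionary | None = None,
    physical_side_cm: float = 1.3,
    min_side_px: int = 18,
) -> list[MarkerObservation]:
    """Find and decode all fiducial markers in an RGB image."""
    from skimage.filters import threshold_otsu

    dictionary = dictionary or default_dictionary()
    img = as_rgb(img)
    if img.max() <= 1.0:
        img = img * 255.0
    gray = img.mean(axis=2)
    if np.ptp(gray) == 0:
        raise MarkerNotFoundError("featureless image contains no marker")
    dark = gray < threshold_otsu(gray)
    labels, n = ndimage.label(dark)
    found: list[MarkerObservation] = []
    for sl in ndimage.find_objects(labels):
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        if min(h, w) < min_side_px or max(h, w) > 3 * min(h, w):
            continue
        comp = labels[sl] > 0
        filled = ndimage.binary_fill_holes(comp)
        # a square border fills to a solid square: check fill fraction
        if filled.mean() < 0.5:
            continue
        coords = np.argwhere(filled)
        coords[:, 0] += sl[0].start
        coords[:, 1] += sl[1].start
        corners = _corner_quad(coords)
        sides = np.linalg.norm(np.roll(corners, -1, axis=0) - corners, axis=1)
        if sides.min() < min_side_px * 0.7 or sides.max() / sides.min() > 1.4:
            continue
        cells = _sample_grid(gray, corners)
        if cells is None:
            continue
        mid = 0.5 * (gray[tuple(coords.T)].mean() + cells.max())
        bits = (cells > mid).astype(np.uint8)
        if bits[0, :].any() or bits[-1, :].any() or bits[:, 0].any() or bits[:, -1].any():
            continue  # border must be all black
        match = dictionary.match(bits[1:-1, 1:-1])
        if match is None:
            continue
        found.append(
            MarkerObservation(
                corners=corners,
                side_length_px=float(sides.mean()),
                marker_id=match[0],
                physical_side_cm=physical_side_cm,
            )
        )
    if not found:
        raise MarkerNotFoundError("no fiducial marker detected")
    found.sort(key=lambda m: -m.side_length_px)
    return found
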