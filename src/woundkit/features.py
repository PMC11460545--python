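"""Handcrafted color/texture descriptor of a cropped wound patch.

Six families of features are concatenated into one fixed-layout vector:

* CIELAB channel distributions (moments + 16-bin histograms, 60 values),
* gray-level co-occurrence (GLCM) statistics of the full crop (12 values),
* distributions of GLCM statistics over non-overlapping 64x64 tiles
  (30 values),
* a 59-bin uniform local-binary-pattern (LBP) histogram,
* a 256-bin local-phase-quantization (LPQ) histogram, and
* mean/variance of Gabor filter-bank response magnitudes (24 values),

for a default total of 441 values.  All texture operators run on the CIELAB
L* (lightness) plane of the crop; extraction is fully deterministic.

Exactly-black pixels (masked-out background) are excluded from the CIELAB
distribution statistics so that the amount of background retained around a
masked wound does not shift the color moments; the texture operators run on
the full rectangular crop.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.color import rgb2lab
from skimage.feature import graycomatrix, graycoprops

from .errors import InvalidInputError
from .image import as_gray, as_rgb, to_unit

__all__ = [
    "GlcmConfig",
    "FeatureConfig",
    "FeatureVector",
    "cielab_distribution_features",
    "quantize_gray",
    "glcm",
    "glcm_features",
    "glcm_features_full",
    "glcm_patch_distribution",
    "lbp_codes",
    "lbp_histogram",
    "lpq_codes",
    "lpq_histogram",
    "gabor_features",
    "extract_feature_vector",
    "features_to_frame",
    "read_features_csv",
    "write_features_csv",
]

GLCM_PROPERTIES = ("contrast", "correlation", "energy", "homogeneity", "entropy", "dissimilarity")


@dataclass(frozen=True)
class GlcmConfig:
    levels: int = 32
    distances: tuple[int, ...] = (1, 2)
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)  # degrees
    properties: tuple[str, ...] = GLCM_PROPERTIES
    patch_side: int = 64

    def __post_init__(self):
        if self.levels < 2:
            raise InvalidInputError("GLCM needs at least 2 gray levels")
        if self.patch_side < 8:
            raise InvalidInputError("patch_side must be >= 8")


@dataclass(frozen=True)
class FeatureConfig:
    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    gabor_orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)  # degrees
    gabor_wavelengths: tuple[float, ...] = (4.0, 8.0, 16.0)  # pixels
    gabor_sigma_factor: float = 0.56  # sigma = factor * wavelength
    lpq_window: int = 7
    min_side: int = 64  # smaller patches are bilinearly resized up

    def config_hash(self) -> str:
        doc = json.dumps(
            {
                "glcm": {
                    "levels": self.glcm.levels,
                    "distances": list(self.glcm.distances),
                    "angles": list(self.glcm.angles),
                    "properties": list(self.glcm.properties),
                    "patch_side": self.glcm.patch_side,
                },
                "gabor_orientations": list(self.gabor_orientations),
                "gabor_wavelengths": list(self.gabor_wavelengths),
                "gabor_sigma_factor": self.gabor_sigma_factor,
                "lpq_window": self.lpq_window,
                "min_side": self.min_side,
            },
            sort_keys=True,
        )
        return hashlib.sha1(doc.encode()).hexdigest()[:12]


@dataclass
class FeatureVector:
    """Fixed-layout descriptor: values plus a named-segment table."""

    values: np.ndarray
    layout: dict[str, tuple[int, int]]
    config_hash: str

    def __len__(self) -> int:
        return len(self.values)

    def segment(self, name: str) -> np.ndarray:
        lo, hi = self.layout[name]
        return self.values[lo:hi]

    def feature_names(self) -> list[str]:
        names = [""] * len(self.values)
        for seg, (lo, hi) in self.layout.items():
            for i in range(lo, hi):
                names[i] = f"{seg}_{i - lo}"
        return names


# ---------------------------------------------------------------------------
# CIELAB distributions

_LAB_RANGES = ((0.0, 100.0), (-128.0, 128.0), (-128.0, 128.0))


def cielab_distribution_features(patch: np.ndarray, n_bins: int = 16) -> np.ndarray:
    """Moments and histograms of the L*, a*, b* planes of a crop.

    Per channel: mean, standard deviation, skewness, excess kurtosis and an
    ``n_bins``-bin normalized histogram over the channel's nominal range
    (L* in [0, 100], a*/b* in [-128, 128]) -> 3 x (4 + n_bins) values.
    Exactly-black pixels are treated as masked background and excluded,
    unless the whole patch is black.
    """
    patch = as_rgb(patch)
    if patch.shape[0] < 8 or patch.shape[1] < 8:
        raise InvalidInputError("patch must be at least 8x8 for distribution features")
    lab = rgb2lab(to_unit(patch))
    keep = np.any(patch != 0, axis=2)
    if not keep.any():
        keep = np.ones(patch.shape[:2], dtype=bool)
    out = []
    for c in range(3):
        vals = lab[:, :, c][keep]
        sd = float(vals.std())
        if sd < 1e-9:  # constant channel up to color-conversion rounding
            sd = 0.0
        if sd > 0:
            skew = float(stats.skew(vals))
            kurt = float(stats.kurtosis(vals))
        else:
            skew = kurt = 0.0
        hist, _ = np.histogram(vals, bins=n_bins, range=_LAB_RANGES[c])
        hist = hist / hist.sum()
        out.extend([float(vals.mean()), sd, skew, kurt])
        out.extend(hist.tolist())
    return np.asarray(out)


# ---------------------------------------------------------------------------
# GLCM

def quantize_gray(gray: np.ndarray, levels: int, value_range: tuple[float, float] | None = None) -> np.ndarray:
    """Quantize a grayscale plane to ``levels`` integer bins.

    With ``value_range=None`` the plane's own min/max span the bins (a
    constant plane maps to level 0).
    """
    gray = as_gray(gray)
    if value_range is None:
        lo, hi = float(gray.min()), float(gray.max())
    else:
        lo, hi = value_range
    if hi <= lo:
        return np.zeros(gray.shape, dtype=np.uint8)
    q = np.floor((gray - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm(
    gray: np.ndarray,
    cfg: GlcmConfig = GlcmConfig(),
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrices.

    Returns an array of shape ``(levels, levels, n_distances, n_angles)``;
    each (distance, angle) slice sums to 1.  Float input is quantized to
    ``cfg.levels`` first; integer input is assumed already quantized.

    ``distances`` count steps along the angle's pixel direction (chessboard
    metric), so distance 2 at 45 degrees pairs pixels offset by (2, 2).
    """
    gray = np.asarray(gray)
    if np.issubdtype(gray.dtype, np.integer):
        q = gray.astype(np.uint8)
        if q.max() >= cfg.levels:
            raise InvalidInputError("integer plane exceeds cfg.levels")
    else:
        q = quantize_gray(gray, cfg.levels, value_range)
    if min(q.shape) <= max(cfg.distances):
        raise InvalidInputError(
            f"image {q.shape} smaller than largest co-occurrence distance {max(cfg.distances)}"
        )
    slices = []
    for a in cfg.angles:
        rad = np.deg2rad(a)
        # stretch diagonal distances so the rounded (row, col) offset is
        # (d, d) rather than collapsing onto the distance-1 diagonal
        diag = abs(np.sin(rad)) > 0.1 and abs(np.cos(rad)) > 0.1
        eff = [d * np.sqrt(2.0) if diag else d for d in cfg.distances]
        m = graycomatrix(q, distances=eff, angles=[rad], levels=cfg.levels,
                         symmetric=True, normed=True)
        slices.append(m[:, :, :, 0])
    return np.stack(slices, axis=3)


def _glcm_entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of each (distance, angle) slice."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=(0, 1))


def glcm_features(p: np.ndarray, properties: tuple[str, ...] = GLCM_PROPERTIES) -> np.ndarray:
    """Property table of a co-occurrence tensor: shape (n_props, n_dist, n_angle)."""
    rows = []
    for prop in properties:
        if prop == "entropy":
            rows.append(_glcm_entropy(p))
        else:
            rows.append(graycoprops(p, prop))
    return np.asarray(rows)


def glcm_features_full(
    gray: np.ndarray,
    cfg: GlcmConfig = GlcmConfig(),
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Angle-averaged GLCM statistics of the whole plane.

    Layout: for each distance (in ``cfg.distances`` order), the properties in
    ``cfg.properties`` order, each averaged over angles -> ``n_dist x n_props``
    values (12 at defaults).
    """
    table = glcm_features(glcm(gray, cfg, value_range), cfg.properties)  # (props, dist, angle)
    per_distance = table.mean(axis=2)  # (props, dist)
    return per_distance.T.reshape(-1)  # distance-major


def glcm_patch_distribution(
    gray: np.ndarray,
    cfg: GlcmConfig = GlcmConfig(),
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Distribution of per-tile GLCM statistics across the plane.

    The plane is tiled into non-overlapping ``patch_side`` squares (partial
    edge tiles discarded).  Each tile yields one scalar per property
    (averaged over distances and angles); the summaries mean, std, min, max,
    median are taken over tiles -> ``n_props x 5`` values (30 at defaults).
    """
    gray = as_gray(gray)
    s = cfg.patch_side
    ny, nx = gray.shape[0] // s, gray.shape[1] // s
    if ny == 0 or nx == 0:
        raise InvalidInputError(f"plane {gray.shape} smaller than one {s}x{s} tile")
    per_tile = []
    for iy in range(ny):
        for ix in range(nx):
            tile = gray[iy * s:(iy + 1) * s, ix * s:(ix + 1) * s]
            table = glcm_features(glcm(tile, cfg, value_range), cfg.properties)
            per_tile.append(table.mean(axis=(1, 2)))
    per_tile = np.asarray(per_tile)  # (tiles, props)
    out = []
    for j in range(per_tile.shape[1]):
        v = per_tile[:, j]
        out.extend([v.mean(), v.std(), v.min(), v.max(), np.median(v)])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# LBP (uniform, 8 neighbors in the 3x3 square, radius 1)

# circular neighbor order: E, NE, N, NW, W, SW, S, SE as (row, col) offsets
_LBP_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))


def _build_lbp_lut() -> tuple[np.ndarray, int]:
    """Map each 8-bit code to a histogram bin: uniform codes (at most two
    0/1 transitions around the circle) get bins 0..57 in ascending code
    order; all non-uniform codes share the last bin."""
    uniform = []
    for code in range(256):
        bits = [(code >> k) & 1 for k in range(8)]
        transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
        if transitions <= 2:
            uniform.append(code)
    lut = np.full(256, len(uniform), dtype=np.int64)
    for i, code in enumerate(uniform):
        lut[code] = i
    return lut, len(uniform) + 1


_LBP_LUT, LBP_BINS = _build_lbp_lut()  # 58 uniform patterns + 1 catch-all = 59 bins


def lbp_codes(gray: np.ndarray) -> np.ndarray:
    """Per-pixel LBP codes over the interior (border excluded).

    Bit k is set when the k-th circular neighbor is strictly greater than
    the center, so flat regions produce the all-zeros pattern.
    """
    gray = as_gray(gray, min_side=3)
    center = gray[1:-1, 1:-1]
    code = np.zeros(center.shape, dtype=np.int64)
    for k, (dy, dx) in enumerate(_LBP_OFFSETS):
        neigh = gray[1 + dy:gray.shape[0] - 1 + dy, 1 + dx:gray.shape[1] - 1 + dx]
        code |= (neigh > center).astype(np.int64) << k
    return code


def lbp_histogram(gray: np.ndarray) -> np.ndarray:
    """59-bin normalized uniform-LBP histogram."""
    codes = _LBP_LUT[lbp_codes(gray)]
    hist = np.bincount(codes.ravel(), minlength=LBP_BINS).astype(np.float64)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# LPQ (local phase quantization)

def _lpq_kernels(window: int) -> tuple[np.ndarray, np.ndarray]:
    """1-D Gaussian window and Gaussian-windowed complex exponential at the
    lowest non-zero STFT frequency a = 1/window."""
    r = window // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    sigma = window / 6.0
    g = np.exp(-(x ** 2) / (2 * sigma ** 2))
    g /= g.sum()
    w = g * np.exp(-2j * np.pi * x / window)
    return g, w


def lpq_codes(gray: np.ndarray, window: int = 7) -> np.ndarray:
    """Per-pixel 8-bit LPQ codes.

    A windowed short-term Fourier transform is evaluated at the four
    frequencies u1=(a,0), u2=(0,a), u3=(a,a), u4=(a,-a), a=1/window, with a
    Gaussian window; the code packs the signs of the four real and four
    imaginary parts.
    """
    gray = as_gray(gray, min_side=window)
    if window < 3 or window % 2 == 0:
        raise InvalidInputError("LPQ window must be odd and >= 3")
    g, w = _lpq_kernels(window)

    def sep(img, kx, ky):
        tmp = ndimage.correlate1d(img.astype(np.complex128), kx, axis=1, mode="reflect")
        return ndimage.correlate1d(tmp, ky, axis=0, mode="reflect")

    f1 = sep(gray, w, g)            # frequency along x
    f2 = sep(gray, g, w)            # frequency along y
    f3 = sep(gray, w, w)            # diagonal
    f4 = sep(gray, w, np.conj(w))   # anti-diagonal
    parts = [f1.real, f2.real, f3.real, f4.real, f1.imag, f2.imag, f3.imag, f4.imag]
    code = np.zeros(gray.shape, dtype=np.int64)
    for k, p in enumerate(parts):
        code |= (p >= 0).astype(np.int64) << k
    return code


def lpq_histogram(gray: np.ndarray, window: int = 7) -> np.ndarray:
    """256-bin normalized LPQ code histogram."""
    codes = lpq_codes(gray, window)
    hist = np.bincount(codes.ravel(), minlength=256).astype(np.float64)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# Gabor filter bank

def _gabor_kernel(wavelength: float, theta_deg: float, sigma_factor: float) -> np.ndarray:
    from skimage.filters import gabor_kernel

    sigma = sigma_factor * wavelength
    k = gabor_kernel(frequency=1.0 / wavelength, theta=np.deg2rad(theta_deg),
                     sigma_x=sigma, sigma_y=sigma)
    return k - k.mean()  # remove DC so constant images give zero response


def gabor_features(
    gray: np.ndarray,
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
    wavelengths: tuple[float, ...] = (4.0, 8.0, 16.0),
    sigma_factor: float = 0.56,
) -> np.ndarray:
    """Mean and variance of response magnitude per Gabor filter.

    The bank pairs every orientation (wave-vector angle, degrees) with every
    wavelength (pixels); sigma = ``sigma_factor`` x wavelength.  Layout is
    orientation-major: for each orientation, for each wavelength,
    (mean, variance) -> 24 values at defaults.
    """
    from scipy.signal import fftconvolve

    gray = as_gray(gray, min_side=16)
    out = []
    for theta in orientations:
        for lam in wavelengths:
            k = _gabor_kernel(lam, theta, sigma_factor)
            py, px = k.shape[0] // 2, k.shape[1] // 2
            padded = np.pad(gray, ((py, py), (px, px)), mode="reflect")
            resp = fftconvolve(padded, k, mode="valid")
            mag = np.abs(resp)
            out.extend([mag.mean(), mag.var()])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# full descriptor

_L_RANGE = (0.0, 100.0)


def extract_feature_vector(patch: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Concatenate all six feature families for one crop.

    Crops smaller than ``cfg.min_side`` on either side are bilinearly
    resized up (aspect preserved) so the tile-based features are defined.
    The grayscale plane for the texture operators is CIELAB L*.
    """
    patch = as_rgb(patch, min_side=8)
    h, w = patch.shape[:2]
    if min(h, w) < cfg.min_side:
        from skimage.transform import resize

        scale = cfg.min_side / min(h, w)
        patch = resize(
            patch, (int(np.ceil(h * scale)), int(np.ceil(w * scale))),
            order=1, preserve_range=True, anti_aliasing=False,
        )
    lum = rgb2lab(to_unit(patch))[:, :, 0]
    segments = [
        ("cielab", cielab_distribution_features(patch)),
        ("glcm_full", glcm_features_full(lum, cfg.glcm, _L_RANGE)),
        ("glcm_patch", glcm_patch_distribution(lum, cfg.glcm, _L_RANGE)),
        ("lbp", lbp_histogram(lum)),
        ("lpq", lpq_histogram(lum, cfg.lpq_window)),
        ("gabor", gabor_features(lum, cfg.gabor_orientations, cfg.gabor_wavelengths,
                                 cfg.gabor_sigma_factor)),
    ]
    layout = {}
    pos = 0
    for name, vec in segments:
        layout[name] = (pos, pos + len(vec))
        pos += len(vec)
    values = np.concatenate([vec for _, vec in segments])
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("non-finite feature values")
    return FeatureVector(values, layout, cfg.config_hash())


# ---------------------------------------------------------------------------
# CSV I/O

def features_to_frame(vectors: list[FeatureVector], index=None):
    import pandas as pd

    if not vectors:
        raise InvalidInputError("no feature vectors")
    names = vectors[0].feature_names()
    return pd.DataFrame([v.values for v in vectors], columns=names, index=index)


def write_features_csv(path, vectors: list[FeatureVector], index=None) -> None:
    frame = features_to_frame(vectors, index)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={vectors[0].config_hash}\n")
        frame.to_csv(fh, index=index is not None)


def read_features_csv(path):
    """Return (DataFrame, config_hash or None)."""
    import pandas as pd

    with open(path) as fh:
        first = fh.readline()
        config_hash = None
        if first.startswith("# config_hash="):
            config_hash = first.strip().split("=", 1)[1]
            frame = pd.read_csv(fh)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh)
    return frame, config_hash
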