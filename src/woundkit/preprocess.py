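"""Photograph normalization and skin/background segmentation.

Skin is separated from the background by thresholding two chroma planes in
which skin pixels cluster at the red-shifted end: the a* (green-red opponent)
channel of CIELAB and the Cr (red-difference) channel of YCbCr.  Each plane
is binarized with Otsu's threshold, the two masks are merged by logical OR
(each single-channel mask misses regions the other recovers), and the merged
mask is cleaned with a median filter to remove isolated speckles.

Conventions: CIELAB uses the sRGB companding curve and the D65 white point;
YCbCr uses the full-range ITU-R BT.601 matrix (8-bit Cr centered at 128).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab

from .errors import DegeneratePlaneError, InvalidInputError, SegmentationError
from .image import as_gray, as_mask, as_rgb, to_unit

__all__ = [
    "min_max_normalize",
    "channel_a_star",
    "channel_cr",
    "otsu_threshold",
    "otsu_mask",
    "skin_mask",
    "apply_mask",
]


def min_max_normalize(img: np.ndarray) -> np.ndarray:
    """Rescale pixel intensities onto [0, 1], jointly over all channels.

    The global (not per-channel) rescaling preserves channel ratios and hence
    hue.  A constant image maps to all-zeros rather than raising, so that
    pipelines running on degenerate crops do not abort.
    """
    img = as_rgb(img)
    if img.size == 0:
        raise InvalidInputError("empty image")
    lo = img.min()
    hi = img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def channel_a_star(img: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Extract the CIELAB a* (green-red) plane.

    With ``rescale`` (default) the plane is shifted onto the 8-bit range
    (a* + 128, clipped); with ``rescale=False`` the raw CIELAB units are
    returned (neutral gray at 0, sRGB red near +80).
    """
    lab = rgb2lab(to_unit(as_rgb(img)))
    a = lab[:, :, 1]
    if rescale:
        return np.clip(a + 128.0, 0.0, 255.0)
    return a


# Full-range BT.601: Cr = 128 + 0.5 R - 0.418688 G - 0.081312 B  (8-bit)
_CR_COEF = np.array([0.5, -0.418688, -0.081312])


def channel_cr(img: np.ndarray) -> np.ndarray:
    """Extract the YCbCr Cr (red-difference) plane, full-range BT.601, 8-bit."""
    img = as_rgb(img)
    if img.max() <= 1.0:
        img = img * 255.0
    cr = 128.0 + img @ _CR_COEF
    return np.clip(cr, 0.0, 255.0)


def otsu_threshold(plane: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    plane = as_gray(plane)
    if np.ptp(plane) == 0:
        raise DegeneratePlaneError("constant plane has no Otsu threshold")
    return float(threshold_otsu(plane))


def otsu_mask(plane: np.ndarray, skin_polarity: str = "high") -> np.ndarray:
    """Binarize a chroma plane with Otsu's threshold.

    ``skin_polarity`` selects which side of the threshold is foreground:
    ``"high"`` (default; skin chroma is red-shifted, so skin sits above the
    threshold in both a* and Cr) or ``"low"`` for unusual backgrounds.
    """
    if skin_polarity not in ("high", "low"):
        raise InvalidInputError(f"skin_polarity must be 'high' or 'low', got {skin_polarity!r}")
    plane = as_gray(plane)
    t = otsu_threshold(plane)
    mask = plane > t
    if skin_polarity == "low":
        mask = ~mask
    return mask


def skin_mask(
    img: np.ndarray,
    median_kernel: int = 5,
    skin_polarity: str = "high",
) -> np.ndarray:
    """Compute the skin-vs-background mask of a wound photograph.

    The mask is the logical OR of the Otsu masks of the a* and Cr planes,
    median-filtered with a ``median_kernel`` x ``median_kernel`` window to
    remove isolated speckles while preserving large components.

    Raises
    ------
    SegmentationError
        If both single-channel masks are empty.
    InvalidInputError
        If ``median_kernel`` is even or < 3.
    """
    if median_kernel < 3 or median_kernel % 2 == 0:
        raise InvalidInputError(f"median_kernel must be odd and >= 3, got {median_kernel}")
    img = as_rgb(img, min_side=2)
    mask_a = otsu_mask(channel_a_star(img), skin_polarity)
    mask_cr = otsu_mask(channel_cr(img), skin_polarity)
    merged = mask_a | mask_cr
    if not merged.any():
        raise SegmentationError("both channel masks are empty; no skin found")
    return ndimage.median_filter(merged, size=median_kernel, mode="nearest")


def apply_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out background pixels; foreground pixels pass through unchanged."""
    img = np.asarray(img)
    mask = as_mask(mask, like=img)
    out = img.copy()
    out[~mask] = 0
    return out
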