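"""Image carriers and small helpers.

Images are plain numpy arrays: RGB rasters are ``(H, W, 3)`` with either
8-bit integer values or unit-interval floats; grayscale planes are ``(H, W)``
floats; binary masks are ``(H, W)`` booleans.  The helpers here validate
those conventions and convert between them.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

MIN_SIDE = 32  # smallest full photograph the pipeline accepts


def as_rgb(img: np.ndarray, min_side: int = 1) -> np.ndarray:
    """Validate an RGB raster and return it as a float64 array.

    8-bit integer input is left on the 0-255 scale; float input is assumed
    to already be on whatever scale the caller uses (typically [0, 1]).
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(f"expected (H, W, 3) RGB image, got shape {img.shape}")
    if img.shape[0] < min_side or img.shape[1] < min_side:
        raise InvalidInputError(
            f"image {img.shape[0]}x{img.shape[1]} smaller than minimum side {min_side}"
        )
    out = img.astype(np.float64, copy=False)
    if not np.all(np.isfinite(out)):
        raise InvalidInputError("image contains non-finite values")
    return out


def to_unit(img: np.ndarray) -> np.ndarray:
    """Map an RGB raster onto the unit interval (divide 8-bit data by 255)."""
    img = as_rgb(img)
    if img.max() > 1.0:
        return img / 255.0
    return img


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Clip and round a raster to an 8-bit image."""
    img = np.asarray(img, dtype=np.float64)
    if img.size and img.max() <= 1.0 and img.min() >= 0.0:
        img = img * 255.0
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def as_mask(mask: np.ndarray, like: np.ndarray | None = None) -> np.ndarray:
    """Validate a binary mask, optionally against the shape of an image."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InvalidInputError(f"expected (H, W) mask, got shape {mask.shape}")
    if like is not None and mask.shape != np.asarray(like).shape[:2]:
        raise InvalidInputError(
            f"mask shape {mask.shape} does not match image shape {np.asarray(like).shape[:2]}"
        )
    return mask.astype(bool, copy=False)


def as_gray(plane: np.ndarray, min_side: int = 1) -> np.ndarray:
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise InvalidInputError(f"expected (H, W) grayscale plane, got shape {plane.shape}")
    if plane.shape[0] < min_side or plane.shape[1] < min_side:
        raise InvalidInputError(f"plane {plane.shape} smaller than minimum side {min_side}")
    return plane


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG file as an (H, W, 3) uint8 array, dropping alpha."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr[:, :, :3])


def write_image(path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, to_uint8(img))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values 0/255."""
    import imageio.v3 as iio

    iio.imwrite(path, (as_mask(mask).astype(np.uint8) * 255))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks; 1.0 when both are empty."""
    a = as_mask(a)
    b = as_mask(b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom
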