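"""Image reading/writing and array validation.

Images are handled as float64 RGB arrays in [0, 1], masks as boolean arrays.
8-bit files are divided by 255 on read; masks are written as 0/255 PNG.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

from .exceptions import ShapeMismatchError, UlcerSegError

#: smallest supported image side, in pixels
MIN_SIZE = 64


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check that ``image`` is a valid H×W×3 intensity array in [0, 1].

    Returns the array unchanged so the call can be used inline.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise UlcerSegError(f"expected an H×W×3 RGB array, got shape {image.shape}")
    if image.shape[0] < MIN_SIZE or image.shape[1] < MIN_SIZE:
        raise UlcerSegError(
            f"image {image.shape[0]}×{image.shape[1]} is below the "
            f"minimum supported size of {MIN_SIZE}×{MIN_SIZE}"
        )
    if not np.issubdtype(image.dtype, np.floating):
        raise UlcerSegError("image must be a float array scaled to [0, 1]")
    lo, hi = float(image.min()), float(image.max())
    if lo < -1e-9 or hi > 1 + 1e-9:
        raise UlcerSegError(f"image intensities outside [0, 1]: min={lo}, max={hi}")
    return image


def validate_mask(mask: np.ndarray, like: np.ndarray | None = None) -> np.ndarray:
    """Check that ``mask`` is a 2-D boolean array, optionally shape-matched to ``like``."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise UlcerSegError(f"expected a 2-D mask, got shape {mask.shape}")
    if mask.dtype != bool:
        raise UlcerSegError(f"mask must be boolean, got dtype {mask.dtype}")
    if like is not None and mask.shape != np.asarray(like).shape[:2]:
        raise ShapeMismatchError(
            f"mask shape {mask.shape} does not match image shape "
            f"{np.asarray(like).shape[:2]}"
        )
    return mask


def read_rgb(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit (or 16-bit) raster file as a normalized RGB array."""
    raw = iio.imread(path)
    if raw.ndim == 2:  # grayscale: replicate into three channels
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[-1] == 4:  # drop alpha
        raw = raw[..., :3]
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
        img = raw.astype(np.float64) / scale
    else:
        img = np.clip(raw.astype(np.float64), 0.0, 1.0)
    return validate_rgb(img)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a single-channel mask file; any nonzero pixel is foreground."""
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[..., 0]
    return raw > 0


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit 0/255 single-channel PNG."""
    validate_mask(mask)
    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def write_rgb(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a [0, 1] float RGB array as an 8-bit PNG."""
    validate_rgb(image)
    iio.imwrite(path, np.round(np.clip(image, 0, 1) * 255).astype(np.uint8))
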