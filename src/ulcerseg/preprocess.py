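"""Preprocessing chain for fluorescein slit-lamp images.

Under cobalt-blue illumination the tear film's specular highlights saturate all
three channels, while fluorescein pools (ulcers, lid-margin menisci) dominate
the green channel.  The chain therefore:

1. builds a specular-reflection mask from the squared blue channel,
2. smooths the green channel and zeroes the reflections,
3. squares and binarizes the result (squaring stretches bright fluorescein
   away from the dimmer sclera before the threshold is chosen),
4. restricts it to an elliptical pre-mask derived from image moments, and
5. thins the surviving foreground to a 1-px skeleton for shape recognition.

All operations are deterministic: identical inputs give bit-identical masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing as _sk_closing
from skimage.morphology import disk
from skimage.morphology import thin as _sk_thin

from .exceptions import EmptyMaskError, ShapeMismatchError, UlcerSegError
from .io import validate_mask, validate_rgb


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain.

    gaussian_sigma
        Std-dev (pixels) of the green-channel low-pass filter. Default 2.0:
        suppresses sensor noise without erasing small point ulcers.
    closing_radius
        Disk radius (pixels) of the morphological closing applied to the
        binarized blue channel; specular highlights are compact blobs.
    threshold_method
        ``"otsu"`` (per-image, parameter-free) or ``"fixed"``.
    fixed_threshold
        Intensity threshold in [0, 1] applied to *squared* values when
        ``threshold_method == "fixed"``.
    ellipse_dilation_factor
        Both semi-axes of the moment-derived ellipse pre-mask are scaled by
        this factor so the pre-mask never clips the true eye border.
    """

    gaussian_sigma: float = 2.0
    closing_radius: int = 5
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.5
    ellipse_dilation_factor: float = 1.15

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.closing_radius < 1:
            raise ValueError("closing_radius must be >= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if not 0.0 <= self.fixed_threshold <= 1.0:
            raise ValueError("fixed_threshold must lie in [0, 1]")
        if not 1.0 <= self.ellipse_dilation_factor <= 2.0:
            raise ValueError("ellipse_dilation_factor must lie in [1, 2]")


def _threshold(values: np.ndarray, cfg: PreprocessConfig) -> float | None:
    """Threshold for ``values`` (already squared). None signals a degenerate input."""
    if cfg.threshold_method == "fixed":
        return cfg.fixed_threshold
    if values.size == 0 or float(values.max() - values.min()) < 1e-12:
        return None
    return float(threshold_otsu(values))


def specular_reflection_mask(image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Complement mask of the specular reflections (True = keep, not reflection).

    The blue channel is squared and binarized; the bright class is closed with
    a disk so each highlight becomes one solid blob; the complement is returned.
    A constant blue channel yields an all-True mask (nothing to exclude) plus
    a warning.
    """
    validate_rgb(image)
    blue = image[..., 2]
    sq = blue * blue
    if float(sq.max() - sq.min()) < 1e-12:
        warnings.warn(
            "blue channel is constant; no specular reflection detected",
            stacklevel=2,
        )
        return np.ones(sq.shape, dtype=bool)
    t = _threshold(sq.ravel(), cfg)
    if t is None:  # unreachable for non-constant input, kept for safety
        return np.ones(sq.shape, dtype=bool)
    bright = sq > t
    closed = _sk_closing(bright, disk(cfg.closing_radius))
    return ~closed


def masked_green(
    image: np.ndarray, reflection_mask: np.ndarray, cfg: PreprocessConfig
) -> np.ndarray:
    """Gaussian-smoothed green channel with reflections zeroed.

    Returns ``G_s ⊙ M`` where ``G_s`` is the green channel convolved with a
    Gaussian of ``cfg.gaussian_sigma`` and ``M`` the reflection (complement)
    mask.  Output stays in [0, 1].
    """
    validate_rgb(image)
    validate_mask(reflection_mask)
    if reflection_mask.shape != image.shape[:2]:
        raise ShapeMismatchError(
            f"reflection mask {reflection_mask.shape} does not match "
            f"image {image.shape[:2]}"
        )
    smoothed = ndi.gaussian_filter(image[..., 1], sigma=cfg.gaussian_sigma)
    return np.clip(smoothed, 0.0, 1.0) * reflection_mask


def square_binarize(
    gray: np.ndarray,
    cfg: PreprocessConfig,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Square the intensities, then binarize.

    Squaring precedes thresholding: it spreads bright fluorescein away from
    the background and moves the Otsu split point.  With ``support`` given,
    the threshold is estimated from (and the mask restricted to) the support
    pixels only — used downstream where the region of interest is a small
    part of the frame.  A constant input yields an empty mask plus a warning.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise UlcerSegError(f"expected a 2-D intensity array, got {gray.shape}")
    if float(gray.min()) < -1e-9 or float(gray.max()) > 1 + 1e-9:
        raise UlcerSegError("intensities must lie in [0, 1]")
    sq = gray * gray
    if support is None:
        values = sq.ravel()
        region = None
    else:
        validate_mask(support)
        if support.shape != gray.shape:
            raise ShapeMismatchError("support mask shape mismatch")
        values = sq[support]
        region = support
        if values.size == 0:
            return np.zeros(gray.shape, dtype=bool)
    t = _threshold(values, cfg)
    if t is None:
        warnings.warn("constant input; binarization is degenerate", stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    out = sq > t
    if region is not None:
        out &= region
    return out


def ellipse_premask(mask: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Axis-aligned elliptical mask covering the foreground of ``mask``.

    Centroid and semi-axes come from the first and second moments of the
    union of True pixels (for a filled ellipse, semi-axis = 2·std along the
    axis); both semi-axes are scaled by ``cfg.ellipse_dilation_factor``.
    Orientation is deliberately zeroed — eyes are near-horizontal in this
    imaging protocol.  A single-pixel mask degenerates to a disk of radius
    ``closing_radius``; an empty mask is an error.
    """
    validate_mask(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("no fluorescein response detected")
    r0, c0 = float(rows.mean()), float(cols.mean())
    rr, cc = np.ogrid[: mask.shape[0], : mask.shape[1]]
    if rows.size == 1:
        rad = float(cfg.closing_radius)
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= rad * rad
    semi_row = max(2.0 * float(rows.std()), 1.0)
    semi_col = max(2.0 * float(cols.std()), 1.0)
    semi_row *= cfg.ellipse_dilation_factor
    semi_col *= cfg.ellipse_dilation_factor
    return ((rr - r0) / semi_row) ** 2 + ((cc - c0) / semi_col) ** 2 <= 1.0


def thin(mask: np.ndarray) -> np.ndarray:
    """Morphological thinning to a 1-px-wide, 8-connected skeleton.

    Homotopic: the number of connected components never increases.
    """
    validate_mask(mask)
    return _sk_thin(mask)
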