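"""Gielis-Superformula shape model for the eye border, and the cornea disk.

The eye aperture outline is modeled by the Superformula (Gielis curve)

    r(φ) = [ |cos(mφ/4)/a|^n2 + |sin(mφ/4)/b|^n3 ]^(−1/n1)

with n1 = n2 = n3 = 1 and rotational symmetry m = 2, which traces the
lens-like palpebral-aperture shape.  The dimensionless curve carries no
pixel geometry: ``a`` and ``b`` stay at 1 and the anisotropy (semi-major vs
semi-minor) is applied as independent per-axis pixel scales when the curve is
discretized into a template.

The cornea sits directly in front of the iris and pupil; it is represented by
a disk whose *diameter* equals the recognized border's semi-minor axis and
whose center coincides with the border center.  Because that sentence-level
rule is geometrically ambiguous, ``radius_mode="semi_minor"`` is available to
use the semi-minor axis as the radius instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import quad

from .exceptions import UlcerSegError


@dataclass(frozen=True)
class GielisParams:
    """Superformula parameter set (a, b, m, n1, n2, n3)."""

    a: float = 1.0
    b: float = 1.0
    m: float = 2.0
    n1: float = 1.0
    n2: float = 1.0
    n3: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be > 0")
        if self.n1 == 0:
            raise ValueError("n1 must be nonzero")


#: eye-border parameter set: n1 = n2 = n3 = 1, m = 2
DEFAULT_EYE_PARAMS = GielisParams()


def gielis_radius(phi, p: GielisParams = DEFAULT_EYE_PARAMS):
    """Radial distance r(φ) of the Gielis curve; accepts scalars or arrays."""
    phi = np.asarray(phi, dtype=np.float64)
    c = np.abs(np.cos(p.m * phi / 4.0) / p.a) ** p.n2
    s = np.abs(np.sin(p.m * phi / 4.0) / p.b) ** p.n3
    total = c + s
    if np.any(total == 0.0):
        raise UlcerSegError("undefined radius: both Superformula terms vanish")
    r = total ** (-1.0 / p.n1)
    return float(r) if r.ndim == 0 else r


@dataclass
class ShapeTemplate:
    """Discretized Gielis curve: zero-mean (row, col) offsets in pixels."""

    points: np.ndarray  # (n, 2) float array of (row_offset, col_offset)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


def gielis_template(
    p: GielisParams,
    n_points: int,
    scale_row: float,
    scale_col: float,
    rotation: float = 0.0,
) -> ShapeTemplate:
    """Sample the closed Gielis outline into a centered pixel-offset template.

    φ is sampled uniformly over [0, 2π); (r, φ) maps to Cartesian offsets with
    independent row/col scaling (this anisotropic scaling realizes the
    semi-minor/semi-major distinction), then rotation, then recentering to
    zero mean.
    """
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = gielis_radius(phi, p)
    row = r * np.sin(phi) * scale_row
    col = r * np.cos(phi) * scale_col
    if rotation != 0.0:
        cr, sr = np.cos(rotation), np.sin(rotation)
        row, col = cr * row - sr * col, sr * row + cr * col
    pts = np.stack([row - row.mean(), col - col.mean()], axis=1)
    return ShapeTemplate(points=pts)


@lru_cache(maxsize=32)
def curve_extents(p: GielisParams = DEFAULT_EYE_PARAMS) -> tuple[float, float]:
    """(row_extent, col_extent): max |offset| of the unit-scale curve.

    For the default eye parameters these are 1/√2 and 1, so a fit with
    semi-minor B and semi-major A uses scales (B/row_extent, A/col_extent).
    """
    phi = np.linspace(0.0, 2.0 * np.pi, 8192, endpoint=False)
    r = gielis_radius(phi, p)
    return float(np.abs(r * np.sin(phi)).max()), float(np.abs(r * np.cos(phi)).max())


@lru_cache(maxsize=32)
def unit_curve_area(p: GielisParams = DEFAULT_EYE_PARAMS) -> float:
    """Enclosed area of the unit-scale curve, ∫ ½ r(φ)² dφ over [0, 2π]."""
    val, _ = quad(lambda f: 0.5 * gielis_radius(f, p) ** 2, 0.0, 2.0 * np.pi, limit=200)
    return float(val)


@dataclass
class EyeBorderFit:
    """Recognized (or ground-truth) eye-border pose.

    ``semi_major``/``semi_minor`` are the pixel half-extents along the
    unrotated column/row axes; ``votes`` and ``vote_fraction`` carry the
    Hough evidence (zero for ground-truth poses).
    """

    center: tuple[float, float]  # (row, col)
    semi_major: float
    semi_minor: float
    rotation: float = 0.0
    votes: int = 0
    vote_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise ValueError(
                f"require semi_major >= semi_minor > 0, got "
                f"{self.semi_major}, {self.semi_minor}"
            )
        if not 0.0 <= self.vote_fraction <= 1.0:
            raise ValueError("vote_fraction must lie in [0, 1]")


def fit_scales(fit: EyeBorderFit, p: GielisParams = DEFAULT_EYE_PARAMS) -> tuple[float, float]:
    """(scale_row, scale_col) realizing the fit's semi-axes for curve ``p``."""
    row_ext, col_ext = curve_extents(p)
    return fit.semi_minor / row_ext, fit.semi_major / col_ext


def template_for_fit(
    fit: EyeBorderFit,
    p: GielisParams = DEFAULT_EYE_PARAMS,
    n_points: int = 512,
) -> ShapeTemplate:
    """Template whose half-extents match the fit's semi-axes."""
    scale_row, scale_col = fit_scales(fit, p)
    return gielis_template(p, n_points, scale_row, scale_col, fit.rotation)


@dataclass
class CorneaDisk:
    """Circular cornea region: center (row, col) and radius, in pixels."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cornea disk radius must be > 0")


def cornea_disk_from_fit(fit: EyeBorderFit, radius_mode: str = "half_semi_minor") -> CorneaDisk:
    """Cornea disk centered on the recognized border.

    ``half_semi_minor`` (default): the disk *diameter* equals the semi-minor
    axis, i.e. radius = semi_minor / 2.  ``semi_minor``: radius = semi_minor
    (the disk then spans the full aperture height).
    """
    if fit.semi_minor <= 0:
        raise ValueError("fit.semi_minor must be > 0")
    if radius_mode == "half_semi_minor":
        radius = fit.semi_minor / 2.0
    elif radius_mode == "semi_minor":
        radius = float(fit.semi_minor)
    else:
        raise ValueError(f"unknown radius_mode {radius_mode!r}")
    return CorneaDisk(center=fit.center, radius=radius)


def disk_mask(disk: CorneaDisk, shape: tuple[int, int]) -> np.ndarray:
    """Filled boolean disk clipped to ``shape``; warns when clipping occurs."""
    h, w = shape
    r0, c0 = disk.center
    rad = disk.radius
    if r0 - rad < -0.5 or c0 - rad < -0.5 or r0 + rad > h - 0.5 or c0 + rad > w - 0.5:
        warnings.warn("cornea disk extends beyond the image and was clipped", stacklevel=2)
    rr, cc = np.ogrid[:h, :w]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= rad * rad
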