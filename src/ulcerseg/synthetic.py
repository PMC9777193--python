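"""Seeded synthetic fluorescein-eye scenes with exhaustive ground truth.

Each scene emulates the salient structure of cobalt-blue slit-lamp
photographs of fluorescein-stained eyes:

* a dark skin background and a lens-shaped (Gielis) palpebral aperture filled
  with a bluish sclera/illumination tone,
* a darker circular cornea/iris region in front of the pupil,
* a bright green tear-film meniscus line hugging the aperture border (the
  lid margins), which is what makes the border recognizable in the green
  channel,
* zero or more bright green ulcer blobs inside the cornea,
* saturated white specular-reflection spots inside the eye, and
* optionally an elongated high-green eyelid-stain arc along the upper border.

Ulcer blobs are smooth elliptical generalized-Gaussian bumps (order 6) whose
half-peak contour defines the ground-truth mask; the steep shoulder keeps
that contour unambiguous under any mid-range binarization threshold.
Everything is reproducible from the scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk as disk_se

from .hough import fill_border
from .shapes import (
    DEFAULT_EYE_PARAMS,
    EyeBorderFit,
    cornea_disk_from_fit,
    disk_mask,
    gielis_radius,
)

# scene palette (R, G, B), chosen once to mimic cobalt-blue illumination:
# periocular skin glows dark violet, sclera is bluish, the cornea/iris darker,
# fluorescein bright green; specular reflexes saturate all channels
BACKGROUND = (0.10, 0.07, 0.16)
SCLERA = (0.08, 0.20, 0.26)
CORNEA = (0.05, 0.10, 0.18)
RING_COLOR = (0.10, 0.85, 0.30)
ARC_BLUE = 0.30
ARC_RED = 0.12

#: tear-meniscus line thickness (pixels) and gap (radians) isolating it from
#: an eyelid-stain arc so the two remain distinct connected components
RING_THICKNESS = 5
RING_ARC_GAP = 0.18

#: generalized-Gaussian order of the ulcer profile (steep half-peak shoulder)
BLOB_ORDER = 6

#: angular position of the upper lid in image coordinates (row axis points
#: down, so the top of the eye is at φ = 3π/2)
UPPER_LID_ANGLE = 3.0 * np.pi / 2.0


@dataclass(frozen=True)
class UlcerBlob:
    """One fluorescein-stained lesion.

    ``semi_axes`` (row, col) give the half-peak contour; ``peak`` is the
    absolute peak green intensity in [0, 1].
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    peak: float


@dataclass(frozen=True)
class EyelidArc:
    """Elongated lid-margin stain along the upper border."""

    thickness: int = 6
    extent: float = 1.2  # radians of border arc covered
    intensity: float = 0.9


@dataclass
class SceneParams:
    """Full description of one synthetic scene."""

    image_size: tuple[int, int] = (240, 320)
    border: EyeBorderFit = field(
        default_factory=lambda: EyeBorderFit(center=(120.0, 160.0), semi_major=105.0, semi_minor=65.0)
    )
    ulcer_blobs: list[UlcerBlob] = field(default_factory=list)
    n_reflections: int = 3
    reflection_radius_range: tuple[int, int] = (4, 7)
    eyelid_arc: EyelidArc | None = None
    noise_sigma: float = 0.01
    seed: int = 0


@dataclass
class SyntheticScene:
    image: np.ndarray
    truth_ulcer: np.ndarray
    truth_cornea: np.ndarray
    truth_border: EyeBorderFit
    truth_reflections: np.ndarray
    truth_eyelid: np.ndarray
    params: SceneParams


def _border_points(fit: EyeBorderFit, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of the border curve at angles ``phi``."""
    from .shapes import fit_scales

    scale_row, scale_col = fit_scales(fit, DEFAULT_EYE_PARAMS)
    r = gielis_radius(phi, DEFAULT_EYE_PARAMS)
    row = r * np.sin(phi) * scale_row
    col = r * np.cos(phi) * scale_col
    if fit.rotation != 0.0:
        cr, sr = np.cos(fit.rotation), np.sin(fit.rotation)
        row, col = cr * row - sr * col, sr * row + cr * col
    return row + fit.center[0], col + fit.center[1]


def _curve_mask(
    rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int], thickness: int
) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    rr = np.round(rows).astype(int)
    cc = np.round(cols).astype(int)
    ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    out[rr[ok], cc[ok]] = True
    if thickness > 1:
        out = ndi.binary_dilation(out, structure=disk_se(thickness // 2))
    return out


def _angdiff(phi: np.ndarray, center: float) -> np.ndarray:
    return np.abs((phi - center + np.pi) % (2.0 * np.pi) - np.pi)


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render one scene and its ground-truth masks. Deterministic in the seed."""
    h, w = params.image_size
    fit = params.border
    cornea = cornea_disk_from_fit(fit)  # generator uses the pipeline's disk rule
    radius = cornea.radius
    for blob in params.ulcer_blobs:
        d = np.hypot(blob.center[0] - cornea.center[0], blob.center[1] - cornea.center[1])
        if d + max(blob.semi_axes) > radius + 1e-9:
            raise ValueError(
                f"ulcer blob at {blob.center} with semi-axes {blob.semi_axes} "
                f"extends outside the cornea disk (radius {radius:.1f})"
            )
        if not 0.0 < blob.peak <= 1.0:
            raise ValueError("blob peak intensity must lie in (0, 1]")

    rng = np.random.default_rng(params.seed)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = BACKGROUND
    eye = fill_border(fit, DEFAULT_EYE_PARAMS, (h, w))
    img[eye] = SCLERA
    truth_cornea = disk_mask(cornea, (h, w))
    img[truth_cornea] = CORNEA

    # tear-film meniscus line along the border; leave a gap around the eyelid
    # arc span so ring and arc binarize into distinct components
    phi = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    ring_phi = phi
    if params.eyelid_arc is not None:
        half = params.eyelid_arc.extent / 2.0 + RING_ARC_GAP
        ring_phi = phi[_angdiff(phi, UPPER_LID_ANGLE) > half]
    ring = _curve_mask(*_border_points(fit, ring_phi), (h, w), RING_THICKNESS)
    img[ring] = RING_COLOR

    truth_eyelid = np.zeros((h, w), dtype=bool)
    if params.eyelid_arc is not None:
        arc = params.eyelid_arc
        arc_phi = phi[_angdiff(phi, UPPER_LID_ANGLE) <= arc.extent / 2.0]
        truth_eyelid = _curve_mask(*_border_points(fit, arc_phi), (h, w), arc.thickness)
        img[truth_eyelid] = (ARC_RED, arc.intensity, ARC_BLUE)

    # ulcer blobs: generalized-Gaussian green bumps, truth = half-peak contour
    truth_ulcer = np.zeros((h, w), dtype=bool)
    rr, cc = np.ogrid[:h, :w]
    for blob in params.ulcer_blobs:
        (br, bc), (s_r, s_c) = blob.center, blob.semi_axes
        rho2 = ((rr - br) / s_r) ** 2 + ((cc - bc) / s_c) ** 2
        profile = np.exp(-np.log(2.0) * rho2 ** (BLOB_ORDER / 2.0))
        amp = blob.peak - CORNEA[1]
        img[..., 1] = np.maximum(img[..., 1], CORNEA[1] + amp * profile)
        truth_ulcer |= profile >= 0.5

    # specular reflections: saturated white disks placed well inside the eye,
    # kept clear of the ulcer truth so the masks stay disjoint by construction
    truth_reflections = np.zeros((h, w), dtype=bool)
    lo, hi = params.reflection_radius_range
    for _ in range(params.n_reflections):
        for _attempt in range(100):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            frac = 0.72 * np.sqrt(rng.uniform())
            r_curve = gielis_radius(ang, DEFAULT_EYE_PARAMS)
            from .shapes import fit_scales

            scale_row, scale_col = fit_scales(fit, DEFAULT_EYE_PARAMS)
            pr = fit.center[0] + frac * r_curve * np.sin(ang) * scale_row
            pc = fit.center[1] + frac * r_curve * np.cos(ang) * scale_col
            rad = int(rng.integers(lo, hi + 1))
            clear = all(
                np.hypot(pr - b.center[0], pc - b.center[1])
                > rad + max(b.semi_axes) * 1.4 + 2
                for b in params.ulcer_blobs
            )
            if clear:
                spot = (rr - pr) ** 2 + (cc - pc) ** 2 <= rad * rad
                truth_reflections |= spot
                img[spot] = (1.0, 1.0, 1.0)
                break

    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    return SyntheticScene(
        image=img,
        truth_ulcer=truth_ulcer,
        truth_cornea=truth_cornea,
        truth_border=fit,
        truth_reflections=truth_reflections,
        truth_eyelid=truth_eyelid,
        params=params,
    )


#: fraction of suite scenes rendered without any ulcer (negative controls)
HEALTHY_FRACTION = 0.10

_DIFFICULTIES = ("easy", "medium", "hard")


def generate_suite(
    n: int,
    difficulty: str = "medium",
    seed: int = 0,
    image_size: tuple[int, int] = (240, 320),
) -> list[SyntheticScene]:
    """Sample ``n`` scenes from difficulty-dependent parameter distributions.

    ``easy``: one high-contrast blob, no eyelid arc, light noise.
    ``medium``: 1–3 blobs, more reflections, eyelid arc in half the scenes.
    ``hard``: low contrast, heavy noise, small eye rotation, arc always.
    Roughly 10% of scenes are healthy (no blobs).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if difficulty not in _DIFFICULTIES:
        raise ValueError(f"difficulty must be one of {_DIFFICULTIES}")
    rng = np.random.default_rng(seed)
    h, w = image_size
    scenes = []
    for _ in range(n):
        center = (h * rng.uniform(0.48, 0.52), w * rng.uniform(0.48, 0.53))
        semi_major = w * rng.uniform(0.28, 0.36)
        semi_minor = h * rng.uniform(0.23, 0.31)
        rotation = rng.uniform(-0.07, 0.07) if difficulty == "hard" else 0.0
        border = EyeBorderFit(
            center=center, semi_major=semi_major, semi_minor=semi_minor, rotation=rotation
        )
        healthy = rng.random() < HEALTHY_FRACTION

        if difficulty == "easy":
            n_blobs, peak_rng, noise = 1, (0.85, 0.95), 0.01
            arc = None
            n_refl = int(rng.integers(2, 4))
        elif difficulty == "medium":
            n_blobs, peak_rng, noise = int(rng.integers(1, 4)), (0.75, 0.90), 0.02
            arc = (
                EyelidArc(extent=float(rng.uniform(0.9, 1.6)))
                if rng.random() < 0.5
                else None
            )
            n_refl = int(rng.integers(2, 5))
        else:
            n_blobs, peak_rng, noise = int(rng.integers(1, 4)), (0.55, 0.75), 0.045
            arc = EyelidArc(extent=float(rng.uniform(0.9, 1.6)))
            n_refl = int(rng.integers(3, 6))

        blobs = []
        if not healthy:
            radius = semi_minor / 2.0
            for _b in range(n_blobs):
                s_r = radius * rng.uniform(0.28, 0.45)
                s_c = radius * rng.uniform(0.28, 0.45)
                margin = radius - max(s_r, s_c) - 2.0
                ang = rng.uniform(0.0, 2.0 * np.pi)
                d = margin * rng.uniform()
                blobs.append(
                    UlcerBlob(
                        center=(center[0] + d * np.sin(ang), center[1] + d * np.cos(ang)),
                        semi_axes=(s_r, s_c),
                        peak=float(rng.uniform(*peak_rng)),
                    )
                )
        params = SceneParams(
            image_size=image_size,
            border=border,
            ulcer_blobs=blobs,
            n_reflections=n_refl,
            eyelid_arc=arc,
            noise_sigma=noise,
            seed=int(rng.integers(2**31)),
        )
        scenes.append(generate_scene(params))
    return scenes
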