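"""Ulcer candidate extraction inside the cornea and eyelid-stain rejection.

Fluorescein also pools along the eyelid margins; those accumulations show up
as elongated segments hugging the recognized eye border.  A candidate segment
is rejected iff it (a) touches the rendered border and (b) has a moment-
ellipse semi-major/semi-minor ratio above a threshold — both conditions are
required, so compact lesions near the border and elongated lesions in the
open cornea both survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import closing as sk_closing
from skimage.morphology import disk

from .config import RunConfig
from .exceptions import (
    BorderNotFoundError,
    CorneaError,
    EmptyMaskError,
    InsufficientEdgeError,
    ShapeMismatchError,
    StageError,
    UlcerSegError,
)
from .hough import fill_border, hough_fit_eye_border, render_border
from .io import validate_mask, validate_rgb
from .preprocess import (
    PreprocessConfig,
    ellipse_premask,
    masked_green,
    specular_reflection_mask,
    square_binarize,
    thin,
)
from .shapes import CorneaDisk, EyeBorderFit, cornea_disk_from_fit, disk_mask

#: floor on the moment-ellipse semi-minor axis (1-px-wide segments), pixels
MINOR_AXIS_FLOOR = 0.5

#: smallest meaningful cornea radius, pixels
MIN_CORNEA_RADIUS = 5.0


@dataclass(frozen=True)
class SegmentFeatures:
    """Moment features of one connected candidate segment."""

    label: int
    area: int
    semi_major: float
    semi_minor: float
    axis_ratio: float
    touches_border: bool


@dataclass
class SegmentationResult:
    """Everything the pipeline produced for one image."""

    ulcer_mask: np.ndarray
    cornea_mask: np.ndarray
    border_fit: EyeBorderFit
    reflection_mask: np.ndarray
    rejected_segments: list[SegmentFeatures]
    overlay: np.ndarray
    stages: dict[str, np.ndarray] = field(default_factory=dict)


def extract_cornea_region(
    image: np.ndarray, cornea: CorneaDisk, reflection_mask: np.ndarray
) -> np.ndarray:
    """Green channel × cornea-disk mask × reflection mask."""
    validate_rgb(image)
    validate_mask(reflection_mask, like=image)
    if cornea.radius < MIN_CORNEA_RADIUS:
        raise CorneaError(f"cornea too small: radius {cornea.radius:.1f} px")
    h, w = image.shape[:2]
    r0, c0 = cornea.center
    if r0 + cornea.radius < 0 or r0 - cornea.radius >= h or c0 + cornea.radius < 0 or c0 - cornea.radius >= w:
        raise CorneaError("cornea disk lies entirely outside the image")
    dmask = disk_mask(cornea, (h, w))
    return image[..., 1] * dmask * reflection_mask


def candidate_ulcer_mask(
    cornea_green: np.ndarray,
    cfg: PreprocessConfig,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Square-and-binarize restricted to the cornea support.

    The threshold is estimated over the support pixels only (default: the
    nonzero pixels), so the zeroed-out surround cannot drag it down.  An
    empty result is legal — a healthy eye has no fluorescein uptake.
    """
    cornea_green = np.asarray(cornea_green, dtype=np.float64)
    if support is None:
        support = cornea_green > 0
    if not support.any():
        return np.zeros(cornea_green.shape, dtype=bool)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant support region → empty mask
        return square_binarize(cornea_green, cfg, support=support)


def segment_features(
    candidates: np.ndarray,
    border: np.ndarray,
    border_dilation_px: int = 2,
) -> tuple[np.ndarray, list[SegmentFeatures]]:
    """Label 8-connected candidate segments and compute their moment features.

    Returns the label image and one SegmentFeatures per segment.  Border
    contact is tested against the rendered border dilated by
    ``border_dilation_px`` (equivalently: the segment dilated by the same
    amount intersects the border), absorbing rasterization gaps.
    """
    validate_mask(candidates)
    validate_mask(border)
    if candidates.shape != border.shape:
        raise ShapeMismatchError("candidate and border masks differ in shape")
    labels = sk_label(candidates, connectivity=2)
    if border_dilation_px > 0:
        border_dil = ndi.binary_dilation(border, structure=disk(border_dilation_px))
    else:
        border_dil = border
    touching = set(np.unique(labels[border_dil])) - {0}
    feats = []
    for prop in regionprops(labels):
        semi_major = prop.axis_major_length / 2.0
        semi_minor = prop.axis_minor_length / 2.0
        ratio = semi_major / max(semi_minor, MINOR_AXIS_FLOOR)
        feats.append(
            SegmentFeatures(
                label=int(prop.label),
                area=int(prop.area),
                semi_major=float(semi_major),
                semi_minor=float(semi_minor),
                axis_ratio=float(max(ratio, 1.0)),
                touches_border=prop.label in touching,
            )
        )
    return labels, feats


def filter_eyelid_segments(
    candidates: np.ndarray,
    border: np.ndarray,
    ratio_threshold: float,
    border_dilation_px: int = 2,
) -> tuple[np.ndarray, list[SegmentFeatures]]:
    """Drop segments that touch the border AND are elongated beyond the threshold.

    Returns the surviving mask and the features of the rejected segments.
    Raising the threshold never removes more segments (anti-monotone filter).
    """
    labels, feats = segment_features(candidates, border, border_dilation_px)
    rejected = [
        f for f in feats if f.touches_border and f.axis_ratio > ratio_threshold
    ]
    kept = candidates.copy()
    for f in rejected:
        kept[labels == f.label] = False
    return kept, rejected


def _stage(name: str):
    """Decorator-free helper: re-raise any stage failure with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, UlcerSegError) and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def segment_ulcer(image: np.ndarray, config: RunConfig | None = None) -> SegmentationResult:
    """Run the full classical chain on one RGB image.

    preprocess → thin → Hough border fit → cornea disk → candidate extraction
    → eyelid-segment rejection → disk clipping → overlay.  A "no ulcer found"
    outcome is a success with an empty mask; stage failures raise StageError
    with the stage name attached.

    Candidate segments are extracted over the *filled fitted border* so that
    lid-margin accumulations remain connected to the border when the contact
    test runs; only the surviving segments are then clipped to the cornea
    disk (the ulcer lives on the cornea).
    """
    if config is None:
        config = RunConfig()
    validate_rgb(image)
    pp = config.preprocess
    gparams = config.shape.gielis_params()
    shape_hw = image.shape[:2]

    with _stage("reflection"):
        reflection = specular_reflection_mask(image, pp)
    with _stage("masked_green"):
        green_s = masked_green(image, reflection, pp)
    with _stage("binarize_green"):
        bin_green = square_binarize(green_s, pp)
    with _stage("ellipse_premask"):
        premask = ellipse_premask(bin_green, pp)
    with _stage("close_and_mask"):
        closed = sk_closing(bin_green, disk(pp.closing_radius)) & premask
    with _stage("thin"):
        edges = thin(closed)
    with _stage("hough"):
        space = config.hough.search_space(shape_hw)
        fit = hough_fit_eye_border(
            edges,
            gparams,
            space,
            min_vote_fraction=config.hough.min_vote_fraction,
            n_points=config.shape.n_points,
        )
    with _stage("border"):
        border = render_border(fit, gparams, shape_hw)
        filled = fill_border(fit, gparams, shape_hw)
    with _stage("cornea"):
        cornea = cornea_disk_from_fit(fit, config.cornea.radius_mode)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # clipping is reported via stages
            cornea_mask = disk_mask(cornea, shape_hw)
        cornea_green = extract_cornea_region(image, cornea, reflection)
    with _stage("candidates"):
        candidates = candidate_ulcer_mask(
            green_s * filled, pp, support=filled & reflection
        )
    with _stage("filter"):
        kept, rejected = filter_eyelid_segments(
            candidates,
            border,
            config.extract.ratio_threshold,
            config.extract.border_dilation_px,
        )
    ulcer = kept & cornea_mask & reflection
    overlay = image * ulcer[..., None]
    stages = {
        "reflection_mask": reflection,
        "masked_green": green_s,
        "binarized_green": bin_green,
        "ellipse_premask": premask,
        "masked_binarized": closed,
        "thinned": edges,
        "border_outline": border,
        "cornea_region": cornea_green,
        "candidates": candidates,
    }
    return SegmentationResult(
        ulcer_mask=ulcer,
        cornea_mask=cornea_mask,
        border_fit=fit,
        reflection_mask=reflection,
        rejected_segments=rejected,
        overlay=overlay,
        stages=stages,
    )
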