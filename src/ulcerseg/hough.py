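"""Generalized Hough transform over the Gielis eye-border template.

The search space covers the template's per-axis pixel scales (semi-minor /
semi-major half-extents) and a small rotation range; the slit-lamp protocol
keeps eyes near-horizontal, so the default rotation band is narrow.

Voting semantics (shared by the vectorized path and the brute-force oracle
used in tests):

* The edge image is dilated by a 3×3 square — the ±1 px tolerance band that
  absorbs rasterization jitter of the unit-thickness template.
* For each (scale_row, scale_col, rotation) cell the template is rasterized
  into the set of *unique* integer offsets ``O``.
* Every dilated-edge pixel ``e`` casts one vote per offset ``o ∈ O`` for the
  candidate center ``c = e − o`` (dual-template voting: mathematically the
  same as sliding the template, far cheaper).  Votes land in accumulator bins
  of ``center_stride`` pixels.
* The global argmax bin is refined at 1-px resolution: the final score of a
  center ``c`` is ``#{o ∈ O : dilated_edges[c + o]}``, so the reported
  ``vote_fraction = votes / |O|`` lies in [0, 1].

Ties are broken deterministically: in the coarse accumulator by (lowest row,
then lowest col, then smallest scale/rotation cell in iteration order); in
the refinement by the exact undilated edge count first (so a rendered
template refits to exactly the same pose), then lowest row/col.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .exceptions import BorderNotFoundError, InsufficientEdgeError
from .io import validate_mask
from .shapes import (
    EyeBorderFit,
    GielisParams,
    curve_extents,
    gielis_template,
    template_for_fit,
)

#: minimum number of raw edge pixels required to attempt recognition
MIN_EDGE_PIXELS = 50


@dataclass
class HoughSearchSpace:
    """Discretized pose-search grid.

    ``row_scale_range``/``col_scale_range`` are (min, max) semi-axis extents
    in pixels (semi-minor along rows, semi-major along columns), sampled with
    ``scale_steps`` points each; ``rotation_range`` is in radians with
    ``rotation_steps`` samples (a single step collapses to the midpoint,
    reproducing a rotation-free search); candidate centers are accumulated on
    a ``center_stride``-pixel grid and refined to 1 px around the peak.
    """

    row_scale_range: tuple[float, float]
    col_scale_range: tuple[float, float]
    scale_steps: int = 12
    rotation_range: tuple[float, float] = (-np.pi / 18.0, np.pi / 18.0)
    rotation_steps: int = 5
    center_stride: int = 2

    def __post_init__(self) -> None:
        for name in ("row_scale_range", "col_scale_range", "rotation_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if min(self.row_scale_range) <= 0 or min(self.col_scale_range) <= 0:
            raise ValueError("scale ranges must be positive")
        if self.scale_steps < 1 or self.rotation_steps < 1:
            raise ValueError("steps must be >= 1")
        if self.center_stride < 1:
            raise ValueError("center_stride must be >= 1")

    def row_scales(self) -> np.ndarray:
        return _grid(*self.row_scale_range, self.scale_steps)

    def col_scales(self) -> np.ndarray:
        return _grid(*self.col_scale_range, self.scale_steps)

    def rotations(self) -> np.ndarray:
        return _grid(*self.rotation_range, self.rotation_steps)


def _grid(lo: float, hi: float, steps: int) -> np.ndarray:
    if steps == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, steps)


def template_offsets(
    p: GielisParams,
    semi_minor: float,
    semi_major: float,
    rotation: float,
    n_points: int = 512,
) -> np.ndarray:
    """Unique integer (row, col) offsets of the rasterized template."""
    row_ext, col_ext = curve_extents(p)
    tpl = gielis_template(p, n_points, semi_minor / row_ext, semi_major / col_ext, rotation)
    return np.unique(np.round(tpl.points).astype(np.int64), axis=0)


def _dilate_edges(edges: np.ndarray) -> np.ndarray:
    return ndi.binary_dilation(edges, structure=np.ones((3, 3), dtype=bool))


def hough_accumulator(
    edges: np.ndarray,
    p: GielisParams,
    space: HoughSearchSpace,
    n_points: int = 512,
) -> np.ndarray:
    """Full vote array, shape (scale_steps, scale_steps, rotation_steps, Hb, Wb).

    Exposed for inspection and oracle cross-checks; ``hough_fit_eye_border``
    computes the same counts cell by cell without materializing the array.
    """
    validate_mask(edges)
    h, w = edges.shape
    stride = space.center_stride
    hb, wb = -(-h // stride), -(-w // stride)
    dil = _dilate_edges(edges)
    pix = np.argwhere(dil)
    rows = space.row_scales()
    cols = space.col_scales()
    rots = space.rotations()
    acc = np.zeros((rows.size, cols.size, rots.size, hb, wb), dtype=np.int64)
    for i, sr in enumerate(rows):
        for j, sc in enumerate(cols):
            for k, rot in enumerate(rots):
                offs = template_offsets(p, sr, sc, rot, n_points)
                acc[i, j, k] = _vote_cell(pix, offs, h, w, stride, hb, wb)
    return acc


def _vote_cell(pix, offs, h, w, stride, hb, wb) -> np.ndarray:
    cand = pix[:, None, :] - offs[None, :, :]
    cr = cand[..., 0].ravel()
    cc = cand[..., 1].ravel()
    ok = (cr >= 0) & (cr < h) & (cc >= 0) & (cc < w)
    flat = (cr[ok] // stride) * wb + (cc[ok] // stride)
    return np.bincount(flat, minlength=hb * wb).reshape(hb, wb)


def _exact_score(dil: np.ndarray, center: tuple[int, int], offs: np.ndarray) -> int:
    """#offsets landing on a dilated-edge pixel when the template sits at center."""
    r = offs[:, 0] + center[0]
    c = offs[:, 1] + center[1]
    ok = (r >= 0) & (r < dil.shape[0]) & (c >= 0) & (c < dil.shape[1])
    return int(dil[r[ok], c[ok]].sum())


def hough_fit_eye_border(
    edges: np.ndarray,
    p: GielisParams,
    space: HoughSearchSpace,
    min_vote_fraction: float = 0.15,
    n_points: int = 512,
) -> EyeBorderFit:
    """Recognize the eye border as the accumulator argmax over the search grid.

    Raises ``InsufficientEdgeError`` below ``MIN_EDGE_PIXELS`` true pixels and
    ``BorderNotFoundError`` when the refined peak's vote fraction falls below
    ``min_vote_fraction``.
    """
    validate_mask(edges)
    n_edges = int(np.count_nonzero(edges))
    if n_edges < MIN_EDGE_PIXELS:
        raise InsufficientEdgeError(
            f"insufficient edge evidence: {n_edges} < {MIN_EDGE_PIXELS} pixels"
        )
    h, w = edges.shape
    stride = space.center_stride
    hb, wb = -(-h // stride), -(-w // stride)
    dil = _dilate_edges(edges)
    pix = np.argwhere(dil)

    best_key = None
    best_cell = None  # (sr, sc, rot, offs)
    for i, sr in enumerate(space.row_scales()):
        for j, sc in enumerate(space.col_scales()):
            for k, rot in enumerate(space.rotations()):
                offs = template_offsets(p, sr, sc, rot, n_points)
                acc = _vote_cell(pix, offs, h, w, stride, hb, wb)
                flat_idx = int(acc.argmax())  # first max: lowest row, then col
                votes = int(acc.ravel()[flat_idx])
                br, bc = divmod(flat_idx, wb)
                key = (-votes, br, bc, i, j, k)
                if best_key is None or key < best_key:
                    best_key = key
                    best_cell = (sr, sc, rot, offs, br, bc)

    sr, sc, rot, offs, br, bc = best_cell
    # refine at 1-px resolution around the winning stride bin; the tolerance
    # band lets the score saturate over adjacent centers, so ties are broken
    # first by the exact (undilated) edge count, then by lowest row/col
    r_lo = max(br * stride - 2, 0)
    r_hi = min(br * stride + stride + 2, h)
    c_lo = max(bc * stride - 2, 0)
    c_hi = min(bc * stride + stride + 2, w)
    best = (-1, -1, 0, 0)
    for r in range(r_lo, r_hi):
        for c in range(c_lo, c_hi):
            s = _exact_score(dil, (r, c), offs)
            if s >= best[0]:
                raw = _exact_score(edges, (r, c), offs)
                if (s, raw) > (best[0], best[1]):
                    best = (s, raw, r, c)
    votes, _, r, c = best
    fraction = votes / offs.shape[0]
    if fraction < min_vote_fraction:
        raise BorderNotFoundError(
            f"no eye border found: best vote fraction {fraction:.3f} "
            f"< {min_vote_fraction}"
        )
    return EyeBorderFit(
        center=(float(r), float(c)),
        semi_major=float(sc),
        semi_minor=float(sr),
        rotation=float(rot),
        votes=votes,
        vote_fraction=float(fraction),
    )


def _fit_points(fit: EyeBorderFit, p: GielisParams, n_points: int) -> np.ndarray:
    tpl = template_for_fit(fit, p, n_points)
    return tpl.points + np.asarray(fit.center)


def render_border(
    fit: EyeBorderFit,
    p: GielisParams,
    shape: tuple[int, int],
    n_points: int = 720,
) -> np.ndarray:
    """1-px-thick closed outline of the fitted shape, clipped to ``shape``."""
    h, w = shape
    pts = np.round(_fit_points(fit, p, n_points)).astype(np.int64)
    out = np.zeros((h, w), dtype=bool)
    for (r0, c0), (r1, c1) in zip(pts, np.roll(pts, -1, axis=0)):
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        out[rr[ok], cc[ok]] = True
    if not out.any():
        warnings.warn("fitted border lies entirely outside the image", stacklevel=2)
    return out


def fill_border(
    fit: EyeBorderFit,
    p: GielisParams,
    shape: tuple[int, int],
    n_points: int = 720,
) -> np.ndarray:
    """Filled interior of the fitted closed curve (outline included)."""
    h, w = shape
    pts = _fit_points(fit, p, n_points)
    rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=(h, w))
    out = np.zeros((h, w), dtype=bool)
    out[rr, cc] = True
    # the polygon rasterization can exclude boundary pixels; union the outline
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out |= render_border(fit, p, (h, w), n_points)
    return out
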