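"""ROI geometry shared by all pipelines.

Polyline handling, band straightening ("linearization" of a segmented line
ROI into a rectangular band), polygon rasterization, and area-fraction
subregions of a cell mask (peripheral / central shells ranked by the
Euclidean distance transform).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage

from .errors import EmptyROIError, InvalidParameterError, InvalidROIError
from .image import DEFAULT_PIXEL_SIZE_UM, IntensityImage

logger = logging.getLogger(__name__)


@dataclass
class PolylineROI:
    """Ordered list of (x, y) pixel coordinates marking a segmentation line.

    ``closed=True`` makes it a polygon (last vertex implicitly connects to
    the first); ``closed=False`` is an open segmented line such as the one
    drawn along the basal cell membrane.
    """

    vertices: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise InvalidROIError(f"polyline needs >= 2 (x, y) vertices, got shape {v.shape}")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise InvalidROIError("consecutive vertices must be distinct")
        self.vertices = v
        if self.arc_length() <= 0:
            raise InvalidROIError("polyline arc length must be > 0")

    def arc_length(self) -> float:
        v = self.vertices
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1).sum()
        if self.closed:
            seg += float(np.linalg.norm(v[-1] - v[0]))
        return float(seg)


@dataclass
class StraightBand:
    """A band of odd width resampled perpendicular to a polyline.

    The polyline maps to ``center_row``; increasing row index points basal.
    ``oob`` flags samples that fell outside the source image (zero-filled).
    """

    values: np.ndarray           # width_px x L
    width_px: int
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    oob: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.width_px % 2 == 0:
            raise InvalidParameterError("band width must be odd")
        if self.values.shape[0] != self.width_px:
            raise ValueError("band height does not match width_px")
        if self.oob is None:
            self.oob = np.zeros_like(self.values, dtype=bool)

    @property
    def center_row(self) -> int:
        return (self.width_px - 1) // 2

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def valid_columns(self, max_oob_fraction: float = 0.5) -> np.ndarray:
        """Boolean mask of columns with <= ``max_oob_fraction`` out-of-bounds samples."""
        return self.oob.mean(axis=0) <= max_oob_fraction


def _resample_polyline(vertices: np.ndarray, step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Resample an open polyline at uniform arc-length spacing.

    Returns (points L x 2, unit normals L x 2).  Normals are the tangent
    rotated so that for a left-to-right horizontal line the normal points to
    increasing y (downward / basal).  Tangents come from central differences
    of the resampled path, which realizes the adjacent-segment-normal mean at
    the original vertices.
    """
    seg = np.diff(vertices, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n_samples = int(round(total)) + 1
    s = np.linspace(0.0, total, n_samples)
    x = np.interp(s, cum, vertices[:, 0])
    y = np.interp(s, cum, vertices[:, 1])
    pts = np.column_stack([x, y])
    tang = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tang /= norms
    # rotate tangent (tx, ty) -> (-ty, tx): for t=(1,0) gives (0,1) = +y (basal)
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    return pts, normals


def straighten_band(
    image: IntensityImage,
    line: PolylineROI,
    width_px: int,
    interpolation: str = "bilinear",
) -> StraightBand:
    """Digitally straighten a band of ``width_px`` pixels centered on a polyline.

    Column ``j`` of the output is the image sampled along the normal to the
    polyline at arc-length sample ``j`` (unit-pixel spacing).  The polyline
    itself maps exactly to the band's center row.  Samples falling outside
    the image are zero-filled and flagged in ``StraightBand.oob``.

    Parameters
    ----------
    interpolation
        ``"bilinear"`` (default) or ``"nearest"``.
    """
    if image.ndim != 2:
        raise InvalidParameterError("straighten_band expects a 2D image")
    if line.closed:
        raise InvalidROIError("straighten_band expects an open polyline")
    if width_px < 3:
        raise InvalidParameterError(f"width_px must be >= 3, got {width_px}")
    if width_px % 2 == 0:
        width_px += 1
        logger.warning("even band width coerced up to %d so a center row exists", width_px)
    if interpolation not in ("bilinear", "nearest"):
        raise InvalidParameterError(f"unknown interpolation {interpolation!r}")

    pts, normals = _resample_polyline(line.vertices)
    half = (width_px - 1) // 2
    offsets = np.arange(-half, half + 1, dtype=float)  # rows 0..width-1 map to -half..+half
    # sample coordinates: (width, L, 2)
    coords = pts[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    xs, ys = coords[..., 0], coords[..., 1]
    h, w = image.shape
    oob = (xs < -0.5) | (xs > w - 0.5) | (ys < -0.5) | (ys > h - 0.5)
    order = 1 if interpolation == "bilinear" else 0
    vals = ndimage.map_coordinates(
        image.values, [ys.ravel(), xs.ravel()], order=order, mode="constant", cval=0.0
    ).reshape(xs.shape)
    vals[oob] = 0.0
    n_oob = int(oob.sum())
    if n_oob:
        logger.info("straighten_band: %d/%d samples out of bounds (zero-filled)", n_oob, oob.size)
    return StraightBand(vals, width_px=width_px, pixel_size_um=image.pixel_size_um, oob=oob)


def polygon_mask(image_shape: tuple[int, int], roi: PolylineROI) -> np.ndarray:
    """Rasterize a closed polygon ROI onto a pixel grid.

    A pixel belongs to the mask when its center lies inside the polygon under
    the even-odd rule; pixels whose centers fall exactly on the boundary are
    included.
    """
    if not roi.closed:
        raise InvalidROIError("polygon_mask requires a closed ROI")
    v = roi.vertices
    if v.shape[0] < 3:
        raise InvalidROIError("polygon needs >= 3 vertices")
    x, y = v[:, 0], v[:, 1]
    area2 = np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area2 == 0:
        raise InvalidROIError("degenerate polygon with zero area")
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    poly = shapely.Polygon(v)
    # intersects = interior or boundary, so pixel centers on an edge are included
    inside = shapely.intersects_xy(poly, xx.ravel(), yy.ravel())
    return inside.reshape(h, w)


def area_fraction_region(mask: np.ndarray, fraction: float, side: str) -> np.ndarray:
    """Peripheral or central subregion of a mask by area fraction.

    Pixels are ranked by their Euclidean distance to the mask boundary
    (distance transform).  ``side="peripheral"`` selects the
    ``round(fraction * area)`` lowest-distance pixels (a shell hugging the
    boundary); ``side="central"`` the same number of highest-distance pixels.
    A single ascending (distance, raster-order) sort is used for both sides,
    so the output size is exactly ``round(fraction * area)`` and peripheral
    and central regions are disjoint whenever their rounded sizes sum to at
    most the mask area (rounding can force a one-pixel overlap exactly at
    complementary fractions).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyROIError("mask is empty")
    if not 0 < fraction <= 1:
        raise InvalidParameterError(f"fraction must be in (0, 1], got {fraction}")
    if side not in ("peripheral", "central"):
        raise InvalidParameterError(f"side must be 'peripheral' or 'central', got {side!r}")

    area = int(mask.sum())
    k = int(round(fraction * area))
    if k == 0:
        return np.zeros_like(mask)
    dist = ndimage.distance_transform_edt(mask)
    flat_idx = np.flatnonzero(mask.ravel())
    order = np.lexsort((flat_idx, dist.ravel()[flat_idx]))  # distance, then raster order
    chosen = flat_idx[order[:k]] if side == "peripheral" else flat_idx[order[area - k:]]
    out = np.zeros(mask.size, dtype=bool)
    out[chosen] = True
    return out.reshape(mask.shape)
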