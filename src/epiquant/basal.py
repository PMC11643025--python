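"""Apico-basal intensity binning and the basal mRNA fraction.

The segmented epithelial layer is divided into ``n_bins`` equal-length bins
along the apico-basal axis (bin 0 is basal-most), fluorescence intensity is
summed per bin after a uniform background subtraction, and the basal mRNA
fraction is the summed fraction in the basal-most bins covering a given
extent of the layer (default: bottom 30%, i.e. 3 of 10 bins).

Binning is per-column along the local layer thickness: each column's in-layer
extent is split into ``n_bins`` equal sub-intervals, and every pixel's unit
row interval ``[y, y+1)`` contributes to bins in proportion to overlap.  For
a rectangular layer of uniform thickness this reduces to global equal bins;
for curved layers it follows the local basal and apical edges.  Tubular
epithelia are first linearized with :func:`epiquant.geometry.straighten_band`
and then binned identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, UndefinedMetricError
from .geometry import StraightBand
from .image import IntensityImage

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 10
DEFAULT_BASAL_EXTENT = 0.30


@dataclass
class LayerProfile:
    """Apico-basal intensity distribution of one segmented layer."""

    bin_fractions: np.ndarray    # length n_bins, sums to 1; index 0 = basal-most
    n_bins: int
    background_level: float = 0.0

    def __post_init__(self) -> None:
        self.bin_fractions = np.asarray(self.bin_fractions, dtype=float)
        if self.bin_fractions.shape != (self.n_bins,):
            raise ValueError("bin_fractions length must equal n_bins")

    def basal_fraction(self, basal_extent: float = DEFAULT_BASAL_EXTENT) -> float:
        return basal_fraction(self, basal_extent)


def subtract_background(image: IntensityImage, level: float) -> IntensityImage:
    """Uniform background subtraction, clipped at zero."""
    if not np.isfinite(level):
        raise InvalidParameterError("background level must be finite")
    if level < 0:
        raise InvalidParameterError(f"background level must be >= 0, got {level}")
    return IntensityImage(
        np.maximum(image.values - level, 0.0),
        pixel_size_um=image.pixel_size_um,
        z_step_um=image.z_step_um,
    )


def estimate_background(image: IntensityImage, layer_mask: np.ndarray) -> float:
    """Default background estimate: median intensity outside the layer mask."""
    outside = ~np.asarray(layer_mask, dtype=bool)
    if not outside.any():
        return 0.0
    return float(np.median(image.values[outside]))


def _per_column_bin_sums(values: np.ndarray, mask: np.ndarray, n_bins: int, basal: str) -> np.ndarray:
    """Accumulate per-bin intensity sums over all columns of a masked layer.

    Each column's extent runs from the basal edge to the apical edge; a pixel
    row interval [y, y+1) is distributed over the bins it overlaps.
    """
    h, w = values.shape
    sums = np.zeros(n_bins)
    thin_columns = 0
    n_cols = 0
    for c in range(w):
        rows = np.flatnonzero(mask[:, c])
        if rows.size == 0:
            continue
        n_cols += 1
        y0, y1 = rows[0], rows[-1] + 1          # layer occupies [y0, y1)
        thickness = y1 - y0
        if thickness < n_bins:
            thin_columns += 1
        edges = np.linspace(y0, y1, n_bins + 1)  # apical -> basal in row order
        v = values[rows, c]
        # cumulative in-layer intensity up to coordinate t: each pixel row y
        # occupies [y, y+1) and contributes v * clip(t - y, 0, 1)
        cum = (v[None, :] * np.clip(edges[:, None] - rows[None, :], 0.0, 1.0)).sum(axis=1)
        sums += np.diff(cum)
    if n_cols and thin_columns > 0.5 * n_cols:
        logger.warning(
            "layer thinner than %d px in %d/%d columns; fractional per-column binning in effect",
            n_bins, thin_columns, n_cols,
        )
    # row order is apical->basal when basal edge is 'bottom' (larger y)
    if basal == "bottom":
        sums = sums[::-1]
    elif basal != "top":
        raise InvalidParameterError(f"basal edge must be 'bottom' or 'top', got {basal!r}")
    return sums


def bin_layer(
    layer: StraightBand | IntensityImage | np.ndarray,
    mask: np.ndarray | None = None,
    n_bins: int = DEFAULT_N_BINS,
    basal: str = "bottom",
    background_level: float = 0.0,
) -> LayerProfile:
    """Bin a segmented layer into equal apico-basal bins and return intensity fractions.

    Parameters
    ----------
    layer
        A :class:`StraightBand` (linearized tubular epithelium; the in-bounds
        band region is the layer), an :class:`IntensityImage`, or a bare 2D
        array.  For images/arrays a boolean ``mask`` selects in-layer pixels;
        with no mask the whole grid is the layer.
    basal
        Which edge of each column is basal-most: ``"bottom"`` (larger row
        index, the convention after straightening) or ``"top"``.
    background_level
        Uniform background subtracted (clipped at zero) before binning.
    """
    if n_bins < 2:
        raise InvalidParameterError(f"n_bins must be >= 2, got {n_bins}")
    if isinstance(layer, StraightBand):
        values = layer.values
        mask = ~layer.oob
        mask = mask & layer.valid_columns()[None, :]
    else:
        values = layer.values if isinstance(layer, IntensityImage) else np.asarray(layer, dtype=float)
        if values.ndim != 2:
            raise InvalidParameterError("bin_layer expects a 2D layer")
        if mask is None:
            mask = np.ones_like(values, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
    if background_level:
        values = np.maximum(values - background_level, 0.0)
    sums = _per_column_bin_sums(values, mask, n_bins, basal)
    total = sums.sum()
    if total <= 0:
        raise UndefinedMetricError("total post-subtraction intensity is zero; profile undefined")
    return LayerProfile(sums / total, n_bins=n_bins, background_level=background_level)


def basal_fraction(profile: LayerProfile, basal_extent: float = DEFAULT_BASAL_EXTENT) -> float:
    """Fraction of layer intensity within ``basal_extent`` of the basal edge.

    ``basal_extent * n_bins`` must be an integer number of bins (default
    0.30 x 10 = 3 bins); partial bins are not interpolated.
    """
    n_basal = basal_extent * profile.n_bins
    if abs(n_basal - round(n_basal)) > 1e-9:
        raise InvalidParameterError(
            f"basal_extent {basal_extent} does not cover an integer number of {profile.n_bins} bins"
        )
    k = int(round(n_basal))
    if not 1 <= k <= profile.n_bins:
        raise InvalidParameterError(f"basal extent covers {k} bins, outside [1, {profile.n_bins}]")
    return float(profile.bin_fractions[:k].sum())
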