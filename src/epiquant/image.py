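"""Intensity-image container with physical pixel metadata.

Coordinate convention used throughout the package: 0-based pixel indices,
pixel centers at integer coordinates, ``x`` = column, ``y`` = row, and ``y``
increasing downward.  After band straightening, "basal" is the direction of
increasing row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default in-plane pixel edge length in micrometres (100x spinning-disk
#: confocal acquisition; a 120-pixel band corresponds to 7.8 um).
DEFAULT_PIXEL_SIZE_UM = 0.065


@dataclass
class IntensityImage:
    """A 2D (rows x cols) or 3D (planes x rows x cols) fluorescence channel.

    Parameters
    ----------
    values
        Non-negative finite intensity grid in arbitrary units.
    pixel_size_um
        Physical edge length of one pixel, isotropic in-plane, in um.
    z_step_um
        Axial step between planes in um; only meaningful for 3D stacks.
    """

    values: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"image must be 2D or 3D, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise ValueError(f"every axis must have length >= 1, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("image contains negative intensities")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.values.ndim == 3 and self.z_step_um is not None and not self.z_step_um > 0:
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel (3D stacks only)."""
        if self.values.ndim != 3:
            raise ValueError("voxel volume is defined for 3D stacks only")
        if self.z_step_um is None:
            raise ValueError("z_step_um is not set on this stack")
        return self.pixel_size_um**2 * self.z_step_um


def max_project(stack: IntensityImage, z_start: int = 0, z_count: int | None = None) -> IntensityImage:
    """Maximum-intensity projection over a contiguous run of optical sections.

    Emulates the pre-analysis projection of ~1 um of optical sections: with a
    known ``z_step_um``, ``z_count`` planes cover ``z_count * z_step_um`` um.
    """
    if stack.ndim != 3:
        raise ValueError("max_project expects a 3D stack")
    n = stack.shape[0]
    if not 0 <= z_start < n:
        raise ValueError(f"z_start {z_start} outside stack of {n} planes")
    stop = n if z_count is None else min(n, z_start + z_count)
    proj = stack.values[z_start:stop].max(axis=0)
    return IntensityImage(proj, pixel_size_um=stack.pixel_size_um)
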