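"""Standard-format I/O: TIFF images, ROI files (JSON/CSV), YAML configuration."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import EpiquantError, InvalidROIError
from .geometry import PolylineROI
from .image import DEFAULT_PIXEL_SIZE_UM, IntensityImage


class FormatError(EpiquantError):
    """A file could not be read in its declared format."""


def read_image(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    z_step_um: float | None = None,
    channel: int | None = None,
    channel_axis: int = 0,
) -> IntensityImage:
    """Read a single- or multi-page TIFF into an :class:`IntensityImage`.

    Multi-page stacks load as 3D with z from page order.  For multi-channel
    images pass ``channel`` (and ``channel_axis`` if channels are not the
    leading axis) to select one channel.
    """
    path = Path(path)
    try:
        values = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    values = np.asarray(values)
    if channel is not None:
        if values.ndim < 3:
            raise FormatError(f"{path}: channel selection requested on a 2D image")
        values = np.take(values, channel, axis=channel_axis)
    if values.ndim not in (2, 3):
        raise FormatError(
            f"{path}: expected 2D or 3D data (got ndim={values.ndim}); "
            "multi-channel images require a channel selector"
        )
    return IntensityImage(values.astype(float), pixel_size_um=pixel_size_um, z_step_um=z_step_um)


def write_image(path: str | Path, image: IntensityImage, dtype=None) -> None:
    """Write an image or stack as TIFF; integer dtypes round-trip bit-exactly."""
    values = image.values
    if dtype is not None:
        values = values.astype(dtype)
    tifffile.imwrite(Path(path), values, photometric="minisblack")


def read_roi(path: str | Path) -> PolylineROI:
    """Read an ROI: JSON ``{"vertices": [[x, y], ...], "closed": bool}`` or two-column x,y CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            data = json.loads(path.read_text())
            return PolylineROI(np.asarray(data["vertices"], dtype=float), closed=bool(data.get("closed", False)))
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise FormatError(f"cannot parse ROI JSON {path}: {exc}") from exc
    if path.suffix.lower() == ".csv":
        try:
            with path.open() as fh:
                rows = list(csv.reader(fh))
            header = [c.strip().lower() for c in rows[0]]
            if header[:2] != ["x", "y"]:
                raise InvalidROIError(f"{path}: CSV ROI needs an 'x,y' header row")
            verts = np.asarray([[float(r[0]), float(r[1])] for r in rows[1:]])
            return PolylineROI(verts, closed=False)
        except (ValueError, IndexError) as exc:
            raise FormatError(f"cannot parse ROI CSV {path}: {exc}") from exc
    raise FormatError(f"unsupported ROI format: {path.suffix}")


def write_roi(path: str | Path, roi: PolylineROI) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"vertices": roi.vertices.tolist(), "closed": roi.closed}))
    elif path.suffix.lower() == ".csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x", "y"])
            w.writerows(roi.vertices.tolist())
    else:
        raise FormatError(f"unsupported ROI format: {path.suffix}")


def read_yaml(path: str | Path) -> dict:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse YAML {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path}: YAML config must be a mapping")
    return data


def write_ground_truth(path: str | Path, truth) -> None:
    """JSON sidecar of a GroundTruth record (arrays as lists; voxel labels omitted)."""
    rec = {
        "seed": truth.seed,
        "params": truth.params,
        "true_basal_fraction": truth.true_basal_fraction,
        "target_basal_fraction": truth.target_basal_fraction,
        "true_mean_abs_displacement_px": truth.true_mean_abs_displacement_px,
        "true_cortical_weight": truth.true_cortical_weight,
        "expected_cortical_ratio": truth.expected_cortical_ratio,
        "true_fiber_volumes_um3": truth.true_fiber_volumes_um3,
        "true_blob_volumes_um3": truth.true_blob_volumes_um3,
    }
    if truth.true_displacement_px is not None:
        rec["true_displacement_px"] = np.asarray(truth.true_displacement_px).tolist()
    Path(path).write_text(json.dumps({k: v for k, v in rec.items() if v is not None}, indent=1))
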