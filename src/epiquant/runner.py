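"""Run configuration and the manifest runner.

A run is described by a YAML config with analysis parameters (all defaults
as used in the source analyses) plus a manifest: a list of entries, each an
(image, ROI/mask) pair with a metric name and condition/animal/ROI labels.
The runner executes the requested metric per entry and emits one tidy row
per (entry, metric): ``condition, animal_id, roi_id, metric, value``.

Fiber-volume entries within one condition group must share the intensity
threshold — thresholding must be equal between samples of a comparison —
and the runner enforces this before any computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import version, PackageNotFoundError
from pathlib import Path
from typing import Any

import pandas as pd

from . import basal, cells, dej, fibers
from .errors import EpiquantError
from .geometry import polygon_mask
from .image import DEFAULT_PIXEL_SIZE_UM
from .io import read_image, read_roi, read_yaml

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


class ConfigError(EpiquantError):
    """The run configuration or manifest violates the schema."""


@dataclass
class RunConfig:
    """Analysis parameters and input manifest for one batch run."""

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float | None = None
    band_width_px: int = 121
    n_bins: int = 10
    basal_extent: float = 0.30
    noise_threshold_px: float = 3.0
    peripheral_frac: float = 0.15
    central_frac: float = 0.65
    fiber_threshold: float | None = None
    min_volume_um3: float = fibers.DEFAULT_MIN_VOLUME_UM3
    max_sphericity_for_small: float = fibers.DEFAULT_MAX_SPHERICITY_FOR_SMALL
    background: float | str = 0.0   # numeric level or "auto"
    seed: int | None = None
    manifest: list[dict[str, Any]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = read_yaml(path)
        schema = data.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if schema != CONFIG_SCHEMA_VERSION:
            raise ConfigError(f"unsupported config schema_version {schema}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


_KNOWN_METRICS = ("basal_fraction", "dej_var", "pdi", "cortical_ratio", "fiber_volume")


def _validate_manifest(config: RunConfig) -> None:
    thresholds_by_condition: dict[str, set] = {}
    for i, entry in enumerate(config.manifest):
        if "metric" not in entry or "image" not in entry:
            raise ConfigError(f"manifest entry {i}: 'metric' and 'image' are required")
        if entry["metric"] not in _KNOWN_METRICS:
            raise ConfigError(f"manifest entry {i}: unknown metric {entry['metric']!r}")
        if entry["metric"] in ("basal_fraction", "dej_var", "pdi", "cortical_ratio") and "roi" not in entry:
            raise ConfigError(f"manifest entry {i}: metric {entry['metric']!r} requires 'roi'")
        if entry["metric"] == "fiber_volume":
            t = entry.get("threshold", config.fiber_threshold)
            if t is None:
                raise ConfigError(f"manifest entry {i}: fiber_volume requires a threshold")
            thresholds_by_condition.setdefault(entry.get("condition", ""), set()).add(float(t))
    for cond, ts in thresholds_by_condition.items():
        if len(ts) > 1:
            raise ConfigError(
                f"condition {cond!r} mixes fiber thresholds {sorted(ts)}; "
                "thresholding must be equal between samples of one comparison"
            )


def _run_entry(entry: dict[str, Any], config: RunConfig) -> float:
    metric = entry["metric"]
    if metric == "fiber_volume":
        stack = read_image(entry["image"], config.pixel_size_um, config.z_step_um)
        threshold = float(entry.get("threshold", config.fiber_threshold))
        _, total = fibers.fiber_pipeline(
            stack, threshold, config.min_volume_um3, config.max_sphericity_for_small
        )
        return total

    image = read_image(entry["image"], config.pixel_size_um)
    roi = read_roi(entry["roi"])
    if metric == "dej_var":
        res = dej.dej_variation_pipeline(
            image, roi, config.band_width_px, config.noise_threshold_px
        )
        return res.dej_var_um
    mask = polygon_mask(image.shape, roi)
    if metric == "basal_fraction":
        level = entry.get("background", config.background)
        if level == "auto":
            level = basal.estimate_background(image, mask)
        profile = basal.bin_layer(image, mask, config.n_bins, background_level=float(level))
        return basal.basal_fraction(profile, config.basal_extent)
    cell = cells.CellROI.from_image(image, mask)
    if metric == "pdi":
        return cells.pdi(cell)
    return cells.cortical_ratio(cell, config.peripheral_frac, config.central_frac)


def run_manifest(config: RunConfig) -> pd.DataFrame:
    """Execute every manifest entry; one tidy row per (entry, metric).

    Partial failures are reported per row (``error`` column) and the run
    continues.  The full parameter set and package version are logged so a
    run is reproducible from its log.
    """
    _validate_manifest(config)
    try:
        pkg_version = version("epiquant")
    except PackageNotFoundError:
        pkg_version = "unknown"
    params = {k: v for k, v in asdict(config).items() if k != "manifest"}
    logger.info("epiquant %s run config: %s", pkg_version, params)
    if not config.manifest:
        logger.warning("manifest is empty; no work to do")
    rows = []
    for entry in config.manifest:
        row = {
            "condition": entry.get("condition", ""),
            "animal_id": entry.get("animal_id", ""),
            "roi_id": entry.get("roi_id", ""),
            "metric": entry["metric"],
            "value": float("nan"),
            "error": "",
        }
        try:
            row["value"] = _run_entry(entry, config)
        except Exception as exc:
            logger.error("manifest entry %s failed: %s", entry, exc)
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=["condition", "animal_id", "roi_id", "metric", "value", "error"])
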