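"""Readers, writers, configuration and the end-to-end pipeline.

File conventions
----------------
Images and label masks travel as TIFF with a YAML sidecar (same stem,
``.yaml``) holding the pixel size and the chip/day/group/location metadata
— the pixel size is never silently defaulted: it must come from the
sidecar or an explicit override.  Tables are plain CSV; fit reports and
the run manifest are JSON.  Every pipeline run serializes its full
configuration into the output directory so results are reproducible from
the manifest plus the inputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .exceptions import MeasurementError, SocmetricsError
from .lumen import ChannelImage, WallCalibration, WidthMeasurement, measure_image
from .morphometry import (
    LabelMask,
    filter_by_area,
    remove_border_labels,
    shape_descriptors,
    shapes_to_frame,
    summarize_morphology,
)
from .stats import ci_divergence_day, fit_lmm, kruskal_dunn, validate_cohort

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "write_channel_image",
    "read_channel_image",
    "write_label_mask",
    "read_label_mask",
    "read_cohort",
    "write_cohort",
    "profiles_frame",
    "chips_frame",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Image / mask round-trip


def write_channel_image(image: ChannelImage, stem: Path) -> Path:
    """Write an image pair as multi-page TIFF + YAML sidecar.

    Page order follows the ``channels`` list in the sidecar.
    """
    stem = Path(stem)
    channels = ["fluorescence"]
    pages = [np.asarray(image.fluorescence, dtype=np.float32)]
    if image.brightfield is not None:
        channels.append("brightfield")
        pages.append(np.asarray(image.brightfield, dtype=np.float32))
    tif = stem.with_suffix(".tif")
    tifffile.imwrite(tif, np.stack(pages))
    meta = {
        "pixel_size_um": float(image.pixel_size_um),
        "chip_id": image.chip_id,
        "day": int(image.day),
        "group": image.group,
        "channels": channels,
    }
    stem.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return tif


def _read_sidecar(tif_path: Path) -> dict:
    sidecar = Path(tif_path).with_suffix(".yaml")
    if not sidecar.exists():
        return {}
    return yaml.safe_load(sidecar.read_text()) or {}


def read_channel_image(
    tif_path: Path, pixel_size_override: Optional[float] = None
) -> ChannelImage:
    """Load a channel image from TIFF + sidecar.

    Raises
    ------
    SocmetricsError
        If the pixel size is neither in the sidecar nor overridden, or if
        a named channel page is missing.
    """
    tif_path = Path(tif_path)
    data = tifffile.imread(tif_path)
    meta = _read_sidecar(tif_path)
    pixel_size = pixel_size_override or meta.get("pixel_size_um")
    if not pixel_size:
        raise SocmetricsError(
            f"{tif_path}: pixel size missing from sidecar and no override given"
        )
    if data.ndim == 2:
        data = data[None]
    channels = meta.get("channels") or ["fluorescence", "brightfield"][: data.shape[0]]
    if len(channels) != data.shape[0]:
        raise SocmetricsError(
            f"{tif_path}: {data.shape[0]} pages but {len(channels)} channel roles"
        )
    by_role = {role: data[i] for i, role in enumerate(channels)}
    if "fluorescence" not in by_role:
        raise SocmetricsError(f"{tif_path}: no page with the 'fluorescence' role")
    return ChannelImage(
        fluorescence=by_role["fluorescence"],
        brightfield=by_role.get("brightfield"),
        pixel_size_um=float(pixel_size),
        chip_id=str(meta.get("chip_id", tif_path.stem)),
        day=int(meta.get("day", 0)),
        group=str(meta.get("group", "")),
    )


def write_label_mask(mask: LabelMask, stem: Path) -> Path:
    stem = Path(stem)
    tif = stem.with_suffix(".tif")
    tifffile.imwrite(tif, mask.labels.astype(np.int32))
    meta = {
        "pixel_size_um": float(mask.pixel_size_um),
        "chip_id": mask.chip_id,
        "day": int(mask.day),
        "location": mask.location,
    }
    stem.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return tif


def read_label_mask(
    tif_path: Path, pixel_size_override: Optional[float] = None
) -> LabelMask:
    tif_path = Path(tif_path)
    labels = tifffile.imread(tif_path)
    meta = _read_sidecar(tif_path)
    pixel_size = pixel_size_override or meta.get("pixel_size_um")
    if not pixel_size:
        raise SocmetricsError(
            f"{tif_path}: pixel size missing from sidecar and no override given"
        )
    return LabelMask(
        labels=np.asarray(labels).astype(np.int32),
        pixel_size_um=float(pixel_size),
        location=str(meta.get("location", "floor")),
        day=int(meta.get("day", 0)),
        chip_id=str(meta.get("chip_id", tif_path.stem)),
    )


def read_cohort(path: Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort(cohort: pd.DataFrame, path: Path) -> Path:
    validate_cohort(cohort)
    cohort.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Measurement tables


def profiles_frame(measurements: Sequence[WidthMeasurement]) -> pd.DataFrame:
    """Per-profile audit table over a set of measured images."""
    rows = []
    for m in measurements:
        for p in m.profiles:
            rows.append(
                {
                    "chip_id": m.chip_id,
                    "day": m.day,
                    "group": m.group,
                    "row_um": p.row_um,
                    "left_px": p.left_px,
                    "right_px": p.right_px,
                    "width_um": p.width_um,
                    "valid": p.valid,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chip_id", "day", "group", "row_um", "left_px", "right_px",
            "width_um", "valid",
        ],
    )


def chips_frame(measurements: Sequence[WidthMeasurement]) -> pd.DataFrame:
    """Per-chip summary table (one row per measured image)."""
    rows = [
        {
            "chip_id": m.chip_id,
            "day": m.day,
            "group": m.group,
            "mean_width_um": m.mean_width_um,
            "n_valid_profiles": m.n_valid_profiles,
            "threshold": m.threshold,
        }
        for m in measurements
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chip_id", "day", "group", "mean_width_um", "n_valid_profiles", "threshold",
        ],
    )


# ---------------------------------------------------------------------------
# Pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of an end-to-end run; library defaults equal CLI defaults."""

    images_dir: Optional[str] = None
    masks_dir: Optional[str] = None
    cohort_csv: Optional[str] = None
    out_dir: str = "socmetrics-out"
    # lumen stage
    spacing_um: float = 25.0
    margin_um: float = 100.0
    correction_factor: float = 1.0
    min_run_px: int = 3
    wall_x: Optional[int] = None
    pixel_size_override: Optional[float] = None
    # morphometry stage
    min_area_um2: float = 200.0
    # stats stage
    ci_level: float = 0.95
    adjustment: str = "bonferroni"
    kw_descriptors: tuple[str, ...] = ("area_um2", "aspect_ratio", "feret_angle_deg")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_um <= 0 or self.margin_um < 0:
            raise ValueError("spacing_um must be > 0 and margin_um >= 0")
        if self.correction_factor <= 0:
            raise ValueError("correction_factor must be > 0")
        if self.min_run_px < 1:
            raise ValueError("min_run_px must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "kw_descriptors" in data:
            data["kw_descriptors"] = tuple(data["kw_descriptors"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kw_descriptors"] = list(d["kw_descriptors"])
        return d


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    version: str
    input_checksums: dict[str, str]
    record_counts: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def write(self, path: Path) -> Path:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                       default=_json_default)
        )
        return Path(path)


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run measure-width → morphometry → stats over the configured inputs.

    Stages whose inputs are not configured are skipped.  If no cohort CSV
    is given but images were measured, the per-chip means become the
    cohort.  Any stage failure aborts with the offending input named;
    per-image warnings are recorded in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    counts: dict[str, int] = {}
    notes: list[str] = []

    calibration = (
        WallCalibration(wall_left_x=config.wall_x, source="manual")
        if config.wall_x is not None
        else None
    )

    cohort: Optional[pd.DataFrame] = None
    if config.images_dir is not None:
        image_paths = sorted(Path(config.images_dir).glob("*.tif"))
        measurements = []
        for p in image_paths:
            checksums[str(p)] = _sha256(p)
            image = read_channel_image(p, config.pixel_size_override)
            try:
                measurements.append(
                    measure_image(
                        image,
                        spacing_um=config.spacing_um,
                        margin_um=config.margin_um,
                        correction_factor=config.correction_factor,
                        min_run_px=config.min_run_px,
                        calibration=calibration,
                    )
                )
            except MeasurementError as exc:
                raise MeasurementError(f"measure-width failed on {p}: {exc}") from exc
            invalid = measurements[-1].n_invalid_profiles
            if invalid:
                notes.append(f"{p.name}: {invalid} invalid profiles")
        profiles_frame(measurements).to_csv(out / "profiles.csv", index=False)
        chips = chips_frame(measurements)
        chips.to_csv(out / "chip_widths.csv", index=False)
        counts["images"] = len(image_paths)
        counts["chips_measured"] = len(chips)
        if config.cohort_csv is None and not chips.empty:
            cohort = chips.rename(columns={"mean_width_um": "width_um"})[
                ["chip_id", "group", "day", "width_um"]
            ]

    if config.masks_dir is not None:
        mask_paths = sorted(Path(config.masks_dir).glob("*.tif"))
        cell_frames = []
        for p in mask_paths:
            checksums[str(p)] = _sha256(p)
            mask = read_label_mask(p, config.pixel_size_override)
            interior = remove_border_labels(mask)
            shapes = filter_by_area(shape_descriptors(interior), config.min_area_um2)
            cell_frames.append(shapes_to_frame(shapes, mask))
        cells = (
            pd.concat(cell_frames, ignore_index=True) if cell_frames else shapes_to_frame([])
        )
        cells.to_csv(out / "cells.csv", index=False)
        counts["masks"] = len(mask_paths)
        counts["cells"] = len(cells)
        if not cells.empty:
            summarize_morphology(cells).to_csv(out / "morphology_summary.csv", index=False)
            kw_rows = []
            for desc in config.kw_descriptors:
                samples = {
                    f"day{d}-{loc}": grp[desc].to_numpy()
                    for (d, loc), grp in cells.groupby(["day", "location"])
                }
                if len(samples) < 2:
                    notes.append(f"kw skipped for {desc}: fewer than 2 groups")
                    continue
                res = kruskal_dunn(samples, adjustment=config.adjustment)
                pw = res.pairwise.copy()
                pw.insert(0, "descriptor", desc)
                pw.insert(1, "H", res.h_statistic)
                pw.insert(2, "p_global", res.p_value)
                kw_rows.append(pw)
            if kw_rows:
                pd.concat(kw_rows, ignore_index=True).to_csv(
                    out / "kw_dunn.csv", index=False
                )

    if config.cohort_csv is not None:
        checksums[str(config.cohort_csv)] = _sha256(Path(config.cohort_csv))
        cohort = read_cohort(Path(config.cohort_csv))
    if cohort is not None:
        validate_cohort(cohort)
        counts["cohort_rows"] = len(cohort)
        fit = fit_lmm(cohort, ci_level=config.ci_level)
        fit.predictions.to_csv(out / "lmm_predictions.csv", index=False)
        report = {
            "method": fit.method,
            "converged": fit.converged,
            "n_iter": fit.n_iter,
            "ci_level": fit.ci_level,
            "days": list(fit.days),
            "groups": list(fit.groups),
            "covariance": fit.covariance.to_numpy().tolist(),
            "predictions": fit.predictions.to_dict(orient="records"),
        }
        if len(fit.groups) == 2:
            div = ci_divergence_day(fit)
            report["first_divergence_day"] = div.first_divergence_day
            report["overlap_by_day"] = {
                str(k): bool(v) for k, v in div.overlap_by_day.items()
            }
        else:
            notes.append("divergence skipped: cohort does not have exactly 2 groups")
        (out / "lmm_fit.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_json_default)
        )

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        input_checksums=checksums,
        record_counts=counts,
        warnings=notes,
    )
    manifest.write(out / "manifest.json")
    return manifest
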