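"""Projected endothelial lumen width from fluorescence images.

The lumen formed in the bottom channel of the chip is imaged top-down in
the red-fluorescence channel.  Its *projected width* is measured by taking
evenly spaced intensity profiles across the channel, thresholding each
profile with a (correction-factor-scaled) Otsu threshold computed once per
image, and reporting the distance between the outermost supra-threshold
runs in micrometres.  The per-chip value is the mean over all valid
profiles of the image.

Conventions
-----------
* The channel runs along image *rows* (axis 0); a profile is one pixel row,
  i.e. a cross-section of the channel along image columns.  Images acquired
  rotated are handled through ``WallCalibration.channel_axis``.
* Coordinates are 0-based.  Edge indices are inclusive: a band occupying
  columns ``l..r`` has edges ``(l, r)`` and projected width
  ``(r - l) * pixel_size``.
* Edge localization is at pixel resolution; the limited pixel resolution is
  an acknowledged property of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .exceptions import (
    CalibrationError,
    DegenerateHistogramError,
    MeasurementError,
    NoProfilesError,
)

__all__ = [
    "ChannelImage",
    "WallCalibration",
    "WidthProfile",
    "WidthMeasurement",
    "otsu_threshold",
    "corrected_threshold",
    "extract_profiles",
    "detect_lumen_edges",
    "projected_width",
    "measure_image",
    "detect_wall",
]


@dataclass(frozen=True)
class ChannelImage:
    """A calibrated 2D image pair (brightfield + fluorescence) with metadata.

    Parameters
    ----------
    fluorescence
        2D intensity raster of the fluorescence (e.g. RFP) channel.
    brightfield
        Optional 2D intensity raster of the brightfield channel, used only
        for wall calibration.  Must share the fluorescence raster's shape.
    pixel_size_um
        Physical pixel size in µm/px, > 0.
    chip_id, day, group
        Experimental metadata carried through to the output tables.
    """

    fluorescence: np.ndarray
    pixel_size_um: float
    brightfield: Optional[np.ndarray] = None
    chip_id: str = "chip"
    day: int = 0
    group: str = ""

    def __post_init__(self) -> None:
        fluo = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "fluorescence", fluo)
        if fluo.ndim != 2:
            raise ValueError("fluorescence raster must be 2D")
        if self.brightfield is not None:
            bf = np.asarray(self.brightfield, dtype=float)
            object.__setattr__(self, "brightfield", bf)
            if bf.shape != fluo.shape:
                raise ValueError("brightfield and fluorescence shapes differ")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class WallCalibration:
    """Position of the leftmost channel wall and channel orientation.

    ``source`` records whether the wall was selected manually (the faithful
    mode of the original protocol) or proposed automatically from the
    brightfield image.
    """

    wall_left_x: int
    channel_axis: int = 0
    source: str = "manual"

    def __post_init__(self) -> None:
        if self.channel_axis not in (0, 1):
            raise ValueError("channel_axis must be 0 or 1")
        if self.wall_left_x < 0:
            raise ValueError("wall_left_x must be non-negative")
        if self.source not in ("manual", "automatic"):
            raise ValueError("source must be 'manual' or 'automatic'")


@dataclass(frozen=True)
class WidthProfile:
    """One cross-channel intensity profile and its detected lumen edges."""

    row_um: float
    row_px: int
    left_px: Optional[int]
    right_px: Optional[int]
    width_um: Optional[float]
    valid: bool


@dataclass(frozen=True)
class WidthMeasurement:
    """Per-image audit record of the projected-width measurement."""

    profiles: tuple[WidthProfile, ...]
    threshold: float
    correction_factor: float
    mean_width_um: float
    n_valid_profiles: int
    chip_id: str = "chip"
    day: int = 0
    group: str = ""

    @property
    def n_invalid_profiles(self) -> int:
        return len(self.profiles) - self.n_valid_profiles


def otsu_threshold(counts: Sequence[float], bin_centers: Sequence[float] | None = None) -> float:
    """Otsu threshold of an intensity histogram.

    Returns the bin center maximizing the between-class variance of the
    two-class split.  Pixels strictly above the returned value are treated
    as foreground by the edge detector.

    Parameters
    ----------
    counts
        Histogram counts per bin.
    bin_centers
        Bin center values; defaults to ``0..len(counts)-1``.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two bins are occupied (constant image).
    """
    counts = np.asarray(counts, dtype=float)
    if bin_centers is None:
        bin_centers = np.arange(counts.size, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    if counts.ndim != 1 or counts.size != bin_centers.size:
        raise ValueError("counts and bin_centers must be 1D of equal length")
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than two occupied bins; Otsu threshold undefined"
        )
    return float(threshold_otsu(hist=(counts, bin_centers)))


def corrected_threshold(
    raster: np.ndarray, correction_factor: float = 1.0, nbins: int = 256
) -> float:
    """Image Otsu threshold scaled by an empirical correction factor.

    The threshold is computed once on the full fluorescence raster (256-bin
    histogram over the observed intensity range) and then multiplied by
    ``correction_factor``.

    Raises
    ------
    DegenerateHistogramError
        If the raster is constant.
    ValueError
        If ``correction_factor`` is not positive.
    """
    if not correction_factor > 0:
        raise ValueError("correction_factor must be > 0")
    raster = np.asarray(raster, dtype=float)
    if raster.size == 0 or np.min(raster) == np.max(raster):
        raise DegenerateHistogramError("constant raster; Otsu threshold undefined")
    counts, edges = np.histogram(raster.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return otsu_threshold(counts, centers) * correction_factor


def extract_profiles(
    n_rows: int,
    pixel_size_um: float,
    spacing_um: float = 25.0,
    margin_um: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced profile positions along the channel axis.

    Positions form the grid ``margin, margin + spacing, ...`` up to
    ``extent - margin`` where ``extent = (n_rows - 1) * pixel_size_um`` is
    the physical position of the last row.  Edge regions (the first and
    last ``margin_um``) are excluded because the lumen edges there are not
    reliably in the field of view.

    Returns
    -------
    positions_um, row_indices
        Physical grid positions and the nearest pixel row for each.

    Raises
    ------
    NoProfilesError
        If the margins leave no usable extent.
    """
    if spacing_um <= 0:
        raise ValueError("spacing_um must be > 0")
    if margin_um < 0:
        raise ValueError("margin_um must be >= 0")
    extent = (n_rows - 1) * pixel_size_um
    usable = extent - 2.0 * margin_um
    if usable < 0:
        raise NoProfilesError(
            f"margin {margin_um} µm leaves no usable extent on a {extent:.1f} µm image"
        )
    n = int(np.floor(usable / spacing_um + 1e-9)) + 1
    positions = margin_um + spacing_um * np.arange(n)
    rows = np.clip(np.rint(positions / pixel_size_um).astype(int), 0, n_rows - 1)
    return positions, rows


def detect_lumen_edges(
    profile: np.ndarray, threshold: float, min_run_px: int = 3
) -> Optional[tuple[int, int]]:
    """Outermost supra-threshold runs of a cross-channel profile.

    The left edge is the start of the first run of at least ``min_run_px``
    consecutive pixels strictly above ``threshold``; the right edge is the
    (inclusive) end of the last such run.  Runs shorter than ``min_run_px``
    (hot pixels) are ignored.

    Returns ``None`` when no qualifying run exists; such profiles are
    flagged invalid and excluded from averaging rather than raising.
    """
    if min_run_px < 1:
        raise ValueError("min_run_px must be >= 1")
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("profile must be non-empty")
    above = profile > threshold
    if not above.any():
        return None
    padded = np.concatenate(([False], above, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1  # inclusive
    long_enough = (ends - starts + 1) >= min_run_px
    if not long_enough.any():
        return None
    return int(starts[long_enough][0]), int(ends[long_enough][-1])


def projected_width(left_px: int, right_px: int, pixel_size_um: float) -> float:
    """Projected width between two edge columns, in µm.

    Profiles are perpendicular to the channel axis, so the Euclidean
    distance between the two edge points reduces to the in-profile column
    separation times the pixel size.
    """
    if right_px < left_px:
        raise ValueError(f"reversed edges: left={left_px} > right={right_px}")
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    return (right_px - left_px) * pixel_size_um


def measure_image(
    image: ChannelImage,
    spacing_um: float = 25.0,
    margin_um: float = 100.0,
    correction_factor: float = 1.0,
    min_run_px: int = 3,
    calibration: Optional[WallCalibration] = None,
) -> WidthMeasurement:
    """Measure the mean projected lumen width of one image.

    Composes :func:`corrected_threshold` → :func:`extract_profiles` →
    :func:`detect_lumen_edges` → :func:`projected_width` and averages over
    valid profiles.  All per-profile results are retained for audit.

    Raises
    ------
    MeasurementError
        If no profile on the image yields a valid edge pair.
    """
    fluo = image.fluorescence
    if calibration is not None and calibration.channel_axis == 1:
        fluo = fluo.T
    threshold = corrected_threshold(fluo, correction_factor)
    positions, rows = extract_profiles(
        fluo.shape[0], image.pixel_size_um, spacing_um, margin_um
    )
    profiles: list[WidthProfile] = []
    widths: list[float] = []
    for pos, row in zip(positions, rows):
        edges = detect_lumen_edges(fluo[row], threshold, min_run_px)
        if edges is None:
            profiles.append(WidthProfile(float(pos), int(row), None, None, None, False))
            continue
        left, right = edges
        w = projected_width(left, right, image.pixel_size_um)
        profiles.append(WidthProfile(float(pos), int(row), left, right, w, True))
        widths.append(w)
    if not widths:
        raise MeasurementError(
            f"no valid lumen profile on image of chip {image.chip_id!r} (day {image.day})"
        )
    return WidthMeasurement(
        profiles=tuple(profiles),
        threshold=float(threshold),
        correction_factor=float(correction_factor),
        mean_width_um=float(np.mean(widths)),
        n_valid_profiles=len(widths),
        chip_id=image.chip_id,
        day=image.day,
        group=image.group,
    )


def detect_wall(
    brightfield: np.ndarray,
    manual: Optional[WallCalibration] = None,
    min_contrast: float = 0.2,
) -> WallCalibration:
    """Propose the leftmost channel wall from a brightfield image.

    The walls appear as dark vertical bands.  The column-mean profile is
    thresholded at the midpoint of its range and the center of the leftmost
    dark run is proposed as ``wall_left_x``.  A manually supplied
    calibration always wins (the faithful mode of the original protocol).

    Raises
    ------
    CalibrationError
        If the image is too flat to locate a wall automatically.
    """
    if manual is not None:
        return manual
    bf = np.asarray(brightfield, dtype=float)
    if bf.ndim != 2:
        raise ValueError("brightfield raster must be 2D")
    col_mean = bf.mean(axis=0)
    lo, hi = col_mean.min(), col_mean.max()
    if hi - lo <= min_contrast * max(abs(hi), 1e-12):
        raise CalibrationError(
            "brightfield too flat for automatic wall detection; "
            "supply a manual WallCalibration"
        )
    dark = col_mean < (lo + hi) / 2.0
    padded = np.concatenate(([False], dark, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    if starts.size == 0:
        raise CalibrationError("no dark band found; supply a manual WallCalibration")
    center = int(round((starts[0] + ends[0]) / 2.0))
    return WallCalibration(wall_left_x=center, channel_axis=0, source="automatic")
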