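"""Ground-truth-annotated synthetic data for the chip analysis pipeline.

Three generators stand in for the study's raw data, each deterministic
given its config and seed:

* :func:`generate_lumen_scene` — low-magnification dual-channel images of a
  bright fluorescent lumen band between two dark channel walls, with
  optional blur, illumination gradient and additive Gaussian noise.
* :func:`generate_cell_mask` — non-overlapping elliptical or rectangular
  cell label masks with controllable area / elongation / orientation
  distributions (fixtures for the morphometry stage).
* :func:`generate_cohort` — longitudinal per-chip width records drawn from
  a multivariate normal with group-specific mean trajectories, a shared
  unstructured covariance across days, and monotone chip dropout.

Default parameters encode the study conditions: a 1300 µm wide channel
(walls 400 px apart at 3.25 µm/px), eight observation days (2, 3, 5–10),
a control group holding ~1300 µm throughout and a co-culture group
remodeling down to ~1023 µm by day 10, with per-day chip counts declining
as in the experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from .exceptions import GeometryError, PackingWarning
from .lumen import ChannelImage

__all__ = [
    "SceneConfig",
    "GroundTruthScene",
    "MaskConfig",
    "CellTruth",
    "CohortDesign",
    "generate_lumen_scene",
    "generate_cell_mask",
    "generate_cohort",
    "default_cohort_design",
]

WidthSpec = Union[float, Sequence[float], Callable[[np.ndarray], np.ndarray]]

#: Observation days of the culture experiment.
DEFAULT_DAYS: tuple[int, ...] = (2, 3, 5, 6, 7, 8, 9, 10)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, optics and noise of one synthetic lumen scene.

    The default geometry covers a 1300 µm wide channel with margin:
    1200×600 px at 3.25 µm/px, walls at columns 100 and 500.  The default
    lumen width equals the wall separation (a wall-attached lumen, the
    day-2 state); remodeling is emulated by passing a smaller constant or a
    per-row width profile.
    """

    image_height_px: int = 1200
    image_width_px: int = 600
    pixel_size_um: float = 3.25
    wall_left_x: int = 100
    wall_right_x: int = 500
    lumen_width_um: WidthSpec = 1300.0
    lumen_center_offset_um: float = 0.0
    intensity_lumen: float = 200.0
    intensity_background: float = 20.0
    noise_sd: float = 5.0
    blur_sigma_px: float = 1.0
    illumination_gradient: float = 0.0
    wall_band_halfwidth_px: int = 4
    seed: int = 0
    chip_id: str = "chip-0"
    day: int = 2
    group: str = "control"

    def __post_init__(self) -> None:
        if self.image_height_px < 2 or self.image_width_px < 2:
            raise ValueError("image must be at least 2x2 px")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not (0 <= self.wall_left_x < self.wall_right_x < self.image_width_px):
            raise ValueError("walls must satisfy 0 <= left < right < width")
        if not self.intensity_lumen > self.intensity_background:
            raise ValueError("intensity_lumen must exceed intensity_background")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sd and blur_sigma_px must be >= 0")

    @property
    def wall_separation_um(self) -> float:
        return (self.wall_right_x - self.wall_left_x) * self.pixel_size_um


@dataclass(frozen=True)
class GroundTruthScene:
    """Simulator-side truth for one scene (continuous µm geometry).

    Edges are the requested geometry before rasterization, so
    ``mean_width_um`` equals the configured width exactly; pixel-grid
    rounding is part of the measurement error budget, not of the truth.
    """

    left_edge_um: np.ndarray
    right_edge_um: np.ndarray
    wall_left_x: int
    wall_right_x: int
    pixel_size_um: float

    @property
    def widths_um(self) -> np.ndarray:
        return self.right_edge_um - self.left_edge_um

    @property
    def mean_width_um(self) -> float:
        return float(np.mean(self.widths_um))


def _resolve_widths(config: SceneConfig, row_um: np.ndarray) -> np.ndarray:
    spec = config.lumen_width_um
    if callable(spec):
        widths = np.asarray(spec(row_um), dtype=float)
    elif np.isscalar(spec):
        widths = np.full(row_um.size, float(spec))
    else:
        widths = np.asarray(spec, dtype=float)
    if widths.shape != row_um.shape:
        raise ValueError("per-row width profile must have one value per image row")
    return widths


def generate_lumen_scene(config: SceneConfig) -> tuple[ChannelImage, GroundTruthScene]:
    """Render one dual-channel scene and its ground truth.

    The fluorescence raster holds ``intensity_lumen`` inside the per-row
    lumen band (inclusive of both rounded edge columns) and
    ``intensity_background`` outside, then Gaussian blur, a multiplicative
    left-to-right illumination ramp, and seeded additive Gaussian noise are
    applied in that order.  The brightfield raster shows dark wall bands at
    the two wall positions.

    Raises
    ------
    GeometryError
        If any requested width exceeds the wall separation (band crossing
        a wall).
    """
    h, w, ps = config.image_height_px, config.image_width_px, config.pixel_size_um
    row_um = np.arange(h) * ps
    widths = _resolve_widths(config, row_um)
    if np.any(widths < 0):
        raise GeometryError("negative lumen width requested")
    center_um = (config.wall_left_x + config.wall_right_x) / 2.0 * ps
    center_um += config.lumen_center_offset_um
    left_um = center_um - widths / 2.0
    right_um = center_um + widths / 2.0
    eps = 1e-9
    if np.any(left_um < config.wall_left_x * ps - eps) or np.any(
        right_um > config.wall_right_x * ps + eps
    ):
        raise GeometryError(
            "lumen band crosses a channel wall: requested width/offset exceeds "
            f"the {config.wall_separation_um:.1f} µm wall separation"
        )

    rng = np.random.default_rng(config.seed)
    fluo = np.full((h, w), config.intensity_background, dtype=float)
    cols = np.arange(w)
    left_px = np.rint(left_um / ps).astype(int)
    right_px = np.rint(right_um / ps).astype(int)
    band = (cols[None, :] >= left_px[:, None]) & (cols[None, :] <= right_px[:, None])
    fluo[band] = config.intensity_lumen
    if config.blur_sigma_px > 0:
        fluo = gaussian_filter(fluo, config.blur_sigma_px)
    if config.illumination_gradient != 0.0:
        ramp = 1.0 + config.illumination_gradient * (cols / (w - 1) - 0.5)
        fluo = fluo * ramp[None, :]
    if config.noise_sd > 0:
        fluo = fluo + rng.normal(0.0, config.noise_sd, size=fluo.shape)

    # Brightfield: bright channel interior, dark wall bands.
    bf = np.full((h, w), 180.0)
    half = config.wall_band_halfwidth_px
    for wall in (config.wall_left_x, config.wall_right_x):
        lo, hi = max(wall - half, 0), min(wall + half + 1, w)
        bf[:, lo:hi] = 40.0
    if config.noise_sd > 0:
        bf = bf + rng.normal(0.0, config.noise_sd, size=bf.shape)

    image = ChannelImage(
        fluorescence=fluo,
        brightfield=bf,
        pixel_size_um=ps,
        chip_id=config.chip_id,
        day=config.day,
        group=config.group,
    )
    truth = GroundTruthScene(
        left_edge_um=left_um,
        right_edge_um=right_um,
        wall_left_x=config.wall_left_x,
        wall_right_x=config.wall_right_x,
        pixel_size_um=ps,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Cell label masks


@dataclass(frozen=True)
class MaskConfig:
    """Distributional parameters of a synthetic cell label mask.

    Areas are normal (µm², clipped to a small positive floor), aspect
    ratios normal clipped to ≥ 1, orientations either uniform on [0, 180)
    (``orientation_sd_deg=None``) or normal around ``orientation_mean_deg``
    wrapped into [0, 180).  Defaults emulate a confluent endothelial
    monolayer imaged at 0.5 µm/px: ~600 µm² cells with moderate elongation.
    """

    n_cells: int = 60
    image_height_px: int = 768
    image_width_px: int = 768
    pixel_size_um: float = 0.5
    area_mean_um2: float = 600.0
    area_sd_um2: float = 150.0
    aspect_mean: float = 2.0
    aspect_sd: float = 0.5
    orientation_mean_deg: float = 0.0
    orientation_sd_deg: Optional[float] = None  # None -> uniform [0, 180)
    shape_family: str = "ellipse"
    min_gap_px: int = 2
    max_attempts_per_cell: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.shape_family not in ("ellipse", "rectangle"):
            raise ValueError("shape_family must be 'ellipse' or 'rectangle'")
        if self.min_gap_px < 1:
            raise ValueError("min_gap_px must be >= 1")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.aspect_mean < 1:
            raise ValueError("aspect_mean must be >= 1")


@dataclass(frozen=True)
class CellTruth:
    """Requested (continuous) shape parameters of one placed cell."""

    label_id: int
    area_um2: float
    aspect_ratio: float
    orientation_deg: float
    center_rc_px: tuple[float, float]


def _rasterize_shape(
    shape_family: str,
    center_rc: tuple[float, float],
    a_px: float,
    b_px: float,
    theta_deg: float,
    shape_hw: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (row, col) indices covered by an oriented ellipse/rectangle.

    Orientation is measured from the image horizontal axis with y up
    (image rows increase downward), matching the Feret-angle convention.
    """
    h, w = shape_hw
    cr, cc = center_rc
    r_ext = int(np.ceil(max(a_px, b_px))) + 1
    r0, r1 = max(int(cr) - r_ext, 0), min(int(cr) + r_ext + 1, h)
    c0, c1 = max(int(cc) - r_ext, 0), min(int(cc) + r_ext + 1, w)
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    x = cc_grid - cc
    y = -(rr - cr)
    th = np.deg2rad(theta_deg)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    if shape_family == "ellipse":
        inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    else:
        inside = (np.abs(u) <= a_px) & (np.abs(v) <= b_px)
    return rr[inside], cc_grid[inside]


def generate_cell_mask(config: MaskConfig) -> tuple[np.ndarray, list[CellTruth]]:
    """Place non-overlapping labeled shapes by rejection sampling.

    Every pair of placed labels is separated by at least ``min_gap_px``
    background pixels (checked with a Chebyshev dilation of the candidate
    footprint).  Shapes are kept fully inside the image.  If the retry
    budget is exhausted before ``n_cells`` shapes are placed, a partial
    mask is returned with a :class:`PackingWarning` — never a silent
    truncation.

    Returns
    -------
    labels, truths
        Integer label raster (0 = background, ids consecutive from 1) and
        the requested shape parameters of each placed cell.
    """
    rng = np.random.default_rng(config.seed)
    h, w, ps = config.image_height_px, config.image_width_px, config.pixel_size_um
    labels = np.zeros((h, w), dtype=np.int32)
    blocked = np.zeros((h, w), dtype=bool)  # occupied + gap halo
    truths: list[CellTruth] = []
    gap = config.min_gap_px
    next_id = 1
    attempts_left = config.max_attempts_per_cell * max(config.n_cells, 1)
    while next_id <= config.n_cells and attempts_left > 0:
        attempts_left -= 1
        area = max(rng.normal(config.area_mean_um2, config.area_sd_um2), 4 * ps**2)
        ar = max(rng.normal(config.aspect_mean, config.aspect_sd), 1.0)
        if config.orientation_sd_deg is None:
            theta = rng.uniform(0.0, 180.0)
        else:
            theta = rng.normal(config.orientation_mean_deg, config.orientation_sd_deg) % 180.0
        if config.shape_family == "ellipse":
            b_um = np.sqrt(area / (np.pi * ar))  # semi-minor: area = pi*a*b
        else:
            b_um = np.sqrt(area / (4.0 * ar))  # half-extent: area = (2a)(2b)
        a_um = b_um * ar
        a_px, b_px = a_um / ps, b_um / ps
        ext = int(np.ceil(max(a_px, b_px))) + gap + 1
        if 2 * ext >= min(h, w):
            continue  # shape cannot fit
        cr = rng.uniform(ext, h - 1 - ext)
        cc = rng.uniform(ext, w - 1 - ext)
        rr, cols = _rasterize_shape(
            config.shape_family, (cr, cc), a_px, b_px, theta, (h, w)
        )
        if rr.size == 0:
            continue
        # Chebyshev dilation of the candidate by `gap`: test the blocked map
        # (which holds previous labels dilated by `gap`) at the raw footprint.
        if blocked[rr, cols].any():
            continue
        labels[rr, cols] = next_id
        r0, r1 = rr.min() - gap, rr.max() + gap + 1
        c0, c1 = cols.min() - gap, cols.max() + gap + 1
        sub = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        sub[rr - r0, cols - c0] = True
        halo = binary_dilation(sub, structure=np.ones((2 * gap + 1, 2 * gap + 1)))
        rs = slice(max(r0, 0), min(r1, h))
        cs = slice(max(c0, 0), min(c1, w))
        blocked[rs, cs] |= halo[rs.start - r0 : rs.stop - r0, cs.start - c0 : cs.stop - c0]
        truths.append(
            CellTruth(
                label_id=next_id,
                area_um2=float(area),
                aspect_ratio=float(ar),
                orientation_deg=float(theta),
                center_rc_px=(float(cr), float(cc)),
            )
        )
        next_id += 1
    if next_id <= config.n_cells:
        warnings.warn(
            f"placed only {next_id - 1} of {config.n_cells} requested cells "
            "before exhausting the retry budget",
            PackingWarning,
            stacklevel=2,
        )
    return labels, truths


# ---------------------------------------------------------------------------
# Longitudinal cohorts


def _default_trajectories() -> dict[str, tuple[float, ...]]:
    # Control holds the full channel width; co-culture remodels from ~day 5.
    return {
        "control": (1295.4, 1297.0, 1298.5, 1299.5, 1300.5, 1301.5, 1302.5, 1304.9),
        "co-culture": (1296.0, 1293.0, 1284.3, 1262.0, 1210.0, 1150.0, 1085.0, 1023.1),
    }


def _default_covariance(n_days: int = 8) -> np.ndarray:
    # Between-chip spread grows as remodeling progresses; neighbouring days
    # correlate.  Free (unstructured) in form: any SPD matrix is accepted.
    sd = np.array([10.0, 12.0, 16.0, 25.0, 40.0, 60.0, 80.0, 100.0])[:n_days]
    idx = np.arange(n_days)
    corr = 0.6 ** np.abs(idx[:, None] - idx[None, :])
    return corr * sd[:, None] * sd[None, :]


@dataclass(frozen=True)
class CohortDesign:
    """Design of a longitudinal width cohort.

    ``dropout_schedule`` maps each group to the number of chips retained
    per day (non-increasing); chip ``j`` of a group is observed on day ``d``
    iff ``j < schedule[d]``, so missingness is monotone — a chip that drops
    out never returns.  The covariance matrix across days is shared by both
    groups (the model the analysis stage assumes).
    """

    days: tuple[int, ...] = DEFAULT_DAYS
    groups: tuple[str, ...] = ("control", "co-culture")
    mean_trajectories: Mapping[str, Sequence[float]] = field(
        default_factory=_default_trajectories
    )
    covariance: np.ndarray = field(default_factory=_default_covariance)
    n_chips: Mapping[str, int] = field(
        default_factory=lambda: {"control": 12, "co-culture": 68}
    )
    dropout_schedule: Optional[Mapping[str, Sequence[int]]] = field(
        default_factory=lambda: {
            "control": (12, 12, 6, 6, 6, 6, 6, 6),
            "co-culture": (68, 68, 65, 62, 34, 34, 33, 26),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "covariance", cov)
        d = len(self.days)
        if cov.shape != (d, d):
            raise ValueError("covariance must be square with one row per day")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive definite") from exc
        for g in self.groups:
            if len(self.mean_trajectories[g]) != d:
                raise ValueError(f"mean trajectory of group {g!r} must have {d} entries")
            if self.n_chips[g] < 1:
                raise ValueError("each group needs at least one chip")
            if self.dropout_schedule is not None:
                sched = list(self.dropout_schedule[g])
                if len(sched) != d:
                    raise ValueError("dropout schedule must have one count per day")
                if any(b > a for a, b in zip(sched, sched[1:])):
                    raise ValueError("dropout counts must be non-increasing over days")
                if sched[0] > self.n_chips[g]:
                    raise ValueError("dropout schedule exceeds n_chips")


def default_cohort_design(seed: int = 0) -> CohortDesign:
    """The study-sized cohort design (default chip counts and dropout)."""
    return CohortDesign(seed=seed)


def generate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Draw a longitudinal cohort table from a :class:`CohortDesign`.

    Each chip's full-day width series is multivariate normal with its
    group's mean trajectory and the shared covariance; the dropout schedule
    then truncates each chip's series (monotone missingness).

    Returns a tidy DataFrame with columns ``chip_id, group, day, width_um``.
    """
    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []
    for g in design.groups:
        mu = np.asarray(design.mean_trajectories[g], dtype=float)
        n = design.n_chips[g]
        series = rng.multivariate_normal(mu, design.covariance, size=n, method="cholesky")
        if design.dropout_schedule is None:
            sched = [n] * len(design.days)
        else:
            sched = list(design.dropout_schedule[g])
        for j in range(n):
            chip = f"{g}-{j:03d}"
            for k, day in enumerate(design.days):
                if j < sched[k]:
                    rows.append(
                        {
                            "chip_id": chip,
                            "group": g,
                            "day": int(day),
                            "width_um": float(series[j, k]),
                        }
                    )
    return pd.DataFrame(rows, columns=["chip_id", "group", "day", "width_um"])
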