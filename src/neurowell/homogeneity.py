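"""Plating-homogeneity scoring of full-well scans.

Uneven plating — cells aggregating toward the well rim (the edge
effect) — confounds downstream imaging assays.  The homogeneity readout
implemented here partitions the well disc into five equal-area regions
(a central disc plus four quadrant sectors of the surrounding annulus),
measures the percent cell-occupied area in each region on the nuclear
stain, and scores the well by the standard deviation of the five
percentages: lower SD means more homogeneous plating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage.filters import gaussian, threshold_otsu

from .config import GeometryConfig, OccupancyConfig

__all__ = [
    "WellScan",
    "RegionPartition",
    "OccupancyProfile",
    "partition_well",
    "detect_well",
    "compute_occupancy",
    "homogeneity_experiment",
    "region_of_points",
]


@dataclass
class WellScan:
    """A (possibly multi-channel) scan of one well.

    ``channels`` maps channel name (e.g. ``"hoechst"``, ``"biii"``) to a
    2-D intensity raster in the 16-bit range.  ``well_center_px`` is
    (x, y) in 0-based pixel coordinates, origin at the top-left corner.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    well_center_px: tuple[float, float]
    well_radius_px: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("WellScan needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        h, w = self.shape
        cx, cy = self.well_center_px
        r = self.well_radius_px
        if cx - r < -0.5 or cy - r < -0.5 or cx + r > w - 0.5 or cy + r > h - 0.5:
            raise ValueError("well disc does not fit inside the raster")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"channel {name!r} not in scan (have {sorted(self.channels)})")


@dataclass
class RegionPartition:
    """Per-pixel region labels: 0 outside the well, 1..n inside."""

    label_raster: np.ndarray
    region_areas_px: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.unique(self.label_raster)
        region_ids = [int(l) for l in labels if l != 0]
        if not region_ids:
            raise ValueError("partition contains no regions")
        if not self.region_areas_px:
            self.region_areas_px = {
                rid: int(np.count_nonzero(self.label_raster == rid)) for rid in region_ids
            }
        for rid, area in self.region_areas_px.items():
            if area <= 0:
                raise ValueError(f"region {rid} has zero area")

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.region_areas_px)


@dataclass
class OccupancyProfile:
    """Percent cell-occupied area per region and the homogeneity score."""

    occupied_pct: tuple[float, ...]
    homogeneity_sd: float

    def __post_init__(self) -> None:
        for pct in self.occupied_pct:
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"occupied_pct out of [0, 100]: {pct}")
        if self.homogeneity_sd < 0:
            raise ValueError("homogeneity_sd must be >= 0")


def region_of_points(
    x_um: np.ndarray,
    y_um: np.ndarray,
    well_radius_um: float,
    geometry: GeometryConfig | None = None,
) -> np.ndarray:
    """Analytic region assignment for points given in µm from the well center.

    Returns an integer label per point: 0 outside the disc, 1 for the
    central disc, ``2 .. n_sectors+1`` for the annulus sectors counted
    counter-clockwise from ``sector_offset_deg``.
    """
    geometry = geometry or GeometryConfig()
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    r = np.hypot(x, y)
    inner_r = well_radius_um * np.sqrt(geometry.center_area_fraction)
    theta = np.degrees(np.arctan2(y, x))
    sector = np.floor(((theta - geometry.sector_offset_deg) % 360.0)
                      / (360.0 / geometry.n_sectors)).astype(int)
    labels = np.where(r <= inner_r, 1, 2 + sector)
    labels = np.where(r <= well_radius_um, labels, 0)
    return labels


def partition_well(scan: WellScan, geometry: GeometryConfig | None = None) -> RegionPartition:
    """Label every pixel of the scan with its analysis region.

    The default geometry is the five-region layout: a central disc of
    one fifth of the well area (radius R/sqrt(5)) plus the surrounding
    annulus cut into four equal quadrant sectors, so all five regions
    have equal area up to rasterization error.
    """
    geometry = geometry or GeometryConfig()
    h, w = scan.shape
    cx, cy = scan.well_center_px
    yy, xx = np.mgrid[0:h, 0:w]
    x_um = (xx - cx) * scan.pixel_size_um
    y_um = (yy - cy) * scan.pixel_size_um
    labels = region_of_points(x_um, y_um, scan.well_radius_px * scan.pixel_size_um, geometry)
    return RegionPartition(label_raster=labels.astype(np.int32))


def detect_well(scan: WellScan, channel: str = "hoechst",
                smooth_sigma_px: float = 2.0) -> tuple[tuple[float, float], float]:
    """Estimate the well circle from the stained foreground.

    Thresholds the (smoothed) nuclei channel with Otsu and returns the
    minimum enclosing circle of the foreground convex hull as
    ``((cx, cy), radius)`` in pixels.  Callers with known stage
    coordinates should override the result.
    """
    import shapely

    img = np.asarray(scan.channel(channel), dtype=float)
    if img.max() == img.min():
        raise ValueError(
            "cannot detect well on a constant image; specify center and radius manually")
    smoothed = gaussian(img, sigma=smooth_sigma_px, preserve_range=True)
    fg = smoothed > threshold_otsu(smoothed)
    coords = np.column_stack(np.nonzero(fg))  # (row, col)
    if coords.shape[0] < 3:
        raise ValueError(
            "too little foreground to detect the well; specify center and radius manually")
    hull = ConvexHull(coords.astype(float))
    pts = coords[hull.vertices][:, ::-1]  # -> (x, y)
    circle = shapely.minimum_bounding_circle(shapely.MultiPoint(pts))
    radius = shapely.minimum_bounding_radius(shapely.MultiPoint(pts))
    center = circle.centroid
    return (float(center.x), float(center.y)), float(radius)


def compute_occupancy(
    scan: WellScan,
    partition: RegionPartition,
    config: OccupancyConfig | None = None,
    channel: str = "hoechst",
) -> OccupancyProfile:
    """Percent cell-occupied area per region and its between-region SD.

    Foreground is an Otsu threshold on the Gaussian-smoothed nuclear
    channel, with the threshold computed over well-interior pixels only
    (rim glare and the dark exterior would otherwise bias the global
    histogram).  Occupancy is a binary area fraction per region; the
    homogeneity score is the sample SD (n-1 denominator by default)
    of the per-region percentages.
    """
    config = config or OccupancyConfig()
    if partition.label_raster.shape != scan.shape:
        raise ValueError("partition is not aligned to the scan")
    img = np.asarray(scan.channel(channel), dtype=float)
    smoothed = gaussian(img, sigma=config.smooth_sigma_px, preserve_range=True)
    interior = partition.label_raster > 0
    raw_vals = np.asarray(scan.channel(channel))[interior]
    if np.all(raw_vals >= 65535):
        warnings.warn("saturated image: entire well interior is foreground", stacklevel=2)
        fg = interior.copy()
    elif raw_vals.max() == raw_vals.min():
        warnings.warn("uniform well interior; reporting zero occupancy", stacklevel=2)
        fg = np.zeros_like(interior)
    else:
        fg = (smoothed > threshold_otsu(smoothed[interior])) & interior
    pcts = []
    for rid in partition.region_ids:
        region = partition.label_raster == rid
        pcts.append(float(
            100.0 * np.count_nonzero(fg & region) / partition.region_areas_px[rid]))
    ddof = 0 if config.population_sd else 1
    sd = float(np.std(pcts, ddof=ddof)) if len(pcts) > 1 else 0.0
    return OccupancyProfile(occupied_pct=tuple(pcts), homogeneity_sd=sd)


def homogeneity_experiment(
    profiles_by_condition: Mapping[str, Sequence[OccupancyProfile]],
) -> pd.DataFrame:
    """Per-condition mean ± SD of the homogeneity score.

    Returns one row per condition with columns ``condition, n,
    mean_homogeneity_sd, sd_homogeneity_sd``; feed the underlying
    per-well scores to :mod:`neurowell.stats` for ANOVA/Tukey testing.
    """
    rows = []
    for condition, profiles in profiles_by_condition.items():
        if len(profiles) == 0:
            raise ValueError(f"condition {condition!r} has no profiles")
        scores = np.array([p.homogeneity_sd for p in profiles], dtype=float)
        rows.append({
            "condition": condition,
            "n": len(scores),
            "mean_homogeneity_sd": float(scores.mean()),
            "sd_homogeneity_sd": float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
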