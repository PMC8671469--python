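"""Nuclei counting, proliferation and LIVE/DEAD viability metrics.

Nuclei are counted automatically from the Hoechst channel with a
distance-transform watershed that splits touching nuclei; at very high
plating densities nuclei cluster and counting accuracy degrades, which
is the regime the plating-density optimisation is meant to avoid.
Viability is the background-subtracted EthD-1 (dead) to calcein (live)
signal ratio — from plate-reader emission tables or, image-based, from
per-channel object counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .config import NucleiSegConfig

__all__ = [
    "NucleiSet",
    "ViabilityMeasurement",
    "count_nuclei",
    "percent_increase",
    "viability_from_reader",
    "viability_from_images",
    "read_reader_table",
    "viability_table",
]


@dataclass
class NucleiSet:
    """Detected nuclei: centroids in µm (x, y) and their count."""

    centroids: np.ndarray
    count: int
    source_image_id: str = ""

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if self.count != len(self.centroids):
            raise ValueError("count must equal the number of centroids")


@dataclass
class ViabilityMeasurement:
    """Background-subtracted live/dead signals and their dead:live ratio.

    ``flagged`` marks measurements whose ratio is undefined (zero live
    signal); such rows are excluded from downstream statistics.
    """

    calcein_signal: float
    ethd1_signal: float
    dead_live_ratio: float
    flagged: bool = False


def count_nuclei(
    nuclei_channel: np.ndarray,
    pixel_size_um: float,
    seg: NucleiSegConfig | None = None,
    image_id: str = "",
) -> NucleiSet:
    """Segment and count nuclei in a single-channel raster.

    Pipeline: Gaussian smooth (σ = 2 px) → Otsu threshold → fill holes →
    distance-transform watershed seeded at local distance maxima (to
    split touching nuclei) → discard fragments smaller than 25% of the
    median nucleus area.  A blank image yields a count of zero, not an
    error.
    """
    seg = seg or NucleiSegConfig()
    img = np.asarray(nuclei_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclei channel must be a 2-D raster")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if img.max() == img.min():
        return NucleiSet(np.empty((0, 2)), 0, image_id)
    smoothed = gaussian(img, sigma=seg.smooth_sigma_px, preserve_range=True)
    t = threshold_otsu(smoothed)
    mask = smoothed > t
    if not mask.any():
        return NucleiSet(np.empty((0, 2)), 0, image_id)
    # reject noise-only images: on pure noise Otsu still splits the
    # histogram, but the two classes stay within ~2 background SDs of
    # each other, far below any real stain-to-background contrast
    below = smoothed[~mask]
    separation = (smoothed[mask].mean() - below.mean()) / max(below.std(), 1e-9)
    if separation < seg.min_contrast_separation:
        return NucleiSet(np.empty((0, 2)), 0, image_id)
    mask = ndi.binary_fill_holes(mask)

    distance = ndi.distance_transform_edt(mask)
    min_dist_px = max(1, int(round(seg.min_separation_um / pixel_size_um)))
    peaks = peak_local_max(distance, min_distance=min_dist_px, labels=mask,
                           exclude_border=False)
    markers = np.zeros_like(mask, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)

    props = regionprops(labels)
    if not props:
        return NucleiSet(np.empty((0, 2)), 0, image_id)
    areas = np.array([p.area for p in props])
    min_area = seg.min_area_fraction_of_median * np.median(areas)
    keep = [p for p in props if p.area >= min_area]
    centroids = np.array([(p.centroid[1], p.centroid[0]) for p in keep], dtype=float)
    centroids *= pixel_size_um
    return NucleiSet(centroids, len(keep), image_id)


def percent_increase(count_start: float, count_end: float) -> float:
    """Percent change in cell population, 100·(end − start)/start."""
    if count_start <= 0:
        raise ValueError("count_start must be > 0 for a percent increase")
    return 100.0 * (count_end - count_start) / count_start


def viability_from_reader(
    raw_calcein: float, raw_ethd1: float, bg_calcein: float, bg_ethd1: float
) -> ViabilityMeasurement:
    """Dead:live ratio from plate-reader emissions.

    Background (blank Matrigel + medium) readings are subtracted per
    filter and negative results floored at zero; the ratio is EthD-1
    over calcein signal, undefined (flagged) when the calcein signal
    is zero.
    """
    for v in (raw_calcein, raw_ethd1, bg_calcein, bg_ethd1):
        if v < 0:
            raise ValueError("emission readings must be >= 0")
    cal = max(raw_calcein - bg_calcein, 0.0)
    eth = max(raw_ethd1 - bg_ethd1, 0.0)
    if cal == 0.0:
        return ViabilityMeasurement(cal, eth, float("nan"), flagged=True)
    return ViabilityMeasurement(cal, eth, eth / cal)


def viability_from_images(
    calcein_channel: np.ndarray,
    ethd1_channel: np.ndarray,
    pixel_size_um: float,
    seg: NucleiSegConfig | None = None,
) -> ViabilityMeasurement:
    """Image-based dead:live ratio from object counts.

    Counts calcein-positive cell bodies and EthD-1-positive nuclei with
    the same watershed segmentation used for nuclei counting and
    reports dead count / live count.  The two channels must be
    co-registered.
    """
    if np.shape(calcein_channel) != np.shape(ethd1_channel):
        raise ValueError("calcein and EthD-1 channels must be co-registered")
    live = count_nuclei(calcein_channel, pixel_size_um, seg).count
    dead = count_nuclei(ethd1_channel, pixel_size_um, seg).count
    if live == 0:
        return ViabilityMeasurement(float(live), float(dead), float("nan"), flagged=True)
    return ViabilityMeasurement(float(live), float(dead), dead / live)


def read_reader_table(path_or_df) -> pd.DataFrame:
    """Load a long-format reader table (columns ``well, filter, emission``)."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:  # round_trip: emission values survive write/read bit-exactly
        df = pd.read_csv(path_or_df, float_precision="round_trip")
    missing = {"well", "filter", "emission"} - set(df.columns)
    if missing:
        raise ValueError(f"reader table missing columns: {sorted(missing)}")
    return df


def viability_table(reader_df: pd.DataFrame, ndigits: int = 3) -> pd.DataFrame:
    """Per-well viability summary from a plate-reader table.

    Background rows (well ID ``"background"``) are averaged per filter
    and subtracted from each well's emissions; the summary reports the
    subtracted signals and the dead:live ratio rounded to ``ndigits``
    decimals, with undefined ratios flagged.
    """
    df = read_reader_table(reader_df)
    bg = df[df["well"] == "background"].groupby("filter")["emission"].mean()
    if not {"calcein", "ethd1"} <= set(bg.index):
        raise ValueError("reader table lacks background rows for both filters")
    wells = df[df["well"] != "background"].pivot_table(
        index="well", columns="filter", values="emission", aggfunc="mean")
    rows = []
    for well, row in wells.iterrows():
        m = viability_from_reader(row["calcein"], row["ethd1"],
                                  bg["calcein"], bg["ethd1"])
        rows.append({
            "well": well,
            "calcein_signal": m.calcein_signal,
            "ethd1_signal": m.ethd1_signal,
            "dead_live_ratio": round(m.dead_live_ratio, ndigits) if not m.flagged else float("nan"),
            "flagged": m.flagged,
        })
    return pd.DataFrame(rows)
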