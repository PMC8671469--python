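"""Synthetic well-image simulator with analytic ground truth.

Generates multi-channel 16-bit well images that emulate the statistical
structure of a differentiated SH-SY5Y 96-well assay: radially uniform or
rim-biased cell placement over the well disc, Hoechst nuclei as filled
discs, βIII-tubulin somata and random-walk neurites with a configurable
soma/neurite/background intensity contrast, and calcein / EthD-1
live/dead channels.  Every draw is governed by a single seed, and the
returned :class:`GroundTruth` carries the quantities the analysis
stages are supposed to recover (cell centers, per-region counts, alive
flags, analytic total neurite length, compartment masks), which makes
the simulator the oracle for the whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .config import GeometryConfig, SimulationConfig
from .homogeneity import WellScan, region_of_points

__all__ = [
    "GroundTruth",
    "sample_positions",
    "render_well",
    "simulate_reader_table",
    "write_simulated_well",
]

_RADIAL_K = 4  # exponent of the rim-bias density term


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover.

    ``cell_centers`` are (x, y) in µm from the well center.  The three
    compartment masks (soma / neurite / background, all on the βIII
    channel grid) are the simulator's own rasterized truth, used to
    check intensity recovery; ``background_mask`` covers well-interior
    pixels belonging to neither compartment.
    """

    cell_centers: np.ndarray
    alive_flags: np.ndarray
    per_region_counts: dict[int, int]
    total_neurite_length_um: float
    nuclei_count: int
    soma_mask: np.ndarray | None = None
    neurite_mask: np.ndarray | None = None
    background_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_centers = np.asarray(self.cell_centers, dtype=float).reshape(-1, 2)
        self.alive_flags = np.asarray(self.alive_flags, dtype=bool).reshape(-1)
        if self.nuclei_count != len(self.cell_centers):
            raise ValueError("nuclei_count must equal the number of cell centers")
        if len(self.alive_flags) != self.nuclei_count:
            raise ValueError("alive_flags must have one entry per cell")
        if sum(self.per_region_counts.values()) != self.nuclei_count:
            raise ValueError("per-region counts must sum to the number of cells")
        if self.total_neurite_length_um < 0:
            raise ValueError("total neurite length must be >= 0")


def _radial_cdf_grid(radius_um: float, edge_bias: float, n: int = 4097):
    """Grid of (r, CDF(r)) for the radial density f(r) ∝ r(1 + b (r/R)^k).

    At ``edge_bias = 0`` this is exactly uniform-over-area sampling
    (CDF r²/R², i.e. r = R·sqrt(U)); positive bias adds a steep
    (r/R)^4 term that concentrates probability at the rim.
    """
    r = np.linspace(0.0, radius_um, n)
    b = float(edge_bias)
    # ∫0^r s(1 + b(s/R)^k) ds = r²/2 + b r^(k+2) / ((k+2) R^k)
    unnorm = r**2 / 2.0 + b * r**(_RADIAL_K + 2) / ((_RADIAL_K + 2) * radius_um**_RADIAL_K)
    return r, unnorm / unnorm[-1]


def sample_positions(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Sample cell centers inside the well disc.

    Returns an ``(n_cells, 2)`` array of (x, y) positions in µm from the
    well center.  The radial coordinate is drawn by inverse-CDF from
    f(r) ∝ r(1 + edge_bias·(r/R)^4) — uniform over the disc when
    ``edge_bias = 0``, increasingly rim-concentrated as the bias grows —
    and the angle is uniform.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    if n == 0:
        return np.empty((0, 2), dtype=float)
    grid_r, grid_cdf = _radial_cdf_grid(config.well_radius_um, config.edge_bias)
    u = rng.random(n)
    r = np.interp(u, grid_cdf, grid_r)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _paint_discs(value_raster, mask_raster, centers_px, radii_px, values, shape):
    """Rasterize filled discs, later discs overwriting earlier ones."""
    for (cx, cy), radius, val in zip(centers_px, radii_px, values):
        rr, cc = draw_disk((cy, cx), max(radius, 1.0), shape=shape)
        value_raster[rr, cc] = val
        mask_raster[rr, cc] = True


def _walk_neurite(rng, config, start_xy_px, pixel, shape, theta0=None):
    """One piecewise-linear random-walk neurite.

    Steps of ``neurite_step_um`` with Gaussian turning angles; the walk
    is truncated if a step would leave the raster, and only completed
    steps count toward the analytic length, so the returned length is
    exactly the length of the drawn polyline.
    """
    h, w = shape
    target = max(config.neurite_step_um,
                 rng.normal(*config.neurite_length_um))
    n_steps = max(1, int(round(target / config.neurite_step_um)))
    theta = rng.uniform(0.0, 2.0 * np.pi) if theta0 is None else theta0
    turn_sd = math.radians(config.neurite_turn_sd_deg)
    x, y = start_xy_px
    pts = [(x, y)]
    length = 0.0
    step_px = config.neurite_step_um / pixel
    for _ in range(n_steps):
        theta += rng.normal(0.0, turn_sd)
        nx = x + step_px * math.cos(theta)
        ny = y + step_px * math.sin(theta)
        if not (0 <= nx < w - 1 and 0 <= ny < h - 1):
            break
        pts.append((nx, ny))
        x, y = nx, ny
        length += config.neurite_step_um
    return pts, length


def render_well(config: SimulationConfig) -> tuple[WellScan, GroundTruth]:
    """Render one synthetic well and its ground truth.

    Emits one 16-bit raster per channel in ``config.channels``:

    - ``hoechst`` — nuclei of all cells as filled discs;
    - ``biii`` — somata and neurites of live cells over background;
    - ``calcein`` — cell bodies of live cells only;
    - ``ethd1`` — nuclei of dead cells only.

    Per-cell intensities are drawn from the configured (mean, sd)
    models, additive Gaussian noise is applied, and the result is
    clipped to [0, 65535] and quantised.  Identical configs produce
    bit-identical output.
    """
    pixel = config.pixel_size_um
    radius_um = config.well_radius_um
    margin_px = int(math.ceil(3.0 * config.soma_radius_um[0] / pixel)) + 2
    well_px = int(math.ceil(config.well_diameter_um / pixel))
    npx = well_px + 2 * margin_px
    if npx < 8:
        raise ValueError("pixel grid too small to contain the well disc")
    shape = (npx, npx)
    center_px = (npx - 1) / 2.0
    radius_px = radius_um / pixel

    rng = np.random.default_rng(config.seed)
    centers_um = sample_positions(config, rng)
    n = len(centers_um)
    alive = rng.random(n) >= config.dead_fraction
    nuc_radii_um = np.clip(rng.normal(*config.nucleus_radius_um, size=n), 0.5, None)
    soma_radii_um = np.clip(rng.normal(*config.soma_radius_um, size=n), 1.0, None)
    nuc_int = np.clip(rng.normal(*config.intensity_nucleus, size=n), 0, 65535)
    # soma intensity varies both between cells and from point to point
    # within a cell; the configured SD is the point-level spread, split
    # evenly (in variance) between the two components
    soma_cell_int = rng.normal(config.intensity_soma[0],
                               config.intensity_soma[1] / np.sqrt(2.0), size=n)
    soma_pixel_sd = config.intensity_soma[1] / np.sqrt(2.0)
    cal_int = np.clip(rng.normal(*config.intensity_calcein, size=n), 0, 65535)
    eth_int = np.clip(rng.normal(*config.intensity_ethd1, size=n), 0, 65535)

    centers_px = centers_um / pixel + center_px

    # neurites: 1-px polylines, dilated to width.  Intensity is drawn per
    # 5 µm step (floored just above background), emulating the strong
    # point-to-point variation along real processes — bright stretches
    # interleaved with faint ones close to background — rather than
    # uniformly stained, sometimes invisible whole neurites.
    neurite_val = np.zeros(shape, dtype=np.float32)
    neurite_thin = np.zeros(shape, dtype=bool)
    neurite_floor = config.intensity_background[0] + 2.0 * config.noise_sd
    total_length = 0.0
    lo, hi = config.neurites_per_cell
    for i in range(n):
        if not alive[i]:
            continue
        k = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        for _ in range(k):
            phi = rng.uniform(0.0, 2.0 * np.pi)
            start = (centers_px[i, 0] + soma_radii_um[i] / pixel * math.cos(phi),
                     centers_px[i, 1] + soma_radii_um[i] / pixel * math.sin(phi))
            if not (0 <= start[0] < npx - 1 and 0 <= start[1] < npx - 1):
                continue
            # processes extend away from the cell body: initial heading is
            # the outward rim normal plus a moderate random deflection
            theta0 = phi + rng.uniform(-math.pi / 3, math.pi / 3)
            pts, length = _walk_neurite(rng, config, start, pixel, shape, theta0)
            total_length += length
            n_steps = len(pts) - 1
            step_int = np.clip(
                rng.normal(*config.intensity_neurite, size=max(n_steps, 0)),
                neurite_floor, 65535)
            for j, ((x0, y0), (x1, y1)) in enumerate(zip(pts[:-1], pts[1:])):
                rr, cc = draw_line(int(round(y0)), int(round(x0)),
                                   int(round(y1)), int(round(x1)))
                neurite_val[rr, cc] = step_int[j]
                neurite_thin[rr, cc] = True

    w_px = int(round(config.neurite_width_um / (2.0 * pixel)))
    if w_px > 0 and neurite_thin.any():
        foot = disk_footprint(w_px)
        neurite_mask = ndi.binary_dilation(neurite_thin, structure=foot)
        # widened pixels take the value of the nearest centre-line pixel,
        # so each step's intensity extends across its own width only
        _, (iy, ix) = ndi.distance_transform_edt(~neurite_thin, return_indices=True)
        neurite_val = neurite_val[iy, ix] * neurite_mask
    else:
        neurite_mask = neurite_thin

    soma_val = np.zeros(shape, dtype=np.float32)
    soma_mask = np.zeros(shape, dtype=bool)
    live = np.nonzero(alive)[0]
    _paint_discs(soma_val, soma_mask, centers_px[live], soma_radii_um[live] / pixel,
                 soma_cell_int[live], shape)
    if soma_mask.any() and soma_pixel_sd > 0:
        soma_val = soma_val + rng.normal(0.0, soma_pixel_sd, size=shape)
        soma_val = np.clip(soma_val, 0, 65535)

    bg_mean = config.intensity_background[0]
    channels: dict[str, np.ndarray] = {}
    for name in config.channels:
        img = np.full(shape, bg_mean, dtype=np.float32)
        if name == "hoechst":
            val = np.zeros(shape, dtype=np.float32)
            m = np.zeros(shape, dtype=bool)
            _paint_discs(val, m, centers_px, nuc_radii_um / pixel, nuc_int, shape)
            img[m] = val[m]
        elif name == "biii":
            img[neurite_mask] = neurite_val[neurite_mask]
            img[soma_mask] = soma_val[soma_mask]
        elif name == "calcein":
            val = np.zeros(shape, dtype=np.float32)
            m = np.zeros(shape, dtype=bool)
            _paint_discs(val, m, centers_px[live], soma_radii_um[live] / pixel,
                         cal_int[live], shape)
            img[m] = val[m]
        elif name == "ethd1":
            val = np.zeros(shape, dtype=np.float32)
            m = np.zeros(shape, dtype=bool)
            dead = np.nonzero(~alive)[0]
            _paint_discs(val, m, centers_px[dead], nuc_radii_um[dead] / pixel,
                         eth_int[dead], shape)
            img[m] = val[m]
        else:
            raise ValueError(f"unknown channel {name!r}")
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=shape)
        channels[name] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    yy, xx = np.mgrid[0:npx, 0:npx]
    inside = (xx - center_px) ** 2 + (yy - center_px) ** 2 <= radius_px**2
    neurite_only = neurite_mask & ~soma_mask
    background_mask = inside & ~soma_mask & ~neurite_mask

    region_labels = region_of_points(
        centers_um[:, 0], centers_um[:, 1], radius_um, GeometryConfig())
    per_region = {rid: int(np.count_nonzero(region_labels == rid))
                  for rid in range(1, GeometryConfig().n_regions + 1)}

    scan = WellScan(channels=channels, pixel_size_um=pixel,
                    well_center_px=(center_px, center_px), well_radius_px=radius_px)
    truth = GroundTruth(
        cell_centers=centers_um,
        alive_flags=alive,
        per_region_counts=per_region,
        total_neurite_length_um=total_length,
        nuclei_count=n,
        soma_mask=soma_mask,
        neurite_mask=neurite_only,
        background_mask=background_mask,
    )
    return scan, truth


def simulate_reader_table(
    wells: Mapping[str, tuple[float, float]],
    background: tuple[float, float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build a plate-reader emission table.

    ``wells`` maps well ID to raw (calcein, EthD-1) emission values;
    ``background`` gives the per-filter blank (Matrigel + medium)
    readings, emitted as rows with well ID ``"background"``.  Optional
    Gaussian noise is added to the well rows only.  The output is the
    long-format table read back by :func:`neurowell.cells.read_reader_table`
    with columns ``well, filter, emission``.
    """
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    rows = []
    for well, (cal, eth) in wells.items():
        if cal < 0 or eth < 0:
            raise ValueError(f"negative emission for well {well!r}")
        if rng is not None:
            cal = max(0.0, cal + rng.normal(0.0, noise_sd))
            eth = max(0.0, eth + rng.normal(0.0, noise_sd))
        rows.append({"well": well, "filter": "calcein", "emission": cal})
        rows.append({"well": well, "filter": "ethd1", "emission": eth})
    bg_cal, bg_eth = background
    if bg_cal < 0 or bg_eth < 0:
        raise ValueError("negative background emission")
    rows.append({"well": "background", "filter": "calcein", "emission": float(bg_cal)})
    rows.append({"well": "background", "filter": "ethd1", "emission": float(bg_eth)})
    return pd.DataFrame(rows, columns=["well", "filter", "emission"])


def write_simulated_well(
    scan: WellScan,
    truth: GroundTruth,
    config: SimulationConfig,
    outdir: str | Path,
    plate: str = "plate1",
    well: str = "A1",
) -> dict[str, Path]:
    """Write one simulated well to disk.

    Emits per-channel single-plane 16-bit TIFFs named
    ``{plate}_{well}_{channel}.tif``, the ground truth as CSV (one row
    per cell: ``well, x_um, y_um, alive, region``) and the config as
    YAML.  Returns the paths written, keyed by artifact name.
    """
    from .io import write_image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, img in scan.channels.items():
        p = outdir / f"{plate}_{well}_{name}.tif"
        write_image(p, img, pixel_size_um=scan.pixel_size_um)
        paths[name] = p
    regions = region_of_points(truth.cell_centers[:, 0], truth.cell_centers[:, 1],
                               config.well_radius_um, GeometryConfig())
    gt = pd.DataFrame({
        "well": well,
        "x_um": truth.cell_centers[:, 0],
        "y_um": truth.cell_centers[:, 1],
        "alive": truth.alive_flags.astype(int),
        "region": regions,
    })
    gt_path = outdir / f"{plate}_{well}_groundtruth.csv"
    gt.to_csv(gt_path, index=False)
    paths["groundtruth"] = gt_path
    cfg_path = outdir / f"{plate}_{well}_config.yaml"
    config.to_yaml(cfg_path)
    paths["config"] = cfg_path
    return paths
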