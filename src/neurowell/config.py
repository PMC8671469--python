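"""Configuration objects for the simulator and the analysis stages.

All physical lengths are micrometres (µm) and all intensities are
16-bit camera counts unless stated otherwise.  Every config round-trips
through YAML so that a run can be reproduced from its provenance log.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import yaml


def _pair(value, name: str) -> tuple[float, float]:
    try:
        mean, sd = value
    except (TypeError, ValueError):
        raise ValueError(f"{name} must be a (mean, sd) pair, got {value!r}")
    mean, sd = float(mean), float(sd)
    if sd < 0:
        raise ValueError(f"{name} SD must be >= 0, got {sd}")
    return mean, sd


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic well.

    The defaults emulate the experimental regime the pipeline targets:
    a standard 96-well (6,400 µm diameter) imaged as 16-bit grayscale,
    cells placed uniformly over the well disc unless ``edge_bias`` > 0
    pushes probability mass toward the rim, and a βIII-tubulin intensity
    model with soma / neurite / background means of 2542 / 769 / 264
    counts — the measured three-compartment contrast of a differentiated
    SH-SY5Y network, in which soma intensity is roughly three times
    neurite intensity and faint distal neurites sit close to background.

    Parameters
    ----------
    well_diameter_um:
        Physical diameter of the simulated well disc.
    pixel_size_um:
        Pixel pitch of the rendered rasters.  0.65 µm corresponds to a
        nominal 20x objective; full-well scans are typically rendered at
        a coarser pitch (e.g. 6.4 µm) to keep rasters manageable.
    n_cells:
        Number of cells placed in the well.
    edge_bias:
        Dimensionless >= 0.  0 gives uniform-over-area placement; larger
        values concentrate cells toward the rim (the plating edge
        effect).  See :func:`neurowell.simulate.sample_positions`.
    nucleus_radius_um, soma_radius_um:
        (mean, sd) of per-cell disc radii for the Hoechst nucleus and
        the βIII-tubulin soma.
    dead_fraction:
        Probability in [0, 1] that a cell is dead.  Dead cells are
        EthD-1 positive and calcein negative and grow no neurites.
    neurites_per_cell:
        Inclusive (low, high) integer range; each live cell grows a
        uniform draw from it.
    neurite_length_um:
        (mean, sd) of the per-neurite path length.  Neurites are
        piecewise-linear random walks with 5 µm steps and Gaussian
        turning angles (SD 20°), so their analytic length is known.
    intensity_*:
        (mean, sd) of the per-cell (or per-compartment) rendered counts.
    noise_sd:
        Additive Gaussian read-noise SD applied to every channel before
        clipping to [0, 65535] and quantising to uint16.
    seed:
        Seed for all randomness; identical configs render bit-identical
        images and ground truth.
    """

    well_diameter_um: float = 6400.0
    pixel_size_um: float = 0.65
    n_cells: int = 2500
    edge_bias: float = 0.0
    nucleus_radius_um: tuple[float, float] = (5.0, 0.8)
    soma_radius_um: tuple[float, float] = (8.0, 1.5)
    dead_fraction: float = 0.0
    neurites_per_cell: tuple[int, int] = (1, 4)
    neurite_length_um: tuple[float, float] = (60.0, 20.0)
    neurite_step_um: float = 5.0
    neurite_turn_sd_deg: float = 20.0
    neurite_width_um: float = 2.0
    intensity_soma: tuple[float, float] = (2542.0, 743.0)
    intensity_neurite: tuple[float, float] = (769.0, 327.0)
    intensity_background: tuple[float, float] = (264.0, 35.0)
    intensity_nucleus: tuple[float, float] = (2000.0, 400.0)
    intensity_calcein: tuple[float, float] = (2500.0, 500.0)
    intensity_ethd1: tuple[float, float] = (2500.0, 500.0)
    noise_sd: float = 35.0
    channels: tuple[str, ...] = ("hoechst", "biii", "calcein", "ethd1")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError(f"n_cells must be >= 0, got {self.n_cells}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.well_diameter_um <= 0:
            raise ValueError("well_diameter_um must be > 0")
        if self.edge_bias < 0:
            raise ValueError("edge_bias must be >= 0")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError(f"dead_fraction must be in [0, 1], got {self.dead_fraction}")
        for name in (
            "nucleus_radius_um", "soma_radius_um", "neurite_length_um",
            "intensity_soma", "intensity_neurite", "intensity_background",
            "intensity_nucleus", "intensity_calcein", "intensity_ethd1",
        ):
            object.__setattr__(self, name, _pair(getattr(self, name), name))
        for name in ("intensity_soma", "intensity_neurite", "intensity_background",
                     "intensity_nucleus", "intensity_calcein", "intensity_ethd1"):
            mean = getattr(self, name)[0]
            if not 0 <= mean <= 65535:
                raise ValueError(f"{name} mean must fit 16 bits, got {mean}")
        lo, hi = self.neurites_per_cell
        if not (0 <= lo <= hi):
            raise ValueError(f"neurites_per_cell must satisfy 0 <= low <= high, got {self.neurites_per_cell}")
        object.__setattr__(self, "neurites_per_cell", (int(lo), int(hi)))
        if self.well_radius_um <= 2 * self.nucleus_radius_um[0]:
            raise ValueError("well radius must exceed twice the mean nucleus radius")

    @property
    def well_radius_um(self) -> float:
        return self.well_diameter_um / 2.0

    def to_yaml(self, stream: IO[str] | str | Path | None = None) -> str | None:
        data = dataclasses.asdict(self)
        data = {k: list(v) if isinstance(v, tuple) else v for k, v in data.items()}
        if stream is None:
            return yaml.safe_dump(data, sort_keys=True)
        if isinstance(stream, (str, Path)):
            Path(stream).write_text(yaml.safe_dump(data, sort_keys=True))
            return None
        yaml.safe_dump(data, stream, sort_keys=True)
        return None

    @classmethod
    def from_yaml(cls, source: IO[str] | str | Path) -> "SimulationConfig":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            text = Path(source).read_text()
        elif isinstance(source, str):
            text = source
        else:
            text = source.read()
        data = yaml.safe_load(text)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        for key, value in data.items():
            if isinstance(value, list):
                data[key] = tuple(value)
        return cls(**data)


@dataclass
class GeometryConfig:
    """Five-region well partition: an equal-area central disc plus the
    surrounding annulus split into quadrant sectors.

    With ``n_sectors`` sectors the well is cut into ``n_sectors + 1``
    equal-area regions when ``center_area_fraction = 1/(n_sectors+1)``;
    the defaults give the five-region layout (center disc of radius
    R/sqrt(5) plus four quadrants of the outer annulus).
    """

    center_area_fraction: float = 0.2
    n_sectors: int = 4
    sector_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.center_area_fraction < 1:
            raise ValueError("center_area_fraction must be in (0, 1)")
        if self.n_sectors < 1:
            raise ValueError("n_sectors must be >= 1")

    @property
    def n_regions(self) -> int:
        return self.n_sectors + 1


@dataclass
class OccupancyConfig:
    """Foreground thresholding for percent cell-occupied area."""

    smooth_sigma_px: float = 2.0
    population_sd: bool = False  # False: sample SD (n-1), spreadsheet convention


@dataclass
class NucleiSegConfig:
    """Watershed nuclei segmentation parameters."""

    smooth_sigma_px: float = 2.0
    min_separation_um: float = 4.0
    min_area_fraction_of_median: float = 0.25
    min_contrast_separation: float = 4.0  # Otsu class separation, in background SDs


@dataclass
class NeuriteSegConfig:
    """Neurite-network segmentation parameters.

    Soma are thresholded at background mean + ``soma_k_sd`` background
    SDs and must overlap a nucleus; neurite foreground is the union of a
    global Otsu on the background-suppressed channel and a multi-scale
    ridge (tubeness) response thresholded at its own Otsu, which
    recovers faint distal neurites close to background.
    """

    soma_k_sd: float = 8.0
    soma_min_area_um2: float = 50.0
    soma_opening_um: float = 2.5
    tubeness_sigmas_px: tuple[float, ...] = (1.0, 2.0, 4.0)
    spur_prune_um: float = 3.0
    smooth_sigma_px: float = 1.0
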