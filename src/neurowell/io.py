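"""File formats, plate layouts and provenance for the pipeline.

Images are single-plane grayscale TIFFs; 16-bit is the native depth
and 8-bit inputs are promoted (v → v·257) with a warning.  Tabular
output is plain CSV.  Every pipeline run can write a provenance record
(config hash, seed, package versions) so results are reproducible from
the log alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("neurowell")

__all__ = [
    "read_image",
    "write_image",
    "PlateLayout",
    "WellInfo",
    "provenance_record",
    "WELL_ID_PATTERN",
]

WELL_ID_PATTERN = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")

_UM_PER_UNIT = {2: 25400.0, 3: 10000.0}  # TIFF ResolutionUnit: inch, cm


def read_image(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a single-plane grayscale TIFF.

    Returns the raster as uint16 plus a metadata dict; ``pixel_size_um``
    is populated from the TIFF resolution tags when present, otherwise
    ``None`` (take it from the run config).  RGB images and multi-page
    stacks are rejected; 8-bit input is promoted to 16-bit (v·257) with
    a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"multi-page stacks are unsupported: {path}")
        page = tif.pages[0]
        arr = page.asarray()
        meta: dict = {"path": str(path), "pixel_size_um": None}
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and unit is not None:
            num, den = res.value
            unit_um = _UM_PER_UNIT.get(int(unit.value))
            if unit_um and num:
                meta["pixel_size_um"] = unit_um * den / num
    if arr.ndim != 2:
        raise ValueError(f"RGB or multi-channel TIFFs are unsupported: {path} "
                         f"(shape {arr.shape})")
    if arr.dtype == np.uint8:
        warnings.warn(f"8-bit input promoted to 16-bit: {path}", stacklevel=2)
        arr = arr.astype(np.uint16) * 257
    elif arr.dtype != np.uint16:
        raise ValueError(f"unsupported TIFF sample format {arr.dtype}: {path}")
    return arr, meta


def write_image(path: str | Path, raster: np.ndarray,
                pixel_size_um: float | None = None) -> Path:
    """Write a uint16 single-plane grayscale TIFF (resolution tags in cm)."""
    path = Path(path)
    arr = np.asarray(raster)
    if arr.dtype != np.uint16:
        raise ValueError(f"expected a uint16 raster, got {arr.dtype}")
    kwargs = {}
    if pixel_size_um:
        px_per_cm = 10000.0 / pixel_size_um
        kwargs = {"resolution": (px_per_cm, px_per_cm), "resolutionunit": "CENTIMETER"}
    tifffile.imwrite(path, arr, photometric="minisblack", **kwargs)
    return path


@dataclass
class WellInfo:
    """Layout entry for one well."""

    well: str
    condition: str
    treatment: str = ""
    concentration: float | None = None
    concentration_unit: str = ""
    arm: str = "differentiated"
    timepoint: str = ""

    def __post_init__(self) -> None:
        if not WELL_ID_PATTERN.match(self.well):
            raise ValueError(f"invalid 96-well ID {self.well!r} (expect A1..H12)")


@dataclass
class PlateLayout:
    """Mapping of 96-well IDs to experimental conditions."""

    plate_id: str
    wells: dict[str, WellInfo] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateLayout":
        data = yaml.safe_load(Path(path).read_text())
        plate_id = data.get("plate_id", Path(path).stem)
        wells: dict[str, WellInfo] = {}
        offenders = []
        for entry in data.get("wells", []):
            well = entry.get("well", "")
            if not WELL_ID_PATTERN.match(str(well)):
                offenders.append(str(well))
                continue
            if well in wells:
                raise ValueError(f"duplicate well ID {well!r} in layout {path}")
            wells[well] = WellInfo(**entry)
        if offenders:
            raise ValueError(f"unknown well IDs in layout {path}: {offenders}")
        return cls(plate_id=plate_id, wells=wells)

    def condition_of(self, well: str) -> str:
        if well not in self.wells:
            raise KeyError(f"well {well!r} not in layout {self.plate_id!r}")
        return self.wells[well].condition


def provenance_record(config: object, seed: int | None = None) -> dict:
    """Provenance dict: canonical config hash, seed and library versions."""
    import neurowell

    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    elif isinstance(config, dict):
        payload = config
    else:
        payload = {"repr": repr(config)}
    canonical = json.dumps(payload, sort_keys=True, default=str)
    import skimage

    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "neurowell": neurowell.__version__,
        "numpy": np.__version__,
        "scikit-image": skimage.__version__,
    }
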