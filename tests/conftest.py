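import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from neurowell import neurites, simulate
from neurowell.config import SimulationConfig

# 2,500 cells per 6,400 µm well, as cells/µm² — the plating density the
# differentiation protocol settles on
DENSITY_2500 = 2500.0 / (math.pi * 3200.0**2)
DENSITY_15000 = 15000.0 / (math.pi * 3200.0**2)


def field_config(n_cells: int, density: float, seed: int, **overrides) -> SimulationConfig:
    """Config for a circular field holding n_cells at the given areal density."""
    diameter = 2.0 * math.sqrt(n_cells / density / math.pi)
    defaults = dict(well_diameter_um=diameter, pixel_size_um=0.65, n_cells=n_cells,
                    seed=seed, neurites_per_cell=(1, 4), neurite_length_um=(60.0, 20.0))
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def neurite_field():
    """One mid-size simulated neurite field shared across read-only tests."""
    cfg = field_config(13, DENSITY_2500, seed=12)
    scan, truth = simulate.render_well(cfg)
    comp = neurites.make_composite(scan.channel("hoechst"), scan.channel("biii"),
                                   cfg.pixel_size_um)
    net = neurites.segment_neurites(comp)
    return cfg, scan, truth, comp, net


@pytest.fixture(scope="session")
def uniform_well_scan():
    """A full-well scan at coarse pixel pitch with uniform plating."""
    cfg = SimulationConfig(pixel_size_um=6.4, n_cells=10_000, edge_bias=0.0,
                           neurites_per_cell=(0, 0), seed=7, channels=("hoechst",))
    scan, truth = simulate.render_well(cfg)
    return cfg, scan, truth
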