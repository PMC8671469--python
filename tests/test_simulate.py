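"""Simulator: placement statistics, rendering fidelity, determinism."""

import dataclasses
import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from neurowell import homogeneity, simulate
from neurowell.config import SimulationConfig

from conftest import field_config, DENSITY_2500


def small_cfg(**kw):
    defaults = dict(well_diameter_um=400.0, pixel_size_um=1.3, n_cells=20,
                    neurites_per_cell=(0, 0), seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSamplePositions:
    def test_zero_cells_gives_empty_ground_truth(self):
        scan, truth = simulate.render_well(small_cfg(n_cells=0))
        assert truth.nuclei_count == 0
        assert len(truth.cell_centers) == 0
        assert sum(truth.per_region_counts.values()) == 0
        assert truth.total_neurite_length_um == 0.0

    def test_negative_cell_count_rejected(self):
        with pytest.raises(ValueError, match="n_cells"):
            small_cfg(n_cells=-1)

    def test_uniform_radial_density_over_disc(self):
        # uniform-over-area sampling puts (R/2)²/R² = 25% of mass inside R/2
        cfg = small_cfg(n_cells=10_000, edge_bias=0.0, seed=3)
        pos = simulate.sample_positions(cfg)
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert np.all(r < cfg.well_radius_um)
        frac_inner = np.mean(r < cfg.well_radius_um / 2)
        assert frac_inner == pytest.approx(0.25, abs=0.02)

    def test_edge_bias_concentrates_mass_at_rim(self):
        # uniform expectation for the r > 0.9R annulus is 1 - 0.9² = 0.19
        cfg = small_cfg(n_cells=10_000, edge_bias=5.0, seed=3)
        pos = simulate.sample_positions(cfg)
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert np.mean(r > 0.9 * cfg.well_radius_um) > 0.19

    @given(bias=st.floats(0.0, 20.0))
    def test_positions_always_inside_disc(self, bias):
        cfg = small_cfg(n_cells=200, edge_bias=bias, seed=1)
        pos = simulate.sample_positions(cfg)
        assert np.all(np.hypot(pos[:, 0], pos[:, 1]) <= cfg.well_radius_um)


class TestRenderWell:
    def test_seed_determinism_bit_identical(self):
        cfg = small_cfg(n_cells=50, neurites_per_cell=(1, 3), seed=9)
        scan1, truth1 = simulate.render_well(cfg)
        scan2, truth2 = simulate.render_well(cfg)
        for name in cfg.channels:
            assert np.array_equal(scan1.channel(name), scan2.channel(name))
        assert np.array_equal(truth1.cell_centers, truth2.cell_centers)
        assert truth1.total_neurite_length_um == truth2.total_neurite_length_um

    def test_region_counts_conserve_cells(self):
        scan, truth = simulate.render_well(small_cfg(n_cells=500, seed=2))
        assert sum(truth.per_region_counts.values()) == 500

    def test_no_neurites_means_background_only_channel(self):
        cfg = small_cfg(n_cells=30, neurites_per_cell=(0, 0), seed=4)
        scan, truth = simulate.render_well(cfg)
        assert truth.total_neurite_length_um == 0.0
        biii = scan.channel("biii").astype(float)
        outside_soma = biii[~truth.soma_mask]
        # background mean ± noise only, no neurite structures
        assert outside_soma.mean() == pytest.approx(cfg.intensity_background[0], rel=0.02)

    def test_straight_neurite_has_exact_analytic_length(self):
        cfg = small_cfg(n_cells=1, neurites_per_cell=(1, 1),
                        neurite_length_um=(100.0, 1e-9),
                        neurite_turn_sd_deg=1e-9, seed=5)
        _, truth = simulate.render_well(cfg)
        assert truth.total_neurite_length_um == pytest.approx(100.0)

    def test_intensity_fidelity_masked_means_within_5pct(self):
        cfg = field_config(60, DENSITY_2500, seed=8)
        scan, truth = simulate.render_well(cfg)
        biii = scan.channel("biii").astype(float)
        assert biii[truth.soma_mask].mean() == pytest.approx(
            cfg.intensity_soma[0], rel=0.05)
        assert biii[truth.neurite_mask].mean() == pytest.approx(
            cfg.intensity_neurite[0], rel=0.05)
        assert biii[truth.background_mask].mean() == pytest.approx(
            cfg.intensity_background[0], rel=0.05)

    def test_soma_to_neurite_contrast_near_three(self):
        cfg = field_config(60, DENSITY_2500, seed=8)
        scan, truth = simulate.render_well(cfg)
        biii = scan.channel("biii").astype(float)
        ratio = biii[truth.soma_mask].mean() / biii[truth.neurite_mask].mean()
        assert 3.0 <= ratio <= 3.6

    def test_live_dead_channel_assignment(self):
        cfg = small_cfg(n_cells=200, dead_fraction=0.4, seed=6,
                        channels=("calcein", "ethd1"))
        scan, truth = simulate.render_well(cfg)
        cal = scan.channel("calcein").astype(float)
        eth = scan.channel("ethd1").astype(float)
        bg = cfg.intensity_background[0]
        # calcein carries structure only where cells are alive, EthD-1 only dead
        assert cal.max() > bg + 10 * cfg.noise_sd
        assert eth.max() > bg + 10 * cfg.noise_sd
        assert 0 < (~truth.alive_flags).sum() < 200

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            simulate.render_well(
                SimulationConfig(well_diameter_um=30.0, pixel_size_um=30.0,
                                 n_cells=1, nucleus_radius_um=(5.0, 0.1)))

    def test_occupancy_sd_monotone_in_edge_bias(self):
        # the homogeneity score, averaged over seeds, must not decrease
        # as cells are pushed toward the rim
        biases = [0.0, 1.0, 3.0, 5.0]
        n_seeds = 20
        means = []
        for bias in biases:
            scores = []
            for seed in range(n_seeds):
                cfg = SimulationConfig(pixel_size_um=12.8, n_cells=10_000,
                                       edge_bias=bias, neurites_per_cell=(0, 0),
                                       seed=seed, channels=("hoechst",))
                scan, _ = simulate.render_well(cfg)
                part = homogeneity.partition_well(scan)
                scores.append(homogeneity.compute_occupancy(scan, part).homogeneity_sd)
            means.append(np.mean(scores))
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))


class TestReaderTable:
    def test_background_subtraction_recovers_configured_signal(self):
        # a 14.66-unit calcein signal above a 2.0 blank survives the
        # write → read → subtract round trip untouched
        table = simulate.simulate_reader_table(
            {"A1": (14.66 + 2.0, 0.0891 + 2.0)}, background=(2.0, 2.0))
        from neurowell.cells import viability_table
        out = viability_table(table)
        assert out.loc[0, "calcein_signal"] == pytest.approx(14.66)
        assert out.loc[0, "ethd1_signal"] == pytest.approx(0.0891)

    def test_all_zero_signals_are_a_valid_table(self):
        table = simulate.simulate_reader_table({"A1": (0.0, 0.0)}, background=(0.0, 0.0))
        assert (table["emission"] == 0).all()

    def test_csv_round_trip_is_exact(self):
        wells = {f"A{i}": (14.0 + i, 0.5 * i) for i in range(1, 13)}
        table = simulate.simulate_reader_table(wells, background=(2.0, 1.5),
                                               noise_sd=0.3, seed=11)
        buf = io.StringIO()
        table.to_csv(buf, index=False)
        buf.seek(0)
        from neurowell.cells import read_reader_table
        back = read_reader_table(buf)
        assert np.array_equal(back["emission"].to_numpy(), table["emission"].to_numpy())

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_reader_table({"A1": (-1.0, 0.0)}, background=(0.0, 0.0))


class TestConfig:
    def test_yaml_round_trip(self):
        cfg = small_cfg(n_cells=42, edge_bias=2.5, seed=13)
        text = cfg.to_yaml()
        assert SimulationConfig.from_yaml(text) == cfg

    @pytest.mark.parametrize("bad", [
        {"dead_fraction": 1.5},
        {"pixel_size_um": 0.0},
        {"edge_bias": -1.0},
        {"intensity_soma": (70000.0, 10.0)},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            small_cfg(**bad)
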