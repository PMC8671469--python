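"""Neurite segmentation, skeletal length and the outgrowth ratio."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from skimage.morphology import skeletonize

from neurowell import cells, neurites, simulate
from neurowell.cells import NucleiSet
from neurowell.config import NeuriteSegConfig
from neurowell.neurites import (NeuriteNetwork, intensity_profile, make_composite,
                                outgrowth_ratio, prune_spurs, segment_neurites,
                                skeleton_length_um)

from conftest import field_config, DENSITY_2500


def bar_composite(width=3, length=201, value=2000, bg=264):
    img = np.full((60, length + 60), float(bg))
    img[30:30 + width, 30:30 + length] = value
    return make_composite(np.zeros_like(img), img.astype(np.uint16), 1.0)


class TestComposite:
    def test_channels_stored_losslessly(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 65535, (512, 512)).astype(np.uint16)
        b = rng.integers(0, 65535, (512, 512)).astype(np.uint16)
        comp = make_composite(a, b, 0.65)
        assert np.array_equal(comp.nuclei_channel, a)
        assert np.array_equal(comp.neurite_channel, b)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            make_composite(np.zeros((10, 10)), np.zeros((12, 10)), 1.0)

    def test_round_trip_through_tiff(self, tmp_path):
        from neurowell.io import read_image, write_image
        rng = np.random.default_rng(1)
        a = rng.integers(0, 65535, (64, 64)).astype(np.uint16)
        write_image(tmp_path / "x.tif", a, pixel_size_um=0.65)
        back, _ = read_image(tmp_path / "x.tif")
        assert np.array_equal(back, a)


class TestSegmentation:
    def test_straight_bar_length(self):
        # a noise-free 3-px bar spanning 201 px at 1 µm/px skeletonizes
        # to its 200 µm midline
        net = segment_neurites(bar_composite())
        assert net.total_length_um == pytest.approx(200.0, abs=2.0)

    def test_blank_channel_gives_zero_length(self):
        comp = make_composite(np.zeros((64, 64)), np.zeros((64, 64)), 1.0)
        net = segment_neurites(comp)
        assert net.total_length_um == 0.0

    def test_skeleton_disjoint_from_soma(self, neurite_field):
        *_, net = neurite_field
        assert not np.logical_and(net.skeleton, net.soma_mask).any()

    def test_skeleton_idempotent(self, neurite_field):
        *_, net = neurite_field
        assert np.array_equal(skeletonize(net.skeleton), net.skeleton)

    def test_length_recovery_against_ground_truth(self, neurite_field):
        cfg, scan, truth, comp, net = neurite_field
        assert net.total_length_um == pytest.approx(
            truth.total_neurite_length_um, rel=0.15)

    def test_length_additive_over_disjoint_fields(self):
        cfg_a = field_config(8, DENSITY_2500, seed=31)
        cfg_b = field_config(8, DENSITY_2500, seed=32)
        scans = [simulate.render_well(c)[0] for c in (cfg_a, cfg_b)]
        nets = [segment_neurites(make_composite(
            s.channel("hoechst"), s.channel("biii"), 0.65)) for s in scans]
        merged_nuc = np.hstack([s.channel("hoechst") for s in scans])
        merged_neu = np.hstack([s.channel("biii") for s in scans])
        merged = segment_neurites(make_composite(merged_nuc, merged_neu, 0.65))
        total = nets[0].total_length_um + nets[1].total_length_um
        assert merged.total_length_um == pytest.approx(total, rel=0.01)

    def test_translation_invariance(self, neurite_field):
        cfg, scan, truth, comp, net = neurite_field
        shifted = make_composite(np.roll(comp.nuclei_channel, (7, -5), axis=(0, 1)),
                                 np.roll(comp.neurite_channel, (7, -5), axis=(0, 1)),
                                 comp.pixel_size_um)
        net2 = segment_neurites(shifted)
        assert net2.total_length_um == pytest.approx(net.total_length_um, rel=0.005)


class TestPruning:
    def test_short_spur_removed_long_branch_kept(self):
        skel = np.zeros((40, 60), dtype=bool)
        skel[20, 5:55] = True   # 50-px main branch
        skel[17:20, 30] = True  # 3-px spur off its middle
        pruned = prune_spurs(skel, min_length_px=5)
        assert not pruned[17:20, 30].any()
        assert pruned[20, 5:55].all()

    def test_long_segment_survives_pruning(self):
        skel = np.zeros((20, 60), dtype=bool)
        skel[10, 5:55] = True
        assert np.array_equal(prune_spurs(skel, min_length_px=5), skel)


class TestOutgrowthRatio:
    def test_arithmetic(self):
        net = NeuriteNetwork(np.zeros((4, 4), bool), np.zeros((4, 4), bool), 500.0)
        nuclei = NucleiSet(np.zeros((100, 2)), 100)
        assert outgrowth_ratio(net, nuclei) == 5.0

    def test_zero_length_gives_zero_ratio(self):
        net = NeuriteNetwork(np.zeros((4, 4), bool), np.zeros((4, 4), bool), 0.0)
        assert outgrowth_ratio(net, NucleiSet(np.zeros((10, 2)), 10)) == 0.0

    def test_zero_nuclei_rejected(self):
        net = NeuriteNetwork(np.zeros((4, 4), bool), np.zeros((4, 4), bool), 10.0)
        with pytest.raises(ValueError, match="zero nuclei"):
            outgrowth_ratio(net, NucleiSet(np.empty((0, 2)), 0))

    def test_threefold_length_contrast_recovered(self):
        # per-cell neurite length 20 vs 60 µm should yield outgrowth
        # ratios differing by a factor 3 ± 20%
        ratios = []
        for mean_len, seed in ((20.0, 41), (60.0, 42)):
            rec = true = 0.0
            counts = 0
            for s in range(3):
                cfg = field_config(13, DENSITY_2500, seed=seed + 10 * s,
                                   neurite_length_um=(mean_len, mean_len / 4))
                scan, truth = simulate.render_well(cfg)
                comp = make_composite(scan.channel("hoechst"), scan.channel("biii"),
                                      0.65)
                net = segment_neurites(comp)
                rec += net.total_length_um
                counts += truth.nuclei_count
            ratios.append(rec / counts)
        assert ratios[1] / ratios[0] == pytest.approx(3.0, rel=0.2)

    def test_monotone_dose_response(self):
        # outgrowth ratio rises strictly with configured per-cell length
        lengths = [20.0, 40.0, 60.0, 80.0]
        mean_ratios = []
        for li, mean_len in enumerate(lengths):
            per_seed = []
            for s in range(4):
                cfg = field_config(8, DENSITY_2500, seed=100 * li + s,
                                   neurite_length_um=(mean_len, mean_len / 4))
                scan, truth = simulate.render_well(cfg)
                net = segment_neurites(make_composite(
                    scan.channel("hoechst"), scan.channel("biii"), 0.65))
                per_seed.append(net.total_length_um / truth.nuclei_count)
            mean_ratios.append(np.mean(per_seed))
        rho, _ = spearmanr(lengths, mean_ratios)
        assert rho == 1.0


class TestIntensityProfile:
    def test_constant_image_has_zero_sd(self):
        img = np.full((50, 50), 500, dtype=np.uint16)
        comp = make_composite(np.zeros_like(img), img, 1.0)
        masks = [np.zeros((50, 50), bool) for _ in range(3)]
        masks[0][:10], masks[1][20:30], masks[2][40:] = True, True, True
        prof = intensity_profile(comp, *masks)
        assert all(v["sd"] == 0.0 for v in prof.values())

    def test_overlapping_masks_rejected(self):
        img = np.zeros((20, 20), dtype=np.uint16)
        comp = make_composite(img, img, 1.0)
        m = np.ones((20, 20), bool)
        with pytest.raises(ValueError, match="disjoint"):
            intensity_profile(comp, m, m, np.zeros((20, 20), bool))

    def test_empty_compartment_flagged(self):
        img = np.full((20, 20), 100, dtype=np.uint16)
        comp = make_composite(np.zeros_like(img), img, 1.0)
        empty = np.zeros((20, 20), bool)
        some = np.zeros((20, 20), bool)
        some[5] = True
        other = np.zeros((20, 20), bool)
        other[10] = True
        prof = intensity_profile(comp, empty, some, other)
        assert prof["soma"]["flagged"]
        assert not prof["neurite"]["flagged"]

    def test_compartment_recovery_on_simulated_field(self):
        cfg = field_config(60, DENSITY_2500, seed=8)
        scan, truth = simulate.render_well(cfg)
        comp = make_composite(scan.channel("hoechst"), scan.channel("biii"), 0.65)
        prof = intensity_profile(comp, truth.soma_mask, truth.neurite_mask,
                                 truth.background_mask, n_points=5000)
        assert prof["soma"]["mean"] == pytest.approx(2542, rel=0.05)
        assert prof["neurite"]["mean"] == pytest.approx(769, rel=0.05)
        assert prof["background"]["mean"] == pytest.approx(264, rel=0.05)
        assert 3.0 <= prof["soma"]["mean"] / prof["neurite"]["mean"] <= 3.6
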