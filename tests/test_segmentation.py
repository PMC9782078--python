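import itertools

import numpy as np
import pytest

from ctcfi.phantom import make_colon_phantom, straight_tube_spec
from ctcfi.segmentation import (IntensityModel, LabelVolume, MRFConfig,
                                SegmentationFailure, fit_intensity_models,
                                graphcut_segment, grow_fluid, iou,
                                label_components, mrf_energy, segment_colon,
                                select_colon, threshold_air)
from ctcfi.volume import CTVolume


def brute_force_minimum(hu, model, config):
    """Independent oracle: enumerate all labelings of a tiny grid."""
    best = np.inf
    for bits in itertools.product([0, 1], repeat=hu.size):
        lab = np.array(bits, dtype=np.uint8).reshape(hu.shape)
        e = mrf_energy(CTVolume(hu), LabelVolume(lab), model, config)
        best = min(best, e)
    return best


class TestThresholdAndComponents:
    def test_all_air_volume_fully_masked(self):
        vol = CTVolume(np.full((4, 4, 4), -1000.0))
        out = threshold_air(vol, MRFConfig(air_threshold_hu=-800))
        assert out.air_mask.all()

    def test_all_tissue_volume_empty_mask(self):
        vol = CTVolume(np.zeros((4, 4, 4)))
        out = threshold_air(vol, MRFConfig(air_threshold_hu=-800))
        assert not out.air_mask.any()

    def test_phantom_threshold_recovers_lumen_count(self, straight_phantom):
        volume, truth = straight_phantom
        out = threshold_air(volume, MRFConfig())
        # exterior air is also below threshold; take the lumen's own component
        comps = label_components(out, 6)
        lumen_id = comps.component_ids[32, 32, 32]
        got = (comps.component_ids == lumen_id).sum()
        assert got == pytest.approx(truth.colon_mask.sum(), rel=0.05)

    def test_two_cubes_two_components(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[1:3, 1:3, 1:3] = 1
        labels[5:7, 5:7, 5:7] = 1
        out = label_components(LabelVolume(labels), 6)
        assert out.component_ids.max() == 2

    def test_empty_mask_zero_components(self):
        out = label_components(LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8)), 6)
        assert out.component_ids.max() == 0

    def test_phantom_lumen_separated_from_exterior(self, straight_phantom):
        volume, truth = straight_phantom
        comps = label_components(threshold_air(volume, MRFConfig()), 6)
        center_id = comps.component_ids[32, 32, 32]
        corner_id = comps.component_ids[32, 1, 1]
        assert center_id > 0 and corner_id > 0 and center_id != corner_id


class TestIntensityModels:
    def test_exact_two_constant_volume(self):
        hu = np.where(np.arange(64).reshape(4, 4, 4) % 2 == 0, -1000.0, 40.0)
        init = LabelVolume(np.where(hu < -500, 1, 0).astype(np.uint8))
        m = fit_intensity_models(CTVolume(hu), init, pooled_sigma=False)
        assert m.mean_air == pytest.approx(-1000)
        assert m.mean_background == pytest.approx(40)
        assert m.sigma_air == 1.0  # floor

    def test_label_swap_swaps_models(self):
        rng = np.random.default_rng(0)
        hu = rng.normal(0, 100, (4, 4, 4))
        init = LabelVolume((hu < 0).astype(np.uint8))
        swapped = LabelVolume((hu >= 0).astype(np.uint8))
        a = fit_intensity_models(CTVolume(hu), init, pooled_sigma=False)
        b = fit_intensity_models(CTVolume(hu), swapped, pooled_sigma=False)
        assert a.mean_air == pytest.approx(b.mean_background)
        assert a.mean_background == pytest.approx(b.mean_air)

    def test_tiny_label_rejected(self):
        hu = np.zeros((3, 3, 3))
        init = LabelVolume(np.zeros((3, 3, 3), dtype=np.uint8))
        init.labels[0, 0, 0] = 1
        with pytest.raises(ValueError):
            fit_intensity_models(CTVolume(hu), init)


class TestMRFEnergy:
    model = IntensityModel(-1000, 100, 40, 100)

    def test_uniform_labeling_has_zero_pairwise_term(self):
        hu = np.full((3, 3, 3), -500.0)
        cfg0 = MRFConfig(lambda_pairwise=0.0)
        cfg5 = MRFConfig(lambda_pairwise=5.0)
        uniform = LabelVolume(np.ones((3, 3, 3), dtype=np.uint8))
        e0 = mrf_energy(CTVolume(hu), uniform, self.model, cfg0)
        e5 = mrf_energy(CTVolume(hu), uniform, self.model, cfg5)
        assert e0 == pytest.approx(e5)

    def test_decoupled_minimum_at_lambda_zero(self):
        rng = np.random.default_rng(3)
        hu = rng.normal(-500, 400, (2, 2, 2))
        cfg = MRFConfig(lambda_pairwise=0.0)
        cost_bg, cost_air = self.model.data_cost(hu)
        ml = LabelVolume((cost_air < cost_bg).astype(np.uint8))
        e_ml = mrf_energy(CTVolume(hu), ml, self.model, cfg)
        assert e_ml == pytest.approx(np.minimum(cost_bg, cost_air).sum())
        assert e_ml <= brute_force_minimum(hu, self.model, cfg) + 1e-9

    def test_energy_matches_hand_sum_on_2x2x2(self):
        rng = np.random.default_rng(4)
        hu = rng.normal(-500, 400, (2, 2, 2))
        cfg = MRFConfig(lambda_pairwise=2.0)
        lab = rng.integers(0, 2, (2, 2, 2)).astype(np.uint8)
        # independent hand computation over explicit voxel/pair lists
        cost_bg, cost_air = self.model.data_cost(hu)
        e_data = sum(cost_air[i] if lab[i] else cost_bg[i]
                     for i in np.ndindex(2, 2, 2))
        pairs = []
        for i in np.ndindex(2, 2, 2):
            for axis in range(3):
                j = list(i)
                j[axis] += 1
                if j[axis] < 2:
                    pairs.append((i, tuple(j)))
        e_pair = sum(2.0 for a, b in pairs if lab[a] != lab[b])
        expected = e_data + e_pair
        got = mrf_energy(CTVolume(hu), LabelVolume(lab), self.model, cfg)
        assert got == pytest.approx(expected)


class TestGraphCut:
    model = IntensityModel(-1000, 100, 40, 100)

    def test_lambda_zero_equals_maximum_likelihood(self):
        rng = np.random.default_rng(5)
        hu = rng.normal(-500, 400, (3, 3, 3))
        cfg = MRFConfig(lambda_pairwise=0.0)
        out = graphcut_segment(CTVolume(hu), self.model, cfg)
        cost_bg, cost_air = self.model.data_cost(hu)
        np.testing.assert_array_equal(out.air_mask, cost_air < cost_bg)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_optimum_on_random_2x2x2(self, seed):
        rng = np.random.default_rng(seed)
        hu = rng.normal(-500, 400, (2, 2, 2))
        cfg = MRFConfig(lambda_pairwise=1.5)
        out = graphcut_segment(CTVolume(hu), self.model, cfg)
        e = mrf_energy(CTVolume(hu), out, self.model, cfg)
        assert e == brute_force_minimum(hu, self.model, cfg)

    def test_energy_never_above_threshold_initialization(self, straight_phantom):
        volume, _ = straight_phantom
        cfg = MRFConfig()
        init = threshold_air(volume, cfg)
        model = fit_intensity_models(volume, init)
        refined = graphcut_segment(volume, model, cfg)
        assert (mrf_energy(volume, refined, model, cfg)
                <= mrf_energy(volume, init, model, cfg) + 1e-6)


class TestFluidGrowing:
    def test_phantom_without_pools_grows_nothing(self, straight_phantom):
        volume, truth = straight_phantom
        seg = segment_colon(volume)
        assert not seg.fluid_mask.any()

    def test_pool_recovered_from_truth(self):
        spec = straight_tube_spec((64, 64, 64), lumen_radius_mm=10.0,
                                  fluid_fill_fraction=0.3,
                                  fluid_segments=[(0.2, 0.6)], seed=2)
        volume, truth = make_colon_phantom(spec)
        seg = segment_colon(volume)
        assert iou(truth.fluid_mask, seg.fluid_mask) >= 0.95

    def test_high_hu_above_air_not_grown(self):
        hu = np.full((8, 8, 8), 40.0)
        hu[:, 4:6, :] = -1000.0     # air band
        hu[:, 1:3, :] = 500.0       # high HU *above* the air (gravity +y)
        labels = LabelVolume(np.where(hu < -800, 1, 0).astype(np.uint8))
        out = grow_fluid(CTVolume(hu), labels, MRFConfig(), "+y")
        assert not out.fluid_mask.any()

    def test_invalid_axis_rejected(self):
        labels = LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            grow_fluid(CTVolume(np.zeros((4, 4, 4))), labels, MRFConfig(), "+w")


class TestColonSelection:
    def test_phantom_exterior_rejected_lumen_kept(self, straight_phantom):
        volume, truth = straight_phantom
        comps = label_components(threshold_air(volume, MRFConfig()), 6)
        out = select_colon(comps, MRFConfig())
        assert iou(truth.colon_mask, out.air_mask) > 0.9

    def test_all_small_components_fail(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[3:5, 3:5, 3:5] = 1
        comps = label_components(LabelVolume(labels), 6)
        with pytest.raises(SegmentationFailure):
            select_colon(comps, MRFConfig(min_component_voxels=100))

    def test_two_interior_segments_both_kept(self):
        labels = np.zeros((24, 24, 24), dtype=np.uint8)
        labels[2:22, 4:9, 4:9] = 1
        labels[2:22, 14:19, 14:19] = 1
        comps = label_components(LabelVolume(labels), 6)
        out = select_colon(comps, MRFConfig(min_component_voxels=100))
        assert len(np.unique(out.component_ids)) == 3  # background + 2 segments


class TestIoU:
    def test_identical_masks(self):
        m = np.random.default_rng(0).random((4, 4, 4)) > 0.5
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        assert iou(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[0:2, 0:2, 0:2] = True
        b = np.zeros((4, 4, 4), dtype=bool)
        b[0:2, 0:2, 0:1] = True
        assert iou(a, b) == 0.5

    def test_both_empty_is_one(self):
        z = np.zeros((2, 2, 2), dtype=bool)
        assert iou(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iou(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))


def test_labels_partition_volume(straight_phantom):
    volume, _ = straight_phantom
    seg = segment_colon(volume)
    total = (seg.labels == 0).sum() + seg.air_mask.sum() + seg.fluid_mask.sum()
    assert total == volume.hu.size
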