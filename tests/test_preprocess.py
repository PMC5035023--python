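"""Merging, calibration and swap handling."""

from dataclasses import replace

import numpy as np
import pytest

from dixoncomp import phantom as ph
from dixoncomp import preprocess as pp
from dixoncomp.errors import (
    AdiposeReferenceError,
    StructuralError,
    ValidationError,
)
from dixoncomp.types import DixonVolume, Label

from conftest import make_constant_slabs


class TestMerge:
    def test_two_overlapping_slabs_give_expected_slice_count(self):
        slabs = make_constant_slabs(n_slices=44, overlap=8)
        vol = pp.merge_slabs(slabs)
        assert vol.shape[2] == 80  # 44 + 44 - 8

    def test_constant_intensity_preserved_exactly_in_overlap(self):
        slabs = make_constant_slabs(value=123.0)
        vol = pp.merge_slabs(slabs)
        assert np.all(vol.water == 123.0)
        assert np.all(vol.fat == 123.0)

    def test_single_slab_is_identity(self):
        slabs = make_constant_slabs()[:1]
        slabs[0].water[3, 4, 10] = 7.5
        vol = pp.merge_slabs(slabs)
        np.testing.assert_array_equal(vol.water, slabs[0].water)
        assert vol.shape[2] == slabs[0].n_slices

    def test_no_slabs_rejected(self):
        with pytest.raises(ValidationError):
            pp.merge_slabs([])

    def test_in_plane_mismatch_rejected(self):
        slabs = make_constant_slabs()
        bad = replace(slabs[1], water=slabs[1].water[:-1],
                      fat=slabs[1].fat[:-1])
        with pytest.raises(StructuralError):
            pp.merge_slabs([slabs[0], bad])

    def test_missing_slab_leaves_recorded_gap_not_interpolation(self):
        res = ph.generate_phantom(ph.PhantomSpec(scale=4, seed=1))
        out = ph.inject_artifact(res.slabs, ph.ArtifactSpec("missing_slab",
                                                            {"index": 3}),
                                 geometry=res.geometry)
        vol = pp.merge_slabs(out)
        assert vol.coverage_gaps  # interior gap recorded
        for k in vol.coverage_gaps:
            assert vol.provenance[k] == ()
            assert np.all(vol.water[:, :, k] == 0)

    def test_overlap_provenance_lists_both_slabs(self):
        slabs = make_constant_slabs(n_slices=20, overlap=6)
        vol = pp.merge_slabs(slabs)
        both = [p for p in vol.provenance if p == (1, 2)]
        assert len(both) >= 5


class TestFatFraction:
    def test_pure_fat_water_and_noise_floor_cases(self):
        w = np.array([[[0.0, 80.0, 1.0]]], dtype=np.float32)
        f = np.array([[[100.0, 0.0, 1.0]]], dtype=np.float32)
        vol = DixonVolume(water=w, fat=f, voxel_size=(1, 1, 1))
        ff = pp.compute_fat_fraction(vol, noise_floor=5.0)
        assert ff.ff[0, 0, 0] == 1.0
        assert ff.ff[0, 0, 1] == 0.0
        assert not ff.valid_mask[0, 0, 2]  # below floor: excluded

    def test_negative_noise_floor_rejected(self):
        vol = DixonVolume(water=np.ones((2, 2, 2), dtype=np.float32),
                          fat=np.ones((2, 2, 2), dtype=np.float32),
                          voxel_size=(1, 1, 1))
        with pytest.raises(ValidationError):
            pp.compute_fat_fraction(vol, noise_floor=-1.0)


class TestAdiposeReference:
    def test_mask_is_subset_of_true_fat(self, phantom_s3_noiseless):
        res, vol = phantom_s3_noiseless
        ff = pp.compute_fat_fraction(vol)
        mask = pp.detect_pure_adipose(ff, vol)
        # evaluate the true tissue class on the composite grid
        geom = res.geometry
        x, y = geom.grid.in_plane_coords()
        f = geom.fields(x[:, None, None], y[None, :, None],
                        vol.z_positions[None, None, :])
        fat_true = geom.tissue_class(f) == 1
        # slab-to-composite resampling moves class boundaries by up to
        # half a slab slice, so allow a one-voxel halo around true fat
        from scipy.ndimage import binary_dilation
        halo = binary_dilation(fat_true, iterations=1)
        assert (mask & ~halo).sum() / mask.sum() < 0.005

    def test_all_water_volume_has_no_reference(self):
        w = np.full((8, 8, 8), 100.0, dtype=np.float32)
        f = np.zeros((8, 8, 8), dtype=np.float32)
        vol = DixonVolume(water=w, fat=f, voxel_size=(2, 2, 2))
        ff = pp.compute_fat_fraction(vol, noise_floor=1.0)
        with pytest.raises(AdiposeReferenceError):
            pp.detect_pure_adipose(ff, vol, min_component_voxels=1)


class TestCalibration:
    def test_pure_fat_mean_is_one_on_noiseless_phantom(self, phantom_s3_noiseless):
        _, vol = phantom_s3_noiseless
        ff = pp.compute_fat_fraction(vol)
        mask = pp.detect_pure_adipose(ff, vol)
        cal = pp.calibrate_volume(vol)
        assert abs(float(cal.fat[mask].mean()) - 1.0) < 0.01

    def test_identity_field_is_identity(self, phantom_s3):
        _, vol = phantom_s3
        field = pp.BiasField(field=np.ones(vol.shape, dtype=np.float32),
                             control_scale=60.0, voxel_size=vol.voxel_size)
        out = pp.calibrate(vol, field)
        np.testing.assert_array_equal(out.water, vol.water)
        np.testing.assert_array_equal(out.fat, vol.fat)

    def test_non_positive_field_rejected(self, phantom_s3):
        _, vol = phantom_s3
        with pytest.raises(ValidationError):
            pp.BiasField(field=np.zeros(vol.shape, dtype=np.float32),
                         control_scale=60.0, voxel_size=vol.voxel_size)

    def test_bias_recovery_within_three_percent(self, phantom_s3):
        res, vol = phantom_s3
        ff = pp.compute_fat_fraction(vol)
        mask = pp.detect_pure_adipose(ff, vol)
        field = pp.estimate_bias_field(vol, mask)
        truth = res.geometry.spec.s_fat * res.bias
        body = vol.total() > pp.default_noise_floor(vol)
        rel = np.abs(field.field[body] - truth[body]) / truth[body]
        assert float(np.median(rel)) < 0.03

    def test_uniform_intensity_gives_constant_field(self):
        rng = np.random.default_rng(0)
        f = np.full((16, 16, 12), 500.0, dtype=np.float32)
        w = np.full((16, 16, 12), 5.0, dtype=np.float32)
        vol = DixonVolume(water=w, fat=f, voxel_size=(20, 20, 20))
        mask = np.zeros(vol.shape, dtype=bool)
        mask[2:14, 2:14, 2:10] = True
        field = pp.estimate_bias_field(vol, mask)
        assert np.allclose(field.field, 500.0, rtol=1e-3)

    def test_calibration_is_scale_invariant(self, phantom_s3):
        _, vol = phantom_s3
        cal = pp.calibrate_volume(vol)
        k = 3.7
        scaled = replace(vol, water=vol.water * k, fat=vol.fat * k,
                         provenance=list(vol.provenance),
                         coverage_gaps=list(vol.coverage_gaps))
        cal_k = pp.calibrate_volume(scaled)
        body = vol.total() > pp.default_noise_floor(vol)
        np.testing.assert_allclose(cal_k.fat[body], cal.fat[body], rtol=1e-4)

    def test_recalibration_is_idempotent_within_one_percent(self, phantom_s3):
        _, vol = phantom_s3
        cal = pp.calibrate_volume(vol)
        cal2 = pp.calibrate_volume(cal)
        body = vol.total() > pp.default_noise_floor(vol)
        rel = np.abs(cal2.fat[body] - cal.fat[body]) / np.maximum(
            np.abs(cal.fat[body]), 1e-2)
        assert float(np.median(rel)) < 0.01


class TestIslandSwaps:
    def test_clean_phantom_has_no_flags(self, phantom_s3):
        _, vol = phantom_s3
        assert pp.detect_separate_island_swaps(vol) == []

    def test_injected_thigh_swap_is_flagged(self):
        res = ph.generate_phantom(ph.PhantomSpec(scale=4, seed=8))
        art = ph.ArtifactSpec("swap_separate_island", {"target": "right_thigh"})
        vol = pp.merge_slabs(ph.inject_artifact(res.slabs, art,
                                                geometry=res.geometry))
        comps = pp.detect_separate_island_swaps(vol)
        assert len(comps) == 1
        assert comps[0].subtype == "island"
        assert "right_thigh" in comps[0].description

    def test_both_thighs_swapped_gives_two_components(self):
        res = ph.generate_phantom(ph.PhantomSpec(scale=4, seed=8))
        slabs = res.slabs
        for target in ("right_thigh", "left_thigh"):
            slabs = ph.inject_artifact(
                slabs, ph.ArtifactSpec("swap_separate_island",
                                       {"target": target}),
                geometry=res.geometry)
        comps = pp.detect_separate_island_swaps(pp.merge_slabs(slabs))
        assert len(comps) == 2
        assert all(c.subtype == "island" for c in comps)

    def test_liver_top_reported_as_distinct_subtype(self):
        res = ph.generate_phantom(ph.PhantomSpec(scale=4, seed=8))
        vol = pp.merge_slabs(ph.inject_artifact(
            res.slabs, ph.ArtifactSpec("swap_liver_top"),
            geometry=res.geometry))
        comps = pp.detect_separate_island_swaps(vol)
        assert [c.subtype for c in comps] == ["liver_top"]

    def test_correct_swap_is_involution_and_liver_top_is_excluded(self):
        res = ph.generate_phantom(ph.PhantomSpec(scale=5, seed=8))
        vol = pp.merge_slabs(res.slabs)
        mask = np.zeros(vol.shape, dtype=bool)
        mask[5:15, 5:15, 10:30] = True
        comp = pp.SwapComponent(mask=mask, subtype="island")
        v1, excl = pp.correct_swap(vol, comp)
        assert excl is None
        assert not np.array_equal(v1.water, vol.water)
        v2, _ = pp.correct_swap(v1, comp)
        np.testing.assert_array_equal(v2.water, vol.water)
        np.testing.assert_array_equal(v2.fat, vol.fat)

        liver = pp.SwapComponent(mask=mask, subtype="liver_top")
        v3, excl = pp.correct_swap(vol, liver)
        np.testing.assert_array_equal(v3.water, vol.water)
        assert excl is not None and excl.any()

    def test_empty_component_is_noop(self, phantom_s3):
        _, vol = phantom_s3
        comp = pp.SwapComponent(mask=np.zeros(vol.shape, dtype=bool),
                                subtype="island")
        out, excl = pp.correct_swap(vol, comp)
        np.testing.assert_array_equal(out.water, vol.water)
        assert excl is None
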