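"""Registration, vote fusion and volume quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dixoncomp import phantom as ph
from dixoncomp import preprocess as pp
from dixoncomp import segmentation as seg
from dixoncomp import validation as V
from dixoncomp.errors import ValidationError
from dixoncomp.types import AtlasPrototype, Label, LabelMap

VOX = (2.0, 2.0, 2.0)


def lm(arr):
    return LabelMap(labels=np.asarray(arr, dtype=np.int16), voxel_size=VOX)


class TestFusion:
    def test_strict_threshold_boundary(self):
        """5 agreeing atlases stay background; 6 cross the '>5' bar."""
        shape = (1, 1, 2)
        maps = []
        for i in range(11):
            a = np.zeros(shape, dtype=np.int16)
            if i < 6:
                a[0, 0, 0] = int(Label.VAT)   # 6 votes at voxel 0
            if i < 5:
                a[0, 0, 1] = int(Label.VAT)   # 5 votes at voxel 1
            maps.append(lm(a))
        fused, votes = seg.fuse_labels(maps, vote_threshold=5)
        assert fused.labels[0, 0, 0] == int(Label.VAT)
        assert fused.labels[0, 0, 1] == 0
        assert votes.counts_for(Label.VAT)[0, 0, 0] == 6

    def test_ties_break_to_lowest_label_code(self):
        maps = [lm([[[1]]])] * 6 + [lm([[[2]]])] * 6
        fused, _ = seg.fuse_labels(maps, vote_threshold=5)
        assert fused.labels[0, 0, 0] == 1

    def test_matches_exhaustive_tally_oracle_on_random_instances(self):
        out = V.fusion_oracle_study(n_instances=60, seed=123)
        assert out["n_mismatch"] == 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        arrays = [rng.integers(0, 7, (3, 3, 3)).astype(np.int16)
                  for _ in range(9)]
        maps = [lm(a) for a in arrays]
        fused, _ = seg.fuse_labels(maps, vote_threshold=3)
        perm = [maps[i] for i in rng.permutation(9)]
        fused_p, _ = seg.fuse_labels(perm, vote_threshold=3)
        np.testing.assert_array_equal(fused.labels, fused_p.labels)

    def test_raising_threshold_never_grows_compartments(self):
        rng = np.random.default_rng(6)
        maps = [lm(rng.integers(0, 7, (4, 4, 4)).astype(np.int16))
                for _ in range(12)]
        prev = None
        for thr in range(0, 13):
            fused, _ = seg.fuse_labels(maps, vote_threshold=thr)
            count = int((fused.labels > 0).sum())
            if prev is not None:
                assert count <= prev
            prev = count

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            seg.fuse_labels([], 5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n_atlases=st.integers(1, 12),
        threshold=st.integers(0, 7),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_fusion_equals_oracle_property(self, n_atlases, threshold, seed):
        rng = np.random.default_rng(seed)
        arrays = [rng.integers(0, 7, (3, 3, 3)).astype(np.int16)
                  for _ in range(n_atlases)]
        fused, _ = seg.fuse_labels([lm(a) for a in arrays], threshold)
        np.testing.assert_array_equal(fused.labels,
                                      V.tally_oracle(arrays, threshold))


class TestWarp:
    def _identity_field(self, shape):
        disp = np.zeros(shape + (3,), dtype=np.float64)
        return seg.DeformationField(displacement=disp, voxel_size=VOX,
                                    z_offset=0.0, similarity_score=0.0)

    def test_identity_field_preserves_labels(self):
        rng = np.random.default_rng(0)
        labels = lm(rng.integers(0, 7, (6, 5, 4)).astype(np.int16))
        fld = self._identity_field(labels.shape)
        out = seg.warp_labels(labels, fld)
        np.testing.assert_array_equal(out.labels, labels.labels)

    def test_one_voxel_translation_shifts_labels(self):
        labels = np.zeros((6, 5, 4), dtype=np.int16)
        labels[2, 2, 2] = 3
        fld = self._identity_field(labels.shape)
        fld.displacement[..., 0] = VOX[0]  # sample from x + one voxel
        out = seg.warp_labels(lm(labels), fld)
        assert out.labels[1, 2, 2] == 3
        assert out.labels[2, 2, 2] == 0

    def test_no_label_invention(self):
        rng = np.random.default_rng(1)
        labels = lm((rng.integers(0, 3, (6, 5, 4))).astype(np.int16))
        fld = self._identity_field(labels.shape)
        fld.displacement[...] = rng.normal(0, 3.0, fld.displacement.shape)
        out = seg.warp_labels(labels, fld)
        assert set(np.unique(out.labels)) <= set(np.unique(labels.labels)) | {0}


class TestQuantification:
    def test_uniform_fat_over_label_at_native_voxel_size(self):
        vox = (2.23, 2.23, 4.5)
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        labels.ravel()[:1000] = int(Label.VAT)
        lmap = LabelMap(labels=labels, voxel_size=vox)
        fat = np.ones((10, 10, 10), dtype=np.float32)
        out = seg.quantify_fat_volume(fat, lmap, Label.VAT)
        assert out == pytest.approx(0.02238, abs=2e-5)  # 1000 x 22.378 mm^3

    def test_zero_fat_gives_zero_volume(self):
        lmap = lm(np.full((4, 4, 4), int(Label.ASAT), dtype=np.int16))
        assert seg.quantify_fat_volume(np.zeros((4, 4, 4), np.float32),
                                       lmap, Label.ASAT) == 0.0

    def test_empty_label_warns_and_returns_zero(self, caplog):
        lmap = lm(np.zeros((4, 4, 4), dtype=np.int16))
        out = seg.quantify_fat_volume(np.ones((4, 4, 4), np.float32),
                                      lmap, Label.VAT)
        assert out == 0.0

    def test_liver_top_exclusion_never_increases_vat(self):
        rng = np.random.default_rng(2)
        labels = lm((rng.random((6, 6, 6)) < 0.4).astype(np.int16))
        fat = rng.uniform(0, 1, (6, 6, 6)).astype(np.float32)
        excl = rng.random((6, 6, 6)) < 0.2
        with_excl = seg.quantify_fat_volume(fat, labels, Label.VAT, excl)
        without = seg.quantify_fat_volume(fat, labels, Label.VAT)
        assert with_excl <= without

    def test_muscle_pure_and_fatty_extremes(self):
        lmap = lm(np.full((4, 4, 4), int(Label.LEFT_ANTERIOR_THIGH),
                          dtype=np.int16))
        ff0 = pp.FatFractionImage(ff=np.zeros((4, 4, 4), np.float32),
                                  valid_mask=np.ones((4, 4, 4), bool),
                                  voxel_size=VOX)
        full = seg.quantify_muscle_volume(ff0, lmap, Label.LEFT_ANTERIOR_THIGH)
        assert full == pytest.approx(64 * 8 / 1e6)
        ff1 = pp.FatFractionImage(ff=np.ones((4, 4, 4), np.float32),
                                  valid_mask=np.ones((4, 4, 4), bool),
                                  voxel_size=VOX)
        assert seg.quantify_muscle_volume(ff1, lmap,
                                          Label.LEFT_ANTERIOR_THIGH) == 0.0

    def test_phantom_muscle_is_fat_free_fraction_of_label(self, phantom_s3):
        res, vol = phantom_s3
        cal = pp.calibrate_volume(vol)
        ff = pp.compute_fat_fraction(cal)
        out = seg.quantify_muscle_volume(ff, res.labels,
                                         Label.LEFT_POSTERIOR_THIGH)
        expected = 0.9 * res.volumes.lpt_l  # 10% intramuscular fat
        assert out == pytest.approx(expected, rel=0.02)


class TestRegistrationAndSegmentSubject:
    def test_self_registration_and_known_transforms(self):
        out = V.registration_study(scale=5.0, seed=0)
        assert out["selfreg_p99_displacement_vox"] < 1.0
        assert out["translation_recovery_err_mm"] < 1.0
        assert out["deformation_min_dice"] > 0.9

    def test_too_few_atlases_for_threshold_rejected(self, calibrated_s5):
        res, cal = calibrated_s5
        atlases = [AtlasPrototype(volume=cal, labels=res.labels,
                                  prototype_id=f"a{i}") for i in range(5)]
        with pytest.raises(ValidationError):
            seg.segment_subject(cal, atlases, vote_threshold=5)

    def test_unanimous_self_atlases_reproduce_labels(self, calibrated_s5):
        res, cal = calibrated_s5
        atlases = [AtlasPrototype(volume=cal, labels=res.labels,
                                  prototype_id=f"a{i}") for i in range(6)]
        fused, vols, votes = seg.segment_subject(cal, atlases,
                                                 vote_threshold=5)
        np.testing.assert_array_equal(fused.labels, res.labels.labels)
        assert votes.n_atlases == 6
        assert vols.vat_l > 0
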