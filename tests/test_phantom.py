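"""Phantom generator: ground-truth conservation, artifacts, fixtures."""

import numpy as np
import pytest

from dixoncomp import phantom as ph
from dixoncomp import preprocess as pp
from dixoncomp.errors import ValidationError
from dixoncomp.types import Label


@pytest.mark.parametrize("scale", [3, 6])
def test_ground_truth_volumes_match_targets_within_one_voxel(scale):
    spec = ph.PhantomSpec(scale=scale, seed=5)
    res = ph.generate_phantom(spec)
    voxvol_l = res.labels.voxel_volume_mm3 / 1e6
    for label, target in spec.targets.items():
        rendered = res.labels.volume_l(label)
        assert abs(rendered - target) <= voxvol_l, label.name


def test_zero_target_renders_empty_compartment():
    res = ph.generate_phantom(ph.PhantomSpec(scale=6, seed=1, vat_l=0.0))
    assert res.labels.volume_l(Label.VAT) == 0.0
    assert res.volumes.vat_l == 0.0


def test_unfittable_target_raises():
    with pytest.raises(ValidationError):
        ph.generate_phantom(ph.PhantomSpec(scale=6, seed=1, vat_l=60.0))


def test_same_seed_is_bit_identical_different_seed_is_not():
    spec = ph.PhantomSpec(scale=6, seed=9)
    a = ph.generate_phantom(spec)
    b = ph.generate_phantom(ph.PhantomSpec(scale=6, seed=9))
    for sa, sb in zip(a.slabs, b.slabs):
        np.testing.assert_array_equal(sa.water, sb.water)
        np.testing.assert_array_equal(sa.fat, sb.fat)
    c = ph.generate_phantom(ph.PhantomSpec(scale=6, seed=10))
    assert any(
        not np.array_equal(sa.water, sc.water)
        for sa, sc in zip(a.slabs, c.slabs)
    )


def test_signal_artifacts_leave_ground_truth_labels_unchanged():
    clean = ph.generate_phantom(ph.PhantomSpec(scale=5, seed=2))
    hurt = ph.generate_phantom(ph.PhantomSpec(
        scale=5, seed=2,
        artifact_list=(ph.ArtifactSpec("metal_void"),),
    ))
    np.testing.assert_array_equal(clean.labels.labels, hurt.labels.labels)


@pytest.mark.parametrize("kind,params", [
    ("swap_separate_island", {"target": "right_thigh"}),
    ("swap_separate_island", {"target": "abdomen"}),
    ("swap_liver_top", {}),
    ("swap_sat", {}),
    ("swap_thigh", {}),
    ("outer_fov_inhomogeneity", {}),
])
def test_swap_injection_is_an_involution(kind, params):
    res = ph.generate_phantom(ph.PhantomSpec(scale=5, seed=4))
    art = ph.ArtifactSpec(kind, params)
    once = ph.inject_artifact(res.slabs, art, geometry=res.geometry)
    assert any(not np.array_equal(a.water, b.water)
               for a, b in zip(res.slabs, once))
    twice = ph.inject_artifact(once, art, geometry=res.geometry)
    for a, b in zip(res.slabs, twice):
        np.testing.assert_array_equal(a.water, b.water)
        np.testing.assert_array_equal(a.fat, b.fat)


def test_missing_slab_removes_exactly_one_slab():
    res = ph.generate_phantom(ph.PhantomSpec(scale=6, seed=4))
    out = ph.inject_artifact(res.slabs, ph.ArtifactSpec("missing_slab", {"index": 3}),
                             geometry=res.geometry)
    assert len(out) == 5
    assert 3 not in {s.slab_index for s in out}


def test_metal_void_zeroes_both_channels_inside_ball():
    res = ph.generate_phantom(ph.PhantomSpec(scale=4, seed=4))
    art = ph.ArtifactSpec("metal_void", {"radius": 30.0})
    out = ph.inject_artifact(res.slabs, art, geometry=res.geometry)
    grid = res.geometry.grid
    x, y = grid.in_plane_coords()
    zeroed = 0
    for s in out:
        mask = res.geometry.region_mask(
            "metal_void", art.params,
            x[:, None, None], y[None, :, None], s.z_positions[None, None, :])
        if mask.any():
            assert (s.water[mask] == 0).all() and (s.fat[mask] == 0).all()
            zeroed += int(mask.sum())
    assert zeroed > 0


def test_unknown_artifact_kind_rejected():
    res = ph.generate_phantom(ph.PhantomSpec(scale=6, seed=4))
    with pytest.raises(ValidationError):
        ph.inject_artifact(res.slabs, ph.ArtifactSpec("gamma_spike"),
                           geometry=res.geometry)


def test_atlas_set_distinct_and_reproducible():
    base = ph.PhantomSpec(scale=6, seed=20)
    atlases = ph.generate_atlas_set(base, 31, seed=77, calibrated=False)
    assert len(atlases) == 31
    vats = [a.labels.volume_l(Label.VAT) for a in atlases]
    assert len(set(np.round(vats, 4))) > 20  # perturbed anatomy differs
    again = ph.generate_atlas_set(base, 31, seed=77, calibrated=False)
    for a, b in zip(atlases, again):
        np.testing.assert_array_equal(a.labels.labels, b.labels.labels)


def test_atlas_zero_perturbation_reproduces_base_phantom():
    base = ph.PhantomSpec(scale=6, seed=21)
    res = ph.generate_phantom(base)
    atlas = ph.generate_atlas_set(base, 1, seed=0, spread=0.0,
                                  calibrated=False)[0]
    np.testing.assert_array_equal(atlas.labels.labels, res.labels.labels)
    np.testing.assert_array_equal(atlas.volume.water,
                                  pp.merge_slabs(res.slabs).water)


def test_atlas_count_must_be_positive():
    with pytest.raises(ValidationError):
        ph.generate_atlas_set(ph.PhantomSpec(scale=6), 0, seed=0)


class TestCohortFixture:
    def test_flag_totals_match_configuration_exactly(self):
        cfg = {
            "analysable": {"fat": 95, "fat_one_thigh": 90, "fat_both_thighs": 88},
            "flags": {"respiratory_artifact": 13, "outer_fov_inhomogeneity": 33},
        }
        recs = ph.generate_cohort_fixture(cfg, 100, seed=1)
        assert sum(r.respiratory_artifact for r in recs) == 13
        assert sum(r.outer_fov_inhomogeneity for r in recs) == 33

    def test_all_clean_cohort(self):
        recs = ph.generate_cohort_fixture({}, 50, seed=1)
        assert all(not r.missing_slabs and r.landmark_valid_abdomen
                   for r in recs)

    def test_every_record_flagged_at_boundary(self):
        recs = ph.generate_cohort_fixture(
            {"flags": {"respiratory_artifact": 20}}, 20, seed=1)
        assert all(r.respiratory_artifact for r in recs)

    def test_inconsistent_tiers_rejected(self):
        with pytest.raises(ValidationError):
            ph.generate_cohort_fixture(
                {"analysable": {"fat": 90, "fat_one_thigh": 95,
                                "fat_both_thighs": 80}}, 100, seed=1)

    def test_flag_count_above_n_rejected(self):
        with pytest.raises(ValidationError):
            ph.generate_cohort_fixture(
                {"flags": {"respiratory_artifact": 101}}, 100, seed=1)
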