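"""QA detectors, the acceptance protocol, and cohort aggregation."""

import numpy as np
import pytest

from dixoncomp import phantom as ph
from dixoncomp import preprocess as pp
from dixoncomp import qa
from dixoncomp.errors import ValidationError
from dixoncomp.types import CompartmentVolumes, QARecord


def _subject(scale=4, seed=0, **kw):
    res = ph.generate_phantom(ph.PhantomSpec(scale=scale, seed=seed, **kw))
    vol = pp.merge_slabs(res.slabs)
    return res, vol


def _artifact_subject(kind, params=None, scale=4, seed=0):
    return _subject(scale, seed,
                    artifact_list=(ph.ArtifactSpec(kind, params or {}),))


class TestMissingSlabs:
    def test_missing_abdominal_slab_maps_to_abdomen(self):
        res, _ = _subject()
        out = ph.inject_artifact(res.slabs,
                                 ph.ArtifactSpec("missing_slab", {"index": 3}),
                                 geometry=res.geometry)
        missing, regions = qa.detect_missing_slabs(out)
        assert missing == {3}
        assert regions == {"abdomen"}

    def test_complete_acquisition_has_no_missing(self):
        res, _ = _subject()
        missing, regions = qa.detect_missing_slabs(res.slabs)
        assert missing == set() and regions == set()

    def test_missing_thigh_slabs(self):
        res, _ = _subject()
        out = [s for s in res.slabs if s.slab_index not in (5, 6)]
        missing, regions = qa.detect_missing_slabs(out)
        assert missing == {5, 6}
        assert regions == {"thigh"}


class TestFovCoverage:
    def test_nominal_phantom_passes_all(self):
        res, vol = _subject()
        cov = qa.check_fov_coverage(vol, res.landmarks)
        assert cov["knee_complete"] and cov["t9_present"]
        assert cov["abdomen_in_fov"] and cov["thigh_in_fov"]
        assert not cov["tilted"]

    def test_tall_subject_loses_knee_coverage(self):
        res, vol = _artifact_subject("tall_subject")
        cov = qa.check_fov_coverage(vol, res.landmarks)
        assert not cov["knee_complete"]

    def test_tilted_subject_clips_right_thigh(self):
        res, vol = _artifact_subject("tilted_subject", {"tilt_deg": 10.0})
        cov = qa.check_fov_coverage(vol, res.landmarks)
        assert cov["tilted"]
        assert cov["tilt_clipped_sides"] == frozenset({"right"})

    def test_missing_landmarks_fail_closed(self):
        _, vol = _subject()
        cov = qa.check_fov_coverage(vol, None)
        assert not cov["knee_complete"] and not cov["t9_present"]
        assert cov.get("knee_unknown") and cov.get("t9_unknown")


class TestMetal:
    def test_metal_void_detected_at_site(self):
        _, vol = _artifact_subject("metal_void")
        flag, voids = qa.detect_metal(vol)
        assert flag and voids
        assert voids[0]["volume_ml"] > 5

    def test_clean_phantom_and_vented_lungs_not_flagged(self):
        _, vol = _subject()
        flag, voids = qa.detect_metal(vol)
        assert not flag  # lungs vent through the airways: not enclosed


class TestRespiratory:
    def test_ghosting_detected(self):
        _, vol = _artifact_subject("respiratory_ghosting",
                                   {"amplitude": 0.2})
        flag, score = qa.detect_respiratory_artifact(vol)
        assert flag and score > 0.01

    def test_clean_phantom_scores_zero(self):
        _, vol = _subject()
        flag, score = qa.detect_respiratory_artifact(vol)
        assert not flag and score == 0.0

    def test_zero_amplitude_ghost_scores_zero(self):
        _, vol = _artifact_subject("respiratory_ghosting",
                                   {"amplitude": 0.0})
        _, score = qa.detect_respiratory_artifact(vol)
        assert score == 0.0


class TestSwapScans:
    def test_dog_bite_detected_in_rind(self):
        _, vol = _artifact_subject("outer_fov_inhomogeneity")
        flag, hits = qa.detect_outer_fov_inhomogeneity(vol)
        assert flag
        assert hits[0]["edge_distance_mm"] <= 30.0

    def test_central_sat_swap_routes_to_sat_detector_not_outer_fov(self):
        _, vol = _artifact_subject("swap_sat")
        outer, _ = qa.detect_outer_fov_inhomogeneity(vol)
        sat, _ = qa.detect_sat_swaps(vol)
        assert sat and not outer

    def test_thigh_swap_blob_detected(self):
        _, vol = _artifact_subject("swap_thigh")
        flag, hits = qa.detect_thigh_swaps(vol)
        assert flag and hits

    def test_clean_phantom_triggers_no_swap_scans(self):
        _, vol = _subject()
        assert not qa.detect_outer_fov_inhomogeneity(vol)[0]
        assert not qa.detect_sat_swaps(vol)[0]
        assert not qa.detect_thigh_swaps(vol)[0]


class TestAcceptanceProtocol:
    def test_missing_abdominal_slab_rejects_fat(self):
        rec = qa.apply_acceptance_protocol(
            QARecord(subject_id="x", missing_slabs=frozenset({3})))
        assert rec.analysable_fat is False
        assert "missing_slabs" in rec.rejection_reasons_fat
        assert rec.analysable_left_thigh and rec.analysable_right_thigh

    def test_clean_record_fully_analysable(self):
        rec = qa.apply_acceptance_protocol(QARecord(subject_id="x"))
        assert rec.analysable_fat
        assert rec.analysable_left_thigh and rec.analysable_right_thigh

    def test_tilt_rejects_only_clipped_side(self):
        rec = qa.apply_acceptance_protocol(QARecord(
            subject_id="x", tilted_subject=True,
            tilt_clipped_sides=frozenset({"right"})))
        assert rec.analysable_left_thigh is True
        assert rec.analysable_right_thigh is False
        assert "tilted" in rec.rejection_reasons_right_thigh

    def test_metal_in_thigh_blocks_that_thigh_only(self):
        rec = qa.apply_acceptance_protocol(QARecord(
            subject_id="x", metal_contamination=True,
            metal_regions=frozenset({"left_thigh"})))
        assert rec.analysable_fat
        assert rec.analysable_left_thigh is False
        assert rec.analysable_right_thigh is True

    def test_reported_artifacts_do_not_reject_alone(self):
        rec = qa.apply_acceptance_protocol(QARecord(
            subject_id="x", respiratory_artifact=True, swap_liver_top=True,
            swap_separate_island=True, outer_fov_inhomogeneity=True,
            swap_sat=True, swap_thigh=True,
            incomplete_knee_coverage=True))
        assert rec.analysable_fat
        assert rec.analysable_left_thigh and rec.analysable_right_thigh

    def test_invalid_abdominal_landmark_rejects_fat(self):
        rec = qa.apply_acceptance_protocol(QARecord(
            subject_id="x", landmark_valid_abdomen=False))
        assert rec.analysable_fat is False
        assert "landmark_invalid" in rec.rejection_reasons_fat

    def test_acceptance_is_deterministic_and_pure(self):
        raw = QARecord(subject_id="x", missing_slabs=frozenset({6}),
                       tilted_subject=True,
                       tilt_clipped_sides=frozenset({"left"}))
        a = qa.apply_acceptance_protocol(raw)
        b = qa.apply_acceptance_protocol(raw)
        assert a == b


class TestCohortSummary:
    def test_all_clean_cohort_is_fully_analysable(self):
        recs = ph.generate_cohort_fixture({}, 100, seed=3)
        s = qa.summarize_cohort(recs)
        assert s.analysable_fat == 100
        assert s.analysable_fat_both_thighs_pct == 100.00

    def test_rejection_reason_shares_over_47_rejected(self):
        cfg = {
            "analysable": {"fat": 953, "fat_one_thigh": 953,
                           "fat_both_thighs": 953},
            "fat_reasons": {"missing_slabs": 6, "landmark_invalid": 39,
                            "other:metal": 1, "other:motion": 1},
        }
        s = qa.summarize_cohort(ph.generate_cohort_fixture(cfg, 1000, seed=4))
        assert s.n_rejected == 47
        assert s.rejection_reason_percentages["missing_slabs"] == 12.77
        assert s.rejection_reason_percentages["landmark_invalid"] == 82.98

    def test_summary_is_order_invariant(self):
        cfg = {"analysable": {"fat": 45, "fat_one_thigh": 42,
                              "fat_both_thighs": 40}}
        recs = ph.generate_cohort_fixture(cfg, 50, seed=5)
        s1 = qa.summarize_cohort(recs)
        s2 = qa.summarize_cohort(list(reversed(recs)))
        assert s1 == s2

    def test_tier_monotonicity_holds(self):
        recs = ph.generate_cohort_fixture(
            {"analysable": {"fat": 80, "fat_one_thigh": 70,
                            "fat_both_thighs": 50}}, 100, seed=6)
        s = qa.summarize_cohort(recs)
        assert (s.analysable_fat_both_thighs <= s.analysable_fat_one_thigh
                <= s.analysable_fat <= s.n)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            qa.summarize_cohort([])


class TestDescriptiveStats:
    def test_single_record_has_zero_sd(self):
        v = CompartmentVolumes(vat_l=3.0, asat_l=6.0, lat_l=1.5, rat_l=1.5,
                               lpt_l=3.0, rpt_l=3.0)
        s = qa.descriptive_stats([v])
        assert s.sd["vat_l"] == 0.0
        assert s.min["vat_l"] == s.max["vat_l"] == s.mean["vat_l"] == 3.0

    def test_two_records_closed_form(self):
        a = CompartmentVolumes(vat_l=2.0)
        b = CompartmentVolumes(vat_l=4.0)
        s = qa.descriptive_stats([a, b])
        assert s.mean["vat_l"] == pytest.approx(3.0)
        assert s.sd["vat_l"] == pytest.approx(np.sqrt(2.0))

    def test_listwise_exclusion_drops_incomplete_records(self):
        a = CompartmentVolumes(vat_l=2.0)
        s = qa.descriptive_stats([a, None, None])
        assert s.n == 1

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            qa.descriptive_stats([None, None])

    def test_histogram_counts_sum_to_n(self):
        vols = [CompartmentVolumes(vat_l=float(i)) for i in range(1, 11)]
        s = qa.descriptive_stats(vols, bins=5)
        _, counts = s.histograms["vat_l"]
        assert counts.sum() == 10
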