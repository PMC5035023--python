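"""Technical quality assurance and the data-acceptance protocol.

Automated counterparts of the visual QA checklist used in large imaging
cohorts: missing-slab detection, field-of-view / landmark coverage,
metal signal voids, respiratory ghosting, water-fat swap scans near and
away from the transverse FOV edge, and the reduced data-acceptance
protocol that decides per-compartment analysability (fat, left thigh,
right thigh).  Cohort-level aggregation reports counts and two-decimal
percentages per criterion, nested analysability tiers, and the breakdown
of rejection reasons; descriptive statistics summarize the quantified
volumes with list-wise exclusion of incomplete records.

Only hard coverage failures reject a compartment: respiratory artifacts,
corrected island swaps, liver-top swaps and outer-FOV inhomogeneities are
reported but are not by themselves grounds for rejection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .phantom import SLAB_TABLE
from .preprocess import default_noise_floor, foreground_depth, _zone_masks
from .types import (
    QA_FLAG_FIELDS,
    REASON_PRECEDENCE,
    CohortSummary,
    CompartmentVolumes,
    DixonSlab,
    DixonVolume,
    QARecord,
    percentage,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptiveStats",
    "detect_missing_slabs",
    "check_fov_coverage",
    "detect_metal",
    "detect_respiratory_artifact",
    "detect_outer_fov_inhomogeneity",
    "detect_sat_swaps",
    "detect_thigh_swaps",
    "collect_qa_record",
    "apply_acceptance_protocol",
    "summarize_cohort",
    "descriptive_stats",
]

#: nominal anatomical region of each protocol slab (by index)
SLAB_REGIONS = {1: ("neck",), 2: ("abdomen",), 3: ("abdomen",),
                4: ("abdomen", "thigh"), 5: ("thigh",), 6: ("thigh",)}


# ---------------------------------------------------------------------------
# detectors


def detect_missing_slabs(slabs: list[DixonSlab]) -> tuple[set, set]:
    """Missing protocol slab indices and the anatomical regions affected."""
    if not slabs:
        raise ValidationError("at least one slab required")
    expected = {idx for idx, *_ in SLAB_TABLE}
    present = {s.slab_index for s in slabs}
    missing = expected - present
    regions = set()
    for idx in missing:
        regions.update(SLAB_REGIONS.get(idx, ()))
    return missing, regions


def _grid_extents(volume: DixonVolume):
    nx, ny, _ = volume.shape
    dx, dy, _ = volume.voxel_size
    return nx * dx / 2.0, ny * dy / 2.0, volume.z_extent


def _estimate_tilt(volume: DixonVolume, fg: np.ndarray):
    """Body-axis in-plane tilt (deg) and FOV-clipped thigh sides.

    Fits the per-slice foreground x-centroid against z; a side is clipped
    when thigh-zone foreground touches the corresponding x boundary.
    """
    nx = volume.shape[0]
    dx, dy, _ = volume.voxel_size
    xs = (np.arange(nx) - (nx - 1) / 2) * dx
    z = volume.z_positions
    thigh_slices, _ = _zone_masks(volume, fg)
    min_area = max(8, int(20e2 / (dx * dy)))

    # per-slice centroid of the lower-body components that do NOT touch
    # the x boundary: a clipped thigh's centroid saturates at the FOV
    # edge and would mask the true axis tilt
    zs, cxs = [], []
    fit_slices = thigh_slices if thigh_slices.sum() >= 4 else fg.any(axis=(0, 1))
    for k in np.nonzero(fit_slices)[0]:
        lab, n = ndimage.label(fg[:, :, k])
        vals = []
        for i in range(1, n + 1):
            m = lab == i
            if m.sum() < min_area:
                continue
            if m[0].any() or m[-1].any():
                continue  # touches x boundary: centroid unreliable
            vals.append(float((m * xs[:, None]).sum() / m.sum()))
        if vals:
            zs.append(z[k])
            cxs.append(np.mean(vals))
    if len(zs) < 4:
        return 0.0, frozenset()
    slope = np.polyfit(zs, cxs, 1)[0]
    angle = float(np.degrees(np.arctan(slope)))
    clipped = set()
    if thigh_slices.any():
        tz = fg[:, :, thigh_slices]
        if tz[0, :, :].any():
            clipped.add("left")
        if tz[-1, :, :].any():
            clipped.add("right")
    return angle, frozenset(clipped)


def check_fov_coverage(
    volume: DixonVolume,
    landmarks: dict | None,
    tilt_threshold_deg: float = 5.0,
    edge_margin_mm: float = 5.0,
) -> dict:
    """Coverage flags from landmark positions and the image itself.

    ``landmarks`` carries world coordinates of the femoral epicondyles and
    the top of vertebra T9 (phantom-provided here; atlas-propagated in a
    production setting).  Missing landmarks make the corresponding flags
    False ("unknown is failing") with a note.
    """
    fx, fy, (zlo, zhi) = _grid_extents(volume)

    def inside(pt) -> bool:
        x, y, z = pt
        return (abs(x) <= fx - edge_margin_mm and abs(y) <= fy - edge_margin_mm
                and zlo + edge_margin_mm <= z <= zhi - edge_margin_mm)

    flags = {}
    lm = landmarks or {}
    if "epicondyle_left" in lm and "epicondyle_right" in lm:
        flags["knee_complete"] = bool(
            inside(lm["epicondyle_left"]) and inside(lm["epicondyle_right"])
        )
    else:
        flags["knee_complete"] = False
        flags["knee_unknown"] = True
    if "t9" in lm:
        flags["t9_present"] = bool(inside(lm["t9"]))
    else:
        flags["t9_present"] = False
        flags["t9_unknown"] = True
    abd = lm.get("abdomen_z")
    flags["abdomen_in_fov"] = bool(
        abd is not None and abd[0] >= zlo and abd[1] <= zhi and flags["t9_present"]
    )
    th = lm.get("thigh_z")
    flags["thigh_in_fov"] = bool(
        th is not None and th[0] >= zlo and flags["knee_complete"]
    )

    fg = volume.total() > default_noise_floor(volume)
    angle, clipped = _estimate_tilt(volume, fg)
    flags["tilt_deg"] = angle
    flags["tilt_clipped_sides"] = clipped
    flags["tilted"] = bool(abs(angle) > tilt_threshold_deg and clipped)
    return flags


def detect_metal(
    volume: DixonVolume,
    noise_floor: float | None = None,
    min_void_ml: float = 5.0,
) -> tuple[bool, list[dict]]:
    """Interior signal voids: low-signal regions fully enclosed by tissue.

    Background air is never flagged (not enclosed); air reaching the
    volume border (e.g. lungs vented through the airways) is ignored.
    """
    if noise_floor is None:
        noise_floor = default_noise_floor(volume)
    fg = volume.total() > noise_floor
    filled = ndimage.binary_fill_holes(fg)
    holes = filled & ~fg
    voids = []
    if holes.any():
        lab, n = ndimage.label(holes)
        voxml = volume.voxel_volume_mm3 / 1000.0
        for i in range(1, n + 1):
            m = lab == i
            ml = float(m.sum()) * voxml
            if ml >= min_void_ml:
                cx = [float(c) for c in ndimage.center_of_mass(m)]
                voids.append({"volume_ml": ml, "center_voxel": cx})
    return bool(voids), voids


def detect_respiratory_artifact(
    volume: DixonVolume,
    threshold: float = 0.01,
    support_frac: float = 0.15,
    dilate_mm: float = 25.0,
) -> tuple[bool, float]:
    """Score ghosting along the phase (y) axis over the breath-hold slabs.

    Respiratory motion replicates the abdomen along the phase-encoding
    direction; the attenuated replicas land beyond the body's y-support.
    Per slice, the body support is taken where the projected signal
    exceeds ``support_frac`` of its peak, dilated by ``dilate_mm`` to
    cover the body's own soft edge; the score is the worst-slice fraction
    of projected signal outside that support.  Zero on ghost-free data.
    """
    abdominal = np.array(
        [any(i in (2, 3, 4) for i in prov) for prov in volume.provenance]
    )
    if not abdominal.any():
        abdominal = np.ones(volume.shape[2], dtype=bool)
    total = volume.total()[:, :, abdominal]
    pad = max(1, int(round(dilate_mm / volume.voxel_size[1])))
    score = 0.0
    for k in range(total.shape[2]):
        p = total[:, :, k].sum(axis=0)
        s = p.sum()
        if s <= 0:
            continue
        support = ndimage.binary_dilation(p > support_frac * p.max(),
                                          iterations=pad)
        outside = float(p[~support].sum())
        score = max(score, outside / s)
    return score > threshold, float(score)


def _shell_swap_scan(
    volume: DixonVolume,
    noise_floor: float | None,
    shell_mm: float,
    min_blob_ml: float,
):
    """Water-dominant blobs in the subcutaneous shell (swap suspects)."""
    if noise_floor is None:
        noise_floor = default_noise_floor(volume)
    fg = volume.total() > noise_floor
    if not fg.any():
        return []
    depth = foreground_depth(fg, volume.voxel_size)
    shell = fg & (depth <= shell_mm)
    water_dom = volume.water > volume.fat
    lab, n = ndimage.label(shell & water_dom)
    blobs = []
    voxml = volume.voxel_volume_mm3 / 1000.0
    for i in range(1, n + 1):
        m = lab == i
        if m.sum() * voxml >= min_blob_ml:
            blobs.append(m)
    return blobs


def _fov_edge_distance(volume: DixonVolume) -> np.ndarray:
    """In-plane distance (mm) of each voxel to the transverse FOV boundary."""
    nx, ny, _ = volume.shape
    dx, dy, _ = volume.voxel_size
    fx, fy = nx * dx / 2.0, ny * dy / 2.0
    x = np.abs((np.arange(nx) - (nx - 1) / 2) * dx)
    y = np.abs((np.arange(ny) - (ny - 1) / 2) * dy)
    dist = np.minimum(fx - x[:, None], fy - y[None, :])
    return dist


def detect_outer_fov_inhomogeneity(
    volume: DixonVolume,
    noise_floor: float | None = None,
    rind_mm: float = 30.0,
    shell_mm: float = 12.0,
    min_blob_ml: float = 15.0,
) -> tuple[bool, list[dict]]:
    """Swap-like artifacts ("dog-bites") near the transverse FOV edge.

    The subcutaneous-shell swap scan restricted to a rind near the FOV
    boundary, where main-field drop produces local water-fat swaps.
    """
    blobs = _shell_swap_scan(volume, noise_floor, shell_mm, min_blob_ml)
    dist = _fov_edge_distance(volume)
    hits = []
    for m in blobs:
        d = dist[:, :, None] * np.ones((1, 1, volume.shape[2]))
        dmin = float(d[m].min())
        if dmin <= rind_mm:
            cx = [float(c) for c in ndimage.center_of_mass(m)]
            hits.append({"center_voxel": cx, "edge_distance_mm": dmin})
    return bool(hits), hits


def detect_sat_swaps(
    volume: DixonVolume,
    noise_floor: float | None = None,
    rind_mm: float = 30.0,
    shell_mm: float = 12.0,
    min_blob_ml: float = 15.0,
) -> tuple[bool, list[dict]]:
    """Water-fat swaps inside subcutaneous fat away from the FOV edge."""
    blobs = _shell_swap_scan(volume, noise_floor, shell_mm, min_blob_ml)
    dist = _fov_edge_distance(volume)
    hits = []
    for m in blobs:
        d = dist[:, :, None] * np.ones((1, 1, volume.shape[2]))
        if float(d[m].min()) > rind_mm:
            cx = [float(c) for c in ndimage.center_of_mass(m)]
            hits.append({"center_voxel": cx})
    return bool(hits), hits


def detect_thigh_swaps(
    volume: DixonVolume,
    noise_floor: float | None = None,
    deep_mm: float = 30.0,
    min_blob_ml: float = 30.0,
    island_fraction: float = 0.5,
) -> tuple[bool, list[dict]]:
    """Partial water-fat swaps inside thigh muscle.

    Fat-dominant blobs deep inside a thigh, too small to be a whole-limb
    island swap (those are reported by the separate-island detector).
    """
    if noise_floor is None:
        noise_floor = default_noise_floor(volume)
    fg = volume.total() > noise_floor
    if not fg.any():
        return False, []
    depth = foreground_depth(fg, volume.voxel_size)
    thigh_slices, _ = _zone_masks(volume, fg)
    deep = fg & (depth > deep_mm) & thigh_slices[None, None, :]
    if not deep.any():
        return False, []
    fat_dom = volume.fat > volume.water
    nx = volume.shape[0]
    xleft = (np.arange(nx) < nx / 2)[:, None, None]
    hits = []
    voxml = volume.voxel_volume_mm3 / 1000.0
    for side in (xleft, ~xleft):
        zone = deep & side
        nz = int(zone.sum())
        if nz == 0:
            continue
        frac = float(fat_dom[zone].mean())
        if frac > island_fraction:
            continue  # whole-limb swap: separate-island detector's case
        lab, n = ndimage.label(fat_dom & zone)
        for i in range(1, n + 1):
            m = lab == i
            if m.sum() * voxml >= min_blob_ml:
                cx = [float(c) for c in ndimage.center_of_mass(m)]
                hits.append({"center_voxel": cx, "volume_ml": float(m.sum() * voxml)})
    return bool(hits), hits


# ---------------------------------------------------------------------------
# record assembly and acceptance


def _metal_regions(volume: DixonVolume, voids: list[dict]) -> frozenset:
    fg = volume.total() > default_noise_floor(volume)
    thigh_slices, _ = _zone_masks(volume, fg)
    regions = set()
    nx = volume.shape[0]
    for v in voids:
        cx, _, cz = v["center_voxel"]
        if thigh_slices[int(round(cz))]:
            regions.add("left_thigh" if cx < nx / 2 else "right_thigh")
        else:
            regions.add("abdomen")
    return frozenset(regions)


def collect_qa_record(
    subject_id: str,
    slabs: list[DixonSlab],
    volume: DixonVolume,
    landmarks: dict | None = None,
    swap_components=None,
) -> QARecord:
    """Run all detectors on one subject and assemble the raw QA record."""
    missing, _ = detect_missing_slabs(slabs)
    cov = check_fov_coverage(volume, landmarks)
    metal, voids = detect_metal(volume)
    resp, _ = detect_respiratory_artifact(volume)
    outer, _ = detect_outer_fov_inhomogeneity(volume)
    satsw, _ = detect_sat_swaps(volume)
    thighsw, _ = detect_thigh_swaps(volume)
    swap_components = swap_components or []
    island = any(c.subtype == "island" for c in swap_components)
    liver = any(c.subtype == "liver_top" for c in swap_components)
    return QARecord(
        subject_id=subject_id,
        respiratory_artifact=resp,
        metal_contamination=metal,
        swap_sat=satsw,
        swap_liver_top=liver,
        swap_thigh=thighsw,
        swap_separate_island=island,
        outer_fov_inhomogeneity=outer,
        incomplete_knee_coverage=not cov["knee_complete"],
        missing_slabs=frozenset(missing),
        landmark_valid_abdomen=cov["abdomen_in_fov"],
        landmark_valid_thigh=cov["thigh_in_fov"],
        tilted_subject=cov["tilted"],
        tilt_clipped_sides=cov["tilt_clipped_sides"],
        metal_regions=_metal_regions(volume, voids) if metal else frozenset(),
    )


def apply_acceptance_protocol(record: QARecord) -> QARecord:
    """Decide per-compartment analysability from the raw flags.

    Fat (VAT+ASAT) is analysable unless slabs are missing over the
    abdomen, the abdominal landmark is invalid (T9 absent / abdomen out of
    FOV), or another abdominal blocker (e.g. metal void, severe motion) is
    recorded.  Each thigh is analysable unless slabs are missing over the
    thighs, the femoral epicondyles are not visible, a tilt clips that
    side out of the FOV, or a side-specific blocker (metal, other) is
    recorded.  Reported artifacts that were analysable in practice
    (respiratory ghosting, corrected island swaps, liver-top swaps,
    outer-FOV inhomogeneities) do not reject on their own.
    """
    missing_regions = set()
    for idx in record.missing_slabs:
        missing_regions.update(SLAB_REGIONS.get(int(idx), ()))

    fat_reasons = []
    if "abdomen" in missing_regions:
        fat_reasons.append("missing_slabs")
    if not record.landmark_valid_abdomen:
        fat_reasons.append("landmark_invalid")
    if "abdomen" in record.metal_regions:
        fat_reasons.append("other:metal")
    if record.other_reason_fat:
        fat_reasons.append(f"other:{record.other_reason_fat}")

    def thigh_reasons(side: str) -> list:
        reasons = []
        if "thigh" in missing_regions:
            reasons.append("missing_slabs")
        if not record.landmark_valid_thigh:
            reasons.append("landmark_invalid")
        if record.tilted_subject and side in record.tilt_clipped_sides:
            reasons.append("tilted")
        if f"{side}_thigh" in record.metal_regions:
            reasons.append("other:metal")
        other = getattr(record, f"other_reason_{side}_thigh")
        if other:
            reasons.append(f"other:{other}")
        return reasons

    left = thigh_reasons("left")
    right = thigh_reasons("right")
    return replace(
        record,
        analysable_fat=not fat_reasons,
        analysable_left_thigh=not left,
        analysable_right_thigh=not right,
        rejection_reasons_fat=tuple(fat_reasons),
        rejection_reasons_left_thigh=tuple(left),
        rejection_reasons_right_thigh=tuple(right),
    )


def summarize_cohort(records: list[QARecord]) -> CohortSummary:
    """Aggregate QA records into counts and two-decimal percentages.

    Analysability tiers are nested: fat only; fat and at least one thigh;
    fat and both thighs.  Rejection-reason shares are reported over the
    subjects with any rejected compartment, using each subject's primary
    (highest-precedence) reason.
    """
    if not records:
        raise ValidationError("cohort must contain at least one record")
    records = [
        r if r.decided else apply_acceptance_protocol(r) for r in records
    ]
    n = len(records)
    flag_counts = {
        f: sum(bool(getattr(r, f)) for r in records) for f in QA_FLAG_FIELDS
    }
    flag_counts["missing_slabs"] = sum(bool(r.missing_slabs) for r in records)
    fat = sum(r.analysable_fat for r in records)
    one = sum(
        r.analysable_fat and (r.analysable_left_thigh or r.analysable_right_thigh)
        for r in records
    )
    both = sum(
        r.analysable_fat and r.analysable_left_thigh and r.analysable_right_thigh
        for r in records
    )
    rejected = [
        r for r in records
        if not (r.analysable_fat and r.analysable_left_thigh
                and r.analysable_right_thigh)
    ]
    reason_counts = {code: 0 for code in REASON_PRECEDENCE}
    for r in rejected:
        code = r.primary_reason()
        if code:
            reason_counts[code] += 1
    n_rej = len(rejected)
    reason_pct = {
        code: (percentage(c, n_rej) if n_rej else 0.0)
        for code, c in reason_counts.items()
    }
    return CohortSummary(
        n=n,
        flag_counts=flag_counts,
        flag_percentages={f: percentage(c, n) for f, c in flag_counts.items()},
        analysable_fat=fat,
        analysable_fat_one_thigh=one,
        analysable_fat_both_thighs=both,
        analysable_fat_pct=percentage(fat, n),
        analysable_fat_one_thigh_pct=percentage(one, n),
        analysable_fat_both_thighs_pct=percentage(both, n),
        n_rejected=n_rej,
        rejection_reason_counts=reason_counts,
        rejection_reason_percentages=reason_pct,
    )


@dataclass
class DescriptiveStats:
    """Mean, SD, range and histograms of the quantified volumes."""

    n: int
    mean: dict
    sd: dict
    min: dict
    max: dict
    histograms: dict  # measurement -> (bin_edges, counts)


_MEASUREMENTS = (
    "vat_l", "asat_l", "total_trunk_fat_l", "total_thigh_l",
    "rat_l", "rpt_l", "lat_l", "lpt_l",
)
_HISTOGRAM_KEYS = ("vat_l", "asat_l", "total_trunk_fat_l", "total_thigh_l")


def descriptive_stats(
    volumes: list, bins: int = 40
) -> DescriptiveStats:
    """Cohort descriptive statistics with list-wise exclusion.

    ``volumes`` items are :class:`CompartmentVolumes` or ``None`` (missing
    subject); subjects with any missing measurement are excluded from all
    statistics (list-wise deletion).
    """
    complete = [
        v for v in volumes
        if isinstance(v, CompartmentVolumes)
        and all(np.isfinite(val) for val in v.as_dict().values())
    ]
    if not complete:
        raise ValidationError("no complete volume records")
    data = {m: np.array([v.as_dict()[m] for v in complete]) for m in _MEASUREMENTS}
    nn = len(complete)
    mean = {m: float(d.mean()) for m, d in data.items()}
    sd = {m: float(d.std(ddof=1)) if nn > 1 else 0.0 for m, d in data.items()}
    mn = {m: float(d.min()) for m, d in data.items()}
    mx = {m: float(d.max()) for m, d in data.items()}
    hists = {}
    for m in _HISTOGRAM_KEYS:
        counts, edges = np.histogram(data[m], bins=bins)
        hists[m] = (edges, counts)
    return DescriptiveStats(n=nn, mean=mean, sd=sd, min=mn, max=mx,
                            histograms=hists)
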