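"""End-to-end cohort orchestration.

For each subject: generate (or load) the slab acquisition, merge,
detect/correct island swaps, calibrate, run the QA detectors, apply the
data-acceptance protocol, segment the accepted compartments with the
multi-atlas method, quantify, and aggregate the cohort report.  Subjects
rejected for the thighs but accepted for fat still receive VAT/ASAT
volumes (tiered analysability); per-subject failures are isolated and
marked non-analysable, never aborting the cohort.  Re-running with the
same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom as ph
from . import preprocess as pp
from . import qa
from . import segmentation as seg
from .config import PipelineConfig
from .errors import DixonError, ValidationError
from .io import write_qa_records
from .types import CompartmentVolumes, QARecord

logger = logging.getLogger(__name__)

__all__ = ["SubjectResult", "process_subject", "run_pipeline"]


@dataclass
class SubjectResult:
    subject_id: str
    record: QARecord
    volumes: CompartmentVolumes | None     # None when fat not analysable
    truth: CompartmentVolumes | None = None


def _subject_artifacts(cfg: PipelineConfig, rng) -> list:
    """Assign configured artifact kinds to subject slots, one each."""
    kinds = []
    for kind, count in cfg.cohort.artifacts.items():
        if kind not in ph.ARTIFACT_KINDS:
            raise ValidationError(f"unknown artifact kind {kind!r}")
        kinds.extend([kind] * int(count))
    if len(kinds) > cfg.cohort.n_subjects:
        raise ValidationError("more artifacts configured than subjects")
    slots = [None] * (cfg.cohort.n_subjects - len(kinds)) + kinds
    perm = rng.permutation(len(slots))
    return [slots[i] for i in perm]


def _subject_spec(cfg: PipelineConfig, seed: int, rng, artifact) -> ph.PhantomSpec:
    p = cfg.phantom
    s = p.subject_spread
    u = lambda lo, hi: float(rng.uniform(lo, hi))
    artifacts = (ph.ArtifactSpec(artifact),) if artifact else ()
    return ph.PhantomSpec(
        scale=p.scale,
        vat_l=p.vat_l * (1 + s * u(-0.3, 0.3)),
        asat_l=p.asat_l * (1 + s * u(-0.2, 0.2)),
        lat_l=p.lat_l * (1 + s * u(-0.15, 0.15)),
        rat_l=p.rat_l * (1 + s * u(-0.15, 0.15)),
        lpt_l=p.lpt_l * (1 + s * u(-0.15, 0.15)),
        rpt_l=p.rpt_l * (1 + s * u(-0.15, 0.15)),
        torso_a=230.0 * (1 + s * u(-0.05, 0.05)),
        torso_b=135.0 * (1 + s * u(-0.05, 0.05)),
        bias_amplitude=p.bias_amplitude,
        noise_sd=p.noise_sd,
        artifact_list=artifacts,
        seed=seed,
    )


def process_subject(
    subject_id: str,
    result: ph.PhantomResult,
    atlases: list,
    cfg: PipelineConfig,
) -> SubjectResult:
    """QA, acceptance and (if accepted) segmentation for one subject."""
    volume = pp.merge_slabs(result.slabs)
    components = pp.detect_separate_island_swaps(
        volume, water_plausibility=cfg.preprocess.swap_water_plausibility
    )
    exclusions = None
    for comp in components:
        volume, excl = pp.correct_swap(volume, comp)
        if excl is not None:
            exclusions = excl if exclusions is None else (exclusions | excl)

    record = qa.collect_qa_record(
        subject_id, result.slabs, volume, result.landmarks, components
    )
    record = qa.apply_acceptance_protocol(record)
    if not record.analysable_fat or not cfg.cohort.segment:
        return SubjectResult(subject_id, record, None, result.fat_free_volumes)

    calibrated = pp.calibrate_volume(
        volume,
        noise_floor=cfg.preprocess.noise_floor,
        pure_fat_threshold=cfg.preprocess.pure_fat_threshold,
        control_scale=cfg.preprocess.bias_control_scale_mm,
        min_component_voxels=cfg.preprocess.min_component_voxels,
    )
    fused, volumes, _ = seg.segment_subject(
        calibrated, atlases,
        vote_threshold=cfg.vote_threshold,
        registration=cfg.registration,
        vat_exclusions=exclusions,
    )
    # thighs only count when accepted
    if not record.analysable_left_thigh:
        volumes = replace(volumes, lat_l=0.0, lpt_l=0.0)
    if not record.analysable_right_thigh:
        volumes = replace(volumes, rat_l=0.0, rpt_l=0.0)
    return SubjectResult(subject_id, record, volumes, result.fat_free_volumes)


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run a synthetic cohort end to end and write the report files.

    Writes ``qa_records.csv``, ``volumes.csv``, ``cohort_summary.csv``,
    ``descriptive_stats.csv`` and histogram images under ``out_dir``;
    returns the per-subject results and the cohort summary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cfg.cohort.n_subjects < 1:
        raise ValidationError("cohort must contain at least one subject")

    master = np.random.SeedSequence(cfg.seed)
    n_extra = cfg.cohort.n_atlases
    seeds = master.generate_state(
        2 * cfg.cohort.n_subjects + n_extra + 2
    ) % (2**31 - 1)
    rng = np.random.default_rng(int(seeds[0]))

    # atlas prototypes are drawn from the same anatomical distribution as
    # the cohort (the study's prototypes were selected to span the
    # phenotype range), artifact-free, then calibrated
    atlas_rng = np.random.default_rng(int(seeds[1]))
    atlases = []
    for a in range(cfg.cohort.n_atlases if cfg.cohort.segment else 0):
        spec = _subject_spec(cfg, int(seeds[2 + a]), atlas_rng, None)
        res = ph.generate_phantom(spec)
        vol = pp.calibrate_volume(pp.merge_slabs(res.slabs))
        from .types import AtlasPrototype
        atlases.append(AtlasPrototype(volume=vol, labels=res.labels,
                                      sex="F" if a % 2 == 0 else "M",
                                      prototype_id=f"atlas{a:02d}"))

    artifacts = _subject_artifacts(cfg, rng)
    results: list[SubjectResult] = []
    for i in range(cfg.cohort.n_subjects):
        sid = f"S{i:04d}"
        try:
            spec = _subject_spec(cfg, int(seeds[2 + n_extra + i]), rng,
                                 artifacts[i])
            res = ph.generate_phantom(spec)
            results.append(process_subject(sid, res, atlases, cfg))
        except DixonError as exc:
            logger.error("subject %s failed: %s", sid, exc)
            rec = qa.apply_acceptance_protocol(
                QARecord(subject_id=sid, other_reason_fat="processing_failure",
                         other_reason_left_thigh="processing_failure",
                         other_reason_right_thigh="processing_failure")
            )
            results.append(SubjectResult(sid, rec, None, None))

    records = [r.record for r in results]
    write_qa_records(records, out_dir / "qa_records.csv")

    rows = []
    for r in results:
        row = {"subject_id": r.subject_id}
        row.update(r.volumes.as_dict() if r.volumes else
                   {k: "" for k in CompartmentVolumes().as_dict()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "volumes.csv", index=False)

    summary = qa.summarize_cohort(records)
    srows = [
        {"measure": "n", "count": summary.n, "percent": ""},
        {"measure": "analysable_fat", "count": summary.analysable_fat,
         "percent": summary.analysable_fat_pct},
        {"measure": "analysable_fat_one_thigh",
         "count": summary.analysable_fat_one_thigh,
         "percent": summary.analysable_fat_one_thigh_pct},
        {"measure": "analysable_fat_both_thighs",
         "count": summary.analysable_fat_both_thighs,
         "percent": summary.analysable_fat_both_thighs_pct},
    ]
    for flag, c in summary.flag_counts.items():
        srows.append({"measure": flag, "count": c,
                      "percent": summary.flag_percentages[flag]})
    for code, c in summary.rejection_reason_counts.items():
        srows.append({"measure": f"rejection:{code}", "count": c,
                      "percent": summary.rejection_reason_percentages[code]})
    pd.DataFrame(srows).to_csv(out_dir / "cohort_summary.csv", index=False)

    fully = [
        r.volumes if (r.volumes is not None and r.record.analysable_left_thigh
                      and r.record.analysable_right_thigh) else None
        for r in results
    ]
    stats = None
    if any(v is not None for v in fully):
        stats = qa.descriptive_stats(fully, bins=20)
        pd.DataFrame({
            "measurement": list(stats.mean),
            "mean_l": [stats.mean[m] for m in stats.mean],
            "sd_l": [stats.sd[m] for m in stats.mean],
            "min_l": [stats.min[m] for m in stats.mean],
            "max_l": [stats.max[m] for m in stats.mean],
        }).to_csv(out_dir / "descriptive_stats.csv", index=False)
        _plot_histograms(stats, out_dir / "histograms.png")

    return {"results": results, "summary": summary, "stats": stats}


def _plot_histograms(stats, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    titles = {
        "vat_l": "VAT [L]", "asat_l": "ASAT [L]",
        "total_trunk_fat_l": "Total trunk fat [L]",
        "total_thigh_l": "Total thigh [L]",
    }
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, (key, title) in zip(axes.ravel(), titles.items()):
        edges, counts = stats.histograms[key]
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
               color="0.4", edgecolor="white")
        ax.set_xlabel(title)
        ax.set_ylabel("subjects")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
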