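"""Volume and table I/O.

Volumes are stored as NIfTI (.nii.gz), one file per channel, float32 on
disk, with a JSON sidecar for acquisition metadata that NIfTI headers do
not carry (slab index, breath-hold flag, provenance).  The NIfTI affine is
diagonal: in-plane coordinates centred on the FOV, z measured from the
inferior edge of the imaged volume.

QA record tables are CSV with a fixed, documented column order.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError
from .types import (
    QA_FLAG_FIELDS,
    DixonSlab,
    DixonVolume,
    LabelMap,
    QARecord,
)

__all__ = [
    "read_slab",
    "write_slab",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "write_qa_records",
    "read_qa_records",
]

_QA_COLUMNS = (
    ["subject_id"]
    + list(QA_FLAG_FIELDS)
    + [
        "missing_slabs",
        "landmark_valid_abdomen",
        "landmark_valid_thigh",
        "tilted_subject",
        "tilt_clipped_sides",
        "metal_regions",
        "other_reason_fat",
        "other_reason_left_thigh",
        "other_reason_right_thigh",
        "analysable_fat",
        "analysable_left_thigh",
        "analysable_right_thigh",
        "rejection_reasons_fat",
        "rejection_reasons_left_thigh",
        "rejection_reasons_right_thigh",
    ]
)


def _affine(voxel_size, shape, z_offset) -> np.ndarray:
    dx, dy, dz = voxel_size
    aff = np.diag([dx, dy, dz, 1.0])
    aff[0, 3] = -(shape[0] - 1) / 2.0 * dx
    aff[1, 3] = -(shape[1] - 1) / 2.0 * dy
    aff[2, 3] = z_offset
    return aff


def _save_nifti(data: np.ndarray, voxel_size, z_offset, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          _affine(voxel_size, data.shape, z_offset))
    img.header.set_zooms(voxel_size)
    nib.save(img, str(path))


def _load_nifti(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    zooms = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    z_offset = float(img.affine[2, 3])
    return data, zooms, z_offset


def write_slab(slab: DixonSlab, directory, stem: str | None = None) -> dict:
    """Write one slab as ``<stem>_water.nii.gz`` / ``<stem>_fat.nii.gz`` + sidecar.

    Returns a dict of the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"slab{slab.slab_index}"
    paths = {
        "water": directory / f"{stem}_water.nii.gz",
        "fat": directory / f"{stem}_fat.nii.gz",
        "meta": directory / f"{stem}_meta.json",
    }
    _save_nifti(slab.water, slab.voxel_size, slab.z_offset, paths["water"])
    _save_nifti(slab.fat, slab.voxel_size, slab.z_offset, paths["fat"])
    meta = {
        "slab_index": int(slab.slab_index),
        "z_offset": float(slab.z_offset),
        "breath_hold": bool(slab.breath_hold),
        "voxel_size": [float(v) for v in slab.voxel_size],
        "n_slices": int(slab.n_slices),
    }
    paths["meta"].write_text(json.dumps(meta, indent=1))
    return paths


def read_slab(path_water, path_fat, metadata) -> DixonSlab:
    """Read a water/fat slab pair, cross-checking geometry against metadata.

    ``metadata`` may be a dict or a path to the JSON sidecar written by
    :func:`write_slab`.
    """
    if not isinstance(metadata, dict):
        metadata = json.loads(Path(metadata).read_text())
    water, wz, woff = _load_nifti(path_water)
    fat, fz, foff = _load_nifti(path_fat)
    if water.shape != fat.shape:
        raise StructuralError(
            f"water grid {water.shape} does not match fat grid {fat.shape}"
        )
    if wz != fz or abs(woff - foff) > 1e-3:
        raise StructuralError("water and fat slab geometries disagree")
    vs = tuple(float(v) for v in metadata.get("voxel_size", wz))
    if any(abs(a - b) > 1e-3 for a, b in zip(vs, wz)):
        raise StructuralError(
            f"header voxel size {wz} disagrees with metadata {vs}"
        )
    if "n_slices" in metadata and int(metadata["n_slices"]) != water.shape[2]:
        raise StructuralError("slice count disagrees with metadata")
    z_offset = float(metadata.get("z_offset", woff))
    if abs(z_offset - woff) > 1e-3:
        raise StructuralError("z offset disagrees with metadata")
    if (water < 0).any() or (fat < 0).any():
        raise ValidationError("negative intensities in slab files")
    return DixonSlab(
        water=water,
        fat=fat,
        voxel_size=wz,
        z_offset=z_offset,
        slab_index=int(metadata["slab_index"]),
        breath_hold=bool(metadata.get("breath_hold", False)),
    )


def write_volume(volume: DixonVolume, directory, stem: str = "composite") -> dict:
    """Write a composite volume (both channels + provenance sidecar)."""
    if volume.shape[2] == 0:
        raise ValidationError("cannot write an empty volume")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "water": directory / f"{stem}_water.nii.gz",
        "fat": directory / f"{stem}_fat.nii.gz",
        "meta": directory / f"{stem}_meta.json",
    }
    _save_nifti(volume.water, volume.voxel_size, volume.z_offset, paths["water"])
    _save_nifti(volume.fat, volume.voxel_size, volume.z_offset, paths["fat"])
    meta = {
        "voxel_size": [float(v) for v in volume.voxel_size],
        "z_offset": float(volume.z_offset),
        "provenance": [list(p) for p in volume.provenance],
        "coverage_gaps": [int(g) for g in volume.coverage_gaps],
    }
    paths["meta"].write_text(json.dumps(meta))
    return paths


def read_volume(directory, stem: str = "composite") -> DixonVolume:
    directory = Path(directory)
    water, vs, zoff = _load_nifti(directory / f"{stem}_water.nii.gz")
    fat, vs2, zoff2 = _load_nifti(directory / f"{stem}_fat.nii.gz")
    if water.shape != fat.shape or vs != vs2:
        raise StructuralError("stored water/fat volumes disagree")
    meta_path = directory / f"{stem}_meta.json"
    provenance, gaps = [], []
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        provenance = [tuple(p) for p in meta.get("provenance", [])]
        gaps = list(meta.get("coverage_gaps", []))
    return DixonVolume(
        water=water, fat=fat, voxel_size=vs, z_offset=zoff,
        provenance=provenance, coverage_gaps=gaps,
    )


def write_labels(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(
        labels.labels.astype(np.int16),
        _affine(labels.voxel_size, labels.shape, labels.z_offset),
    )
    img.header.set_zooms(labels.voxel_size)
    nib.save(img, str(path))


def read_labels(path) -> LabelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValidationError("label file contains non-integer values")
    zooms = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    return LabelMap(labels=data.astype(np.int16), voxel_size=zooms,
                    z_offset=float(img.affine[2, 3]))


def _encode_set(values) -> str:
    return ";".join(str(v) for v in sorted(values))


def _decode_set(text) -> frozenset:
    if text is None or text == "" or (isinstance(text, float) and np.isnan(text)):
        return frozenset()
    return frozenset(str(text).split(";"))


def write_qa_records(records: list[QARecord], path) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id}
        row.update(r.flags())
        row.update(
            missing_slabs=_encode_set(r.missing_slabs),
            landmark_valid_abdomen=r.landmark_valid_abdomen,
            landmark_valid_thigh=r.landmark_valid_thigh,
            tilted_subject=r.tilted_subject,
            tilt_clipped_sides=_encode_set(r.tilt_clipped_sides),
            metal_regions=_encode_set(r.metal_regions),
            other_reason_fat=r.other_reason_fat or "",
            other_reason_left_thigh=r.other_reason_left_thigh or "",
            other_reason_right_thigh=r.other_reason_right_thigh or "",
            analysable_fat=r.analysable_fat,
            analysable_left_thigh=r.analysable_left_thigh,
            analysable_right_thigh=r.analysable_right_thigh,
            rejection_reasons_fat=_encode_set(r.rejection_reasons_fat),
            rejection_reasons_left_thigh=_encode_set(r.rejection_reasons_left_thigh),
            rejection_reasons_right_thigh=_encode_set(r.rejection_reasons_right_thigh),
        )
        rows.append(row)
    pd.DataFrame(rows, columns=_QA_COLUMNS).to_csv(path, index=False)


def read_qa_records(path) -> list[QARecord]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    records = []

    def _bool(v):
        if isinstance(v, str):
            if v == "":
                return None
            return v.strip().lower() == "true"
        return bool(v)

    for _, row in df.iterrows():
        records.append(
            QARecord(
                subject_id=str(row["subject_id"]),
                **{f: _bool(row[f]) for f in QA_FLAG_FIELDS},
                missing_slabs=frozenset(int(i) for i in _decode_set(row["missing_slabs"])),
                landmark_valid_abdomen=_bool(row["landmark_valid_abdomen"]),
                landmark_valid_thigh=_bool(row["landmark_valid_thigh"]),
                tilted_subject=_bool(row["tilted_subject"]),
                tilt_clipped_sides=_decode_set(row["tilt_clipped_sides"]),
                metal_regions=_decode_set(row["metal_regions"]),
                other_reason_fat=row["other_reason_fat"] or None,
                other_reason_left_thigh=row["other_reason_left_thigh"] or None,
                other_reason_right_thigh=row["other_reason_right_thigh"] or None,
                analysable_fat=_bool(row["analysable_fat"]),
                analysable_left_thigh=_bool(row["analysable_left_thigh"]),
                analysable_right_thigh=_bool(row["analysable_right_thigh"]),
                rejection_reasons_fat=tuple(sorted(_decode_set(row["rejection_reasons_fat"]))),
                rejection_reasons_left_thigh=tuple(sorted(_decode_set(row["rejection_reasons_left_thigh"]))),
                rejection_reasons_right_thigh=tuple(sorted(_decode_set(row["rejection_reasons_right_thigh"]))),
            )
        )
    return records
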