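"""Shared domain types for the Dixon body-composition pipeline.

Conventions
-----------
* Image arrays are indexed ``[x, y, z]``; the axial (z) axis increases
  foot -> head.  Voxel indices are 0-based.
* World coordinates are in millimetres.  In-plane (x, y) coordinates are
  centred on the field of view; axial position is measured from the
  inferior edge of the imaged volume, with ``z_offset`` giving the world
  z of the centre of the first (most inferior) slice.
* All signal intensities are non-negative magnitudes in arbitrary units
  until calibration, after which pure adipose tissue has fat signal ~ 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import numpy as np

from .errors import StructuralError, ValidationError

__all__ = [
    "Label",
    "MUSCLE_LABELS",
    "FAT_LABELS",
    "round_half_up",
    "percentage",
    "DixonSlab",
    "DixonVolume",
    "LabelMap",
    "AtlasPrototype",
    "CompartmentVolumes",
    "QARecord",
    "CohortSummary",
]


class Label(enum.IntEnum):
    """Compartment label codes used throughout the pipeline."""

    BACKGROUND = 0
    VAT = 1            # visceral adipose tissue
    ASAT = 2           # abdominal subcutaneous adipose tissue
    LEFT_ANTERIOR_THIGH = 3
    RIGHT_ANTERIOR_THIGH = 4
    LEFT_POSTERIOR_THIGH = 5
    RIGHT_POSTERIOR_THIGH = 6


MUSCLE_LABELS = (
    Label.LEFT_ANTERIOR_THIGH,
    Label.RIGHT_ANTERIOR_THIGH,
    Label.LEFT_POSTERIOR_THIGH,
    Label.RIGHT_POSTERIOR_THIGH,
)
FAT_LABELS = (Label.VAT, Label.ASAT)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (the convention of the printed tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, n: int, decimals: int = 2) -> float:
    """100 * count / n, rounded half-up to ``decimals`` places."""
    if n <= 0:
        raise ValidationError("percentage denominator must be positive")
    return round_half_up(100.0 * count / n, decimals)


def _check_channels(water: np.ndarray, fat: np.ndarray) -> None:
    if water.ndim != 3 or fat.ndim != 3:
        raise ValidationError("water and fat must be 3D arrays")
    if water.shape != fat.shape:
        raise StructuralError(
            f"water grid {water.shape} does not match fat grid {fat.shape}"
        )
    if not (np.isfinite(water).all() and np.isfinite(fat).all()):
        raise ValidationError("intensities must be finite")
    if (water < 0).any() or (fat < 0).any():
        raise ValidationError("intensities must be non-negative")


@dataclass
class DixonSlab:
    """One axial acquisition slab: a water/fat channel pair on a common grid.

    Parameters
    ----------
    water, fat:
        3D magnitude images, identical shape ``(nx, ny, nz)``.
    voxel_size:
        ``(dx, dy, dz)`` in mm.
    z_offset:
        World z (mm) of the centre of the first slice, measured from the
        inferior edge of the imaged volume.
    slab_index:
        Position in the acquisition protocol, 1 (neck) .. 6 (knees).
    breath_hold:
        True for the abdominal slabs acquired during a breath-hold.
    """

    water: np.ndarray
    fat: np.ndarray
    voxel_size: tuple[float, float, float]
    z_offset: float
    slab_index: int
    breath_hold: bool = False

    def __post_init__(self) -> None:
        _check_channels(self.water, self.fat)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size must be three positive lengths (mm)")
        if not 1 <= int(self.slab_index):
            raise ValidationError("slab_index must be a positive integer")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.water.shape

    @property
    def n_slices(self) -> int:
        return self.water.shape[2]

    @property
    def z_positions(self) -> np.ndarray:
        """World z (mm) of each slice centre."""
        return self.z_offset + np.arange(self.n_slices) * self.voxel_size[2]

    @property
    def z_extent(self) -> tuple[float, float]:
        """World z-range covered by the slab, edge to edge (mm)."""
        dz = self.voxel_size[2]
        return (self.z_offset - dz / 2, self.z_offset + (self.n_slices - 0.5) * dz)

    def copy(self) -> "DixonSlab":
        return replace(self, water=self.water.copy(), fat=self.fat.copy())


@dataclass
class DixonVolume:
    """Composite (or single-slab) water/fat volume on a uniform grid."""

    water: np.ndarray
    fat: np.ndarray
    voxel_size: tuple[float, float, float]
    z_offset: float = 0.0
    #: per-slice tuple of contributing slab indices (empty tuple = coverage gap)
    provenance: list = field(default_factory=list)
    #: slice indices with no slab coverage (interior gaps are QA findings)
    coverage_gaps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_channels(self.water, self.fat)
        if self.water.shape[2] == 0:
            raise ValidationError("volume must contain at least one slice")
        if not self.provenance:
            self.provenance = [()] * self.water.shape[2]
        if len(self.provenance) != self.water.shape[2]:
            raise ValidationError("provenance must have one entry per slice")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.water.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    @property
    def z_positions(self) -> np.ndarray:
        return self.z_offset + np.arange(self.shape[2]) * self.voxel_size[2]

    @property
    def z_extent(self) -> tuple[float, float]:
        dz = self.voxel_size[2]
        return (self.z_offset - dz / 2, self.z_offset + (self.shape[2] - 0.5) * dz)

    def total(self) -> np.ndarray:
        return self.water + self.fat

    def copy(self) -> "DixonVolume":
        return replace(
            self,
            water=self.water.copy(),
            fat=self.fat.copy(),
            provenance=list(self.provenance),
            coverage_gaps=list(self.coverage_gaps),
        )


@dataclass
class LabelMap:
    """Integer compartment labels on a DixonVolume grid."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        codes = np.unique(self.labels)
        allowed = {int(l) for l in Label}
        if not set(codes.tolist()) <= allowed:
            raise ValidationError(f"unknown label codes: {set(codes.tolist()) - allowed}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def mask(self, label: Label) -> np.ndarray:
        return self.labels == int(label)

    def volume_l(self, label: Label) -> float:
        """Anatomical (voxel-count) volume of one compartment, in litres."""
        return float(self.mask(label).sum()) * self.voxel_volume_mm3 / 1e6

    def copy(self) -> "LabelMap":
        return replace(self, labels=self.labels.copy())


@dataclass
class AtlasPrototype:
    """An atlas: a segmented reference subject used as a segmentation prior."""

    volume: DixonVolume
    labels: LabelMap
    sex: str = "F"
    prototype_id: str = ""

    def __post_init__(self) -> None:
        if self.labels.shape != self.volume.shape:
            raise StructuralError("atlas labels must share the volume grid")
        if self.sex not in ("F", "M"):
            raise ValidationError("sex must be 'F' or 'M'")


@dataclass
class CompartmentVolumes:
    """Quantified compartment volumes for one subject, in litres."""

    vat_l: float = 0.0
    asat_l: float = 0.0
    lat_l: float = 0.0   # left anterior thigh
    rat_l: float = 0.0   # right anterior thigh
    lpt_l: float = 0.0   # left posterior thigh
    rpt_l: float = 0.0   # right posterior thigh

    def __post_init__(self) -> None:
        for name in ("vat_l", "asat_l", "lat_l", "rat_l", "lpt_l", "rpt_l"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def total_trunk_fat_l(self) -> float:
        return self.vat_l + self.asat_l

    @property
    def total_thigh_l(self) -> float:
        return self.lat_l + self.rat_l + self.lpt_l + self.rpt_l

    def by_label(self, label: Label) -> float:
        return {
            Label.VAT: self.vat_l,
            Label.ASAT: self.asat_l,
            Label.LEFT_ANTERIOR_THIGH: self.lat_l,
            Label.RIGHT_ANTERIOR_THIGH: self.rat_l,
            Label.LEFT_POSTERIOR_THIGH: self.lpt_l,
            Label.RIGHT_POSTERIOR_THIGH: self.rpt_l,
        }[label]

    def as_dict(self) -> dict:
        return {
            "vat_l": self.vat_l,
            "asat_l": self.asat_l,
            "lat_l": self.lat_l,
            "rat_l": self.rat_l,
            "lpt_l": self.lpt_l,
            "rpt_l": self.rpt_l,
            "total_trunk_fat_l": self.total_trunk_fat_l,
            "total_thigh_l": self.total_thigh_l,
        }


# QA flag names reported at cohort level, in the fixed order of the tables.
QA_FLAG_FIELDS = (
    "respiratory_artifact",
    "metal_contamination",
    "swap_sat",
    "swap_liver_top",
    "swap_thigh",
    "swap_separate_island",
    "outer_fov_inhomogeneity",
    "incomplete_knee_coverage",
)

# Rejection reason codes, in precedence order for "primary reason" reporting.
REASON_PRECEDENCE = ("missing_slabs", "landmark_invalid", "tilted", "other")


@dataclass
class QARecord:
    """Per-subject QA flags and per-compartment analysability decisions.

    Raw artifact flags are observations; the ``analysable_*`` fields are a
    pure function of the remaining fields under the data-acceptance
    protocol (``qa.apply_acceptance_protocol``).
    """

    subject_id: str
    respiratory_artifact: bool = False
    metal_contamination: bool = False
    swap_sat: bool = False
    swap_liver_top: bool = False
    swap_thigh: bool = False
    swap_separate_island: bool = False
    outer_fov_inhomogeneity: bool = False
    incomplete_knee_coverage: bool = False
    missing_slabs: frozenset = frozenset()
    landmark_valid_abdomen: bool = True
    landmark_valid_thigh: bool = True
    tilted_subject: bool = False
    #: which thighs a tilt actually clips: subset of {"left", "right"}
    tilt_clipped_sides: frozenset = frozenset()
    #: body regions with metal voids: subset of {"abdomen", "left_thigh", "right_thigh"}
    metal_regions: frozenset = frozenset()
    #: free-text "other" blockers per region; None = no blocker
    other_reason_fat: Optional[str] = None
    other_reason_left_thigh: Optional[str] = None
    other_reason_right_thigh: Optional[str] = None
    # decided by the acceptance protocol
    analysable_fat: Optional[bool] = None
    analysable_left_thigh: Optional[bool] = None
    analysable_right_thigh: Optional[bool] = None
    rejection_reasons_fat: tuple = ()
    rejection_reasons_left_thigh: tuple = ()
    rejection_reasons_right_thigh: tuple = ()

    def flags(self) -> dict:
        return {name: bool(getattr(self, name)) for name in QA_FLAG_FIELDS}

    @property
    def decided(self) -> bool:
        return self.analysable_fat is not None

    def primary_reason(self) -> Optional[str]:
        """Highest-precedence rejection reason across compartments, if any."""
        reasons = set(
            self.rejection_reasons_fat
            + self.rejection_reasons_left_thigh
            + self.rejection_reasons_right_thigh
        )
        base = {r.split(":")[0] for r in reasons}
        for code in REASON_PRECEDENCE:
            if code in base:
                return code
        return None


@dataclass
class CohortSummary:
    """Cohort-level QA aggregation (counts and two-decimal percentages)."""

    n: int
    flag_counts: dict
    flag_percentages: dict
    analysable_fat: int
    analysable_fat_one_thigh: int      # fat AND at least one thigh
    analysable_fat_both_thighs: int
    analysable_fat_pct: float
    analysable_fat_one_thigh_pct: float
    analysable_fat_both_thighs_pct: float
    n_rejected: int                    # subjects with any rejected compartment
    rejection_reason_counts: dict
    rejection_reason_percentages: dict  # shares of n_rejected

    def __post_init__(self) -> None:
        if not (
            self.analysable_fat_both_thighs
            <= self.analysable_fat_one_thigh
            <= self.analysable_fat
            <= self.n
        ):
            raise ValidationError("analysability tiers must be nested")
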