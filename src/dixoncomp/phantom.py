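"""Synthetic neck-to-knee Dixon phantoms with volumetric ground truth.

The phantom emulates the six-slab axial acquisition geometry of a
large-cohort neck-to-knee Dixon protocol: six overlapping slabs with the
protocol's per-slab slice counts and voxel sizes (64 slices at 3 mm over
the neck, three 44-slice 4.5 mm breath-hold slabs over the abdomen, a
72-slice 3.5 mm slab and a 64-slice 4 mm slab over the thighs), covering
~1.1 m.  A ``scale`` factor uniformly coarsens the grids for desk-scale
work.

The body is a stack of superellipse cross-sections: a torso with a
subcutaneous fat rind, an abdominal muscle wall and a visceral cavity, a
liver-like organ capping the cavity, a narrowing shoulder/neck section,
and two cylindrical thighs with fat rinds and anterior/posterior muscle
compartments.  Anatomical realism is a non-goal; the contract is exact
volumetric ground truth: each target compartment is rendered by
thresholding a continuous placement key at the N-th smallest value over
the grid, so the rendered voxel count equals ``round(target / voxel
volume)`` and the ground-truth volume matches the target to within half a
voxel.

Signal model: piecewise-constant class means (fat, muscle, organ, air),
a smooth multiplicative bias field, and multiplicative Gaussian noise.
Artifacts reproducing every QA category (water-fat swaps, metal voids,
respiratory ghosting, missing slabs, positioning failures) can be
injected with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .types import (
    CompartmentVolumes,
    DixonSlab,
    Label,
    LabelMap,
    QARecord,
)

__all__ = [
    "SLAB_TABLE",
    "ProtocolGrid",
    "PhantomSpec",
    "ArtifactSpec",
    "PhantomResult",
    "ARTIFACT_KINDS",
    "generate_phantom",
    "inject_artifact",
    "generate_atlas_set",
    "generate_cohort_fixture",
]

# ---------------------------------------------------------------------------
# acquisition protocol geometry

#: (slab_index, n_slices, dz_mm, breath_hold) for the full-resolution protocol,
#: slab 1 over the neck down to slab 6 over the knees.
SLAB_TABLE = (
    (1, 64, 3.0, False),
    (2, 44, 4.5, True),
    (3, 44, 4.5, True),
    (4, 44, 4.5, True),
    (5, 72, 3.5, False),
    (6, 64, 4.0, False),
)
MATRIX = (224, 174)
IN_PLANE_MM = 2.23
OVERLAP_SLICES = 8  # overlap between adjacent slabs, in slices of the lower slab


@dataclass(frozen=True)
class ProtocolGrid:
    """Slab and composite grid geometry at a given desk-scale factor.

    ``scale`` coarsens the axial sampling (slice counts and spacings);
    ``scale_xy`` the in-plane matrix (defaults to ``scale``).  The native
    acquisition is itself anisotropic, so independent factors stay within
    the protocol's character.
    """

    scale: float = 1.0
    overlap_slices: int | None = None
    scale_xy: float | None = None

    @property
    def _sxy(self) -> float:
        return self.scale_xy if self.scale_xy is not None else self.scale

    @property
    def nx(self) -> int:
        return max(8, round(MATRIX[0] / self._sxy))

    @property
    def ny(self) -> int:
        return max(8, round(MATRIX[1] / self._sxy))

    @property
    def dxy(self) -> float:
        return IN_PLANE_MM * self._sxy

    @property
    def overlap(self) -> int:
        if self.overlap_slices is not None:
            return self.overlap_slices
        return max(2, round(OVERLAP_SLICES / self.scale))

    def slab_geometry(self) -> list[dict]:
        """Per-slab dict: index, n_slices, dz, z_offset (first-slice centre), breath_hold."""
        slabs = []
        for idx, n, dz, bh in SLAB_TABLE:
            slabs.append(
                dict(
                    slab_index=idx,
                    n_slices=max(4, round(n / self.scale)),
                    dz=dz * self.scale,
                    breath_hold=bh,
                )
            )
        # stack from the knees (slab 6, bottom edge at z = 0) upwards
        z_bottom = 0.0
        for s in reversed(slabs):
            s["z_offset"] = z_bottom + s["dz"] / 2
            z_bottom += (s["n_slices"] - self.overlap) * s["dz"]
        return slabs

    def in_plane_coords(self) -> tuple[np.ndarray, np.ndarray]:
        x = (np.arange(self.nx) - (self.nx - 1) / 2) * self.dxy
        y = (np.arange(self.ny) - (self.ny - 1) / 2) * self.dxy
        return x, y

    @property
    def fov_half(self) -> tuple[float, float]:
        return (self.nx * self.dxy / 2, self.ny * self.dxy / 2)


def composite_z_grid(z_offsets, n_slices, dzs) -> tuple[float, float, int]:
    """Common z-grid covering a set of slabs: (z0, dz, n) of slice centres."""
    dz = float(min(dzs))
    z0 = float(min(z_offsets))
    zmax = float(max(o + (n - 1) * d for o, n, d in zip(z_offsets, n_slices, dzs)))
    n = int(math.floor((zmax - z0) / dz + 0.5)) + 1
    return z0, dz, n


# ---------------------------------------------------------------------------
# anatomy layout (mm, nominal anatomical frame; z = 0 at the knee edge)

KNEE_Z = 60.0            # femoral epicondyles
THIGH_BOTTOM = 25.0
THIGH_TOP = 480.0        # crotch / hip transition
FEMHEAD_TOP = 520.0      # top of the femoral head (lower ASAT bound)
T9_Z = 850.0             # top of vertebra T9 (upper ASAT bound)
CAVITY_Z = (500.0, 870.0)
LIVER_Z = (820.0, 870.0)
VAT_Z = (520.0, 770.0)   # kept clear of the liver zone by construction
LUNG_Z = (880.0, 1000.0)
TRACHEA_Z = 990.0        # air channel from the lungs out through the neck
TRACHEA_R = 14.0
TORSO_Z = (480.0, 950.0)
NECK_TOP = 1200.0
SHOULDER_Z = 950.0
TILT_PIVOT = 700.0
ANTERIOR_SPLIT_Y = 20.0   # anterior/posterior thigh split plane (posterior larger)

_HEIGHT_SHIFT = {"short": 20.0, "average": 0.0, "tall": -80.0}

# tissue classes
_AIR, _FAT, _MUSCLE, _ORGAN = 0, 1, 2, 3


@dataclass
class ArtifactSpec:
    """One injectable artifact; each kind triggers exactly one QA flag."""

    kind: str
    params: dict = field(default_factory=dict)


#: artifact kind -> the QARecord flag/criterion it is designed to trigger
ARTIFACT_KINDS = {
    "missing_slab": "missing_slabs",
    "swap_separate_island": "swap_separate_island",
    "swap_liver_top": "swap_liver_top",
    "swap_sat": "swap_sat",
    "swap_thigh": "swap_thigh",
    "outer_fov_inhomogeneity": "outer_fov_inhomogeneity",
    "metal_void": "metal_contamination",
    "respiratory_ghosting": "respiratory_artifact",
    "invalid_landmark": "landmark_valid_thigh",
    "tilted_subject": "tilted_subject",
    "tall_subject": "incomplete_knee_coverage",
}
_ANATOMY_KINDS = ("invalid_landmark", "tilted_subject", "tall_subject")


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic subject.

    Default compartment targets are the cohort means of the study this
    geometry emulates (VAT 3.73 L, ASAT 6.91 L, thigh muscles 1.66/1.68/
    3.36/3.39 L), used as a realistic operating point.
    """

    subject_height_class: str = "average"
    scale: float = 2.0                   # desk-scale grid coarsening factor (axial)
    scale_xy: float | None = None        # in-plane factor; defaults to scale
    torso_a: float = 230.0               # torso half-width, mm
    torso_b: float = 135.0               # torso half-depth, mm
    torso_exponent: float = 2.5          # superellipse exponent
    thigh_radius: float = 100.0
    thigh_offset_x: float = 115.0
    neck_radius: float = 70.0
    sat_torso_mm: float = 28.0           # subcutaneous rind thickness
    sat_thigh_mm: float = 20.0
    wall_mm: float = 15.0                # abdominal muscle wall thickness
    vat_l: float = 3.73
    asat_l: float = 6.91
    lat_l: float = 1.66
    rat_l: float = 1.68
    lpt_l: float = 3.36
    rpt_l: float = 3.39
    landmark_offset_mm: float = 0.0      # axial mis-positioning of the subject
    tilt_deg: float = 0.0                # in-plane tilt of the body axis
    bias_amplitude: float = 0.2          # +-20% multiplicative inhomogeneity
    bias_length_mm: float = 150.0
    noise_sd: float = 0.025              # fractional (multiplicative) noise
    muscle_fat_fraction: float = 0.10
    organ_fat_fraction: float = 0.05
    fat_water_epsilon: float = 0.02      # residual water signal in pure fat
    s_fat: float = 600.0                 # class signal levels, arbitrary units
    s_muscle: float = 500.0
    s_organ: float = 550.0
    overlap_slices: int | None = None
    artifact_list: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_height_class not in _HEIGHT_SHIFT:
            raise ValidationError(
                f"unknown height class {self.subject_height_class!r}"
            )
        for name in ("vat_l", "asat_l", "lat_l", "rat_l", "lpt_l", "rpt_l"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.scale < 1:
            raise ValidationError("scale must be >= 1")
        if not 0 <= self.bias_amplitude < 1:
            raise ValidationError("bias_amplitude must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    @property
    def targets(self) -> dict:
        return {
            Label.VAT: self.vat_l,
            Label.ASAT: self.asat_l,
            Label.LEFT_ANTERIOR_THIGH: self.lat_l,
            Label.RIGHT_ANTERIOR_THIGH: self.rat_l,
            Label.LEFT_POSTERIOR_THIGH: self.lpt_l,
            Label.RIGHT_POSTERIOR_THIGH: self.rpt_l,
        }


class PhantomGeometry:
    """Continuous anatomy of one phantom; evaluable on any voxel grid.

    Holds the effective anatomical shift/tilt (after positioning
    artifacts), the compartment placement thresholds computed on the
    composite grid, the analytic bias field, and the landmark positions.
    """

    def __init__(self, spec: PhantomSpec, shift: float, tilt_deg: float, rng):
        self.spec = spec
        self.shift = shift
        self.tilt_deg = tilt_deg
        self.grid = ProtocolGrid(spec.scale, spec.overlap_slices, spec.scale_xy)
        self.thresholds: dict = {}
        # smooth multiplicative bias: mean of three seeded plane-wave cosines
        a = spec.bias_amplitude
        dirs = rng.normal(size=(3, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        self._bias_dirs, self._bias_phases, self._bias_amp = dirs, phases, a

    # -- coordinate helpers -------------------------------------------------
    def _anat(self, x, y, z):
        """World -> anatomical coordinates (shift + in-plane tilt shear)."""
        z_anat = z - self.shift
        if self.tilt_deg:
            shear = math.tan(math.radians(self.tilt_deg)) * np.clip(
                TILT_PIVOT - z_anat, 0.0, None
            )
            x_eff = x - shear
        else:
            x_eff = x + np.zeros_like(z_anat)
        return x_eff, y, z_anat

    def bias(self, x, y, z) -> np.ndarray:
        L = self.spec.bias_length_mm
        out = np.zeros(np.broadcast_shapes(x.shape, y.shape, z.shape))
        for k, phi in zip(self._bias_dirs, self._bias_phases):
            out += np.cos(2 * np.pi * (k[0] * x + k[1] * y + k[2] * z) / L + phi)
        return 1.0 + self._bias_amp * out / 3.0

    # -- anatomy fields -----------------------------------------------------
    def fields(self, x, y, z) -> dict:
        """Geometry masks and placement keys on the broadcast grid x, y, z.

        x, y, z must be broadcastable to the 3D voxel grid (world mm).
        """
        s = self.spec
        xe, ye, za = self._anat(x, y, z)
        shape = np.broadcast_shapes(xe.shape, np.shape(ye), za.shape)
        xe = np.broadcast_to(xe, shape).astype(np.float32)
        ye = np.broadcast_to(ye, shape).astype(np.float32)
        za = np.broadcast_to(za, shape).astype(np.float32)

        # torso / shoulder superellipse, tapering above the shoulders
        t = np.clip((za - SHOULDER_Z) / (NECK_TOP - SHOULDER_Z), 0.0, 1.0)
        a_z = s.torso_a + (s.neck_radius - s.torso_a) * t
        b_z = s.torso_b + (s.neck_radius - s.torso_b) * t
        p = s.torso_exponent
        rho_t = (
            np.abs(xe / a_z) ** p + np.abs(ye / b_z) ** p
        ) ** (1.0 / p)
        torso_active = (za >= THIGH_TOP) & (za <= NECK_TOP)
        m_torso = np.where(torso_active, (1.0 - rho_t) * np.minimum(a_z, b_z), -1.0)

        # thighs: circular cylinders
        r = s.thigh_radius
        thigh_active = (za >= THIGH_BOTTOM) & (za <= THIGH_TOP)
        rho_l = np.sqrt((xe + s.thigh_offset_x) ** 2 + ye**2) / r
        rho_r = np.sqrt((xe - s.thigh_offset_x) ** 2 + ye**2) / r
        m_left = np.where(thigh_active, (1.0 - rho_l) * r, -1.0)
        m_right = np.where(thigh_active, (1.0 - rho_r) * r, -1.0)

        margins = np.stack([m_torso, m_left, m_right])
        provider = np.argmax(margins, axis=0)  # 0 torso, 1 left, 2 right
        m = margins.max(axis=0)
        body = m > 0

        sat_depth = np.where(provider == 0, s.sat_torso_mm, s.sat_thigh_mm)
        sat = body & (m <= sat_depth)
        # subcutaneous fat pads capping the exposed axial body surfaces
        # (groin below the abdominal cavity, above the knees): real bodies
        # carry subcutaneous fat there too, and without them bare muscle
        # would sit on the body surface
        sat |= body & (provider == 0) & (za < CAVITY_Z[0])
        sat |= body & (provider > 0) & (za <= THIGH_BOTTOM + s.sat_thigh_mm)
        interior = body & ~sat

        in_cavity_z = (za >= CAVITY_Z[0]) & (za <= CAVITY_Z[1])
        wall = interior & (provider == 0) & in_cavity_z & (
            m <= sat_depth + s.wall_mm
        )
        cavity = interior & (provider == 0) & in_cavity_z & (
            m > sat_depth + s.wall_mm
        )
        liver = cavity & (za >= LIVER_Z[0]) & (za <= LIVER_Z[1])

        # air-filled lungs capping the cavity, vented through a trachea so
        # they are not "enclosed" voids; gives the chest a signal gap like
        # real anatomy and bounds the abdominal interior from above
        lungs = (
            interior & (provider == 0)
            & (za >= LUNG_Z[0]) & (za <= LUNG_Z[1])
            & (m > sat_depth + s.wall_mm)
        )
        trachea = (za >= TRACHEA_Z) & (
            xe**2 + (ye - 20.0) ** 2 < TRACHEA_R**2
        ) & body

        # deterministic symmetry-breaking term so placement keys are
        # unique; float64 so mirror-symmetric voxels never collapse to
        # the same key (which would break exact-count rendering)
        xe64 = xe.astype(np.float64)
        ye64 = ye.astype(np.float64)
        za64 = za.astype(np.float64)
        tie = 1e-6 * (0.9171 * xe64 + 0.5374 * ye64 + 0.3119 * za64)
        vat_key = (
            np.sqrt(
                (xe64 / 1.7) ** 2 + ye64**2 + ((za64 - 650.0) / 1.9) ** 2
            )
            + tie
        )
        asat_key = np.abs(za64 - 685.0) + 0.01 * m + tie
        thigh_key = np.where(provider == 1, rho_l, rho_r).astype(np.float64) * r + tie

        return dict(
            body=body, m=m, provider=provider, z_anat=za, y=ye,
            sat=sat, wall=wall, cavity=cavity, liver=liver,
            lungs=lungs, trachea=trachea,
            vat_key=vat_key, asat_key=asat_key, thigh_key=thigh_key,
        )

    # -- compartment masks ----------------------------------------------------
    def _candidates(self, f: dict, label: Label) -> np.ndarray:
        za = f["z_anat"]
        if label == Label.VAT:
            return f["cavity"] & (za >= VAT_Z[0]) & (za <= VAT_Z[1])
        if label == Label.ASAT:
            return (
                f["sat"] & (f["provider"] == 0)
                & (za >= FEMHEAD_TOP) & (za <= T9_Z)
            )
        side = 1 if label in (Label.LEFT_ANTERIOR_THIGH, Label.LEFT_POSTERIOR_THIGH) else 2
        anterior = label in (Label.LEFT_ANTERIOR_THIGH, Label.RIGHT_ANTERIOR_THIGH)
        muscle = f["body"] & ~f["sat"] & (f["provider"] == side)
        ant = f["y"] > ANTERIOR_SPLIT_Y
        return muscle & (ant if anterior else ~ant)

    _KEYS = {
        Label.VAT: "vat_key",
        Label.ASAT: "asat_key",
        Label.LEFT_ANTERIOR_THIGH: "thigh_key",
        Label.RIGHT_ANTERIOR_THIGH: "thigh_key",
        Label.LEFT_POSTERIOR_THIGH: "thigh_key",
        Label.RIGHT_POSTERIOR_THIGH: "thigh_key",
    }

    def compute_thresholds(self, f: dict, voxel_volume_mm3: float) -> None:
        """Fix each compartment's placement threshold on the composite grid."""
        nominal = self.shift == 0 and self.tilt_deg == 0
        for label, target_l in self.spec.targets.items():
            n_target = int(round(target_l * 1e6 / voxel_volume_mm3))
            if n_target == 0:
                self.thresholds[label] = -np.inf
                continue
            cand = f[self._KEYS[label]][self._candidates(f, label)]
            if cand.size < n_target:
                if nominal:
                    raise ValidationError(
                        f"target volume for {label.name} ({target_l} L) does not "
                        f"fit inside the body geometry "
                        f"({cand.size * voxel_volume_mm3 / 1e6:.2f} L available)"
                    )
                self.thresholds[label] = np.inf  # clipped anatomy: take all
                continue
            self.thresholds[label] = float(np.partition(cand, n_target - 1)[n_target - 1])

    def compartment_mask(self, f: dict, label: Label) -> np.ndarray:
        thr = self.thresholds[label]
        if thr == -np.inf:
            return np.zeros(f["body"].shape, dtype=bool)
        return self._candidates(f, label) & (f[self._KEYS[label]] <= thr)

    def labels_from_fields(self, f: dict) -> np.ndarray:
        out = np.zeros(f["body"].shape, dtype=np.int16)
        for label in self.spec.targets:
            out[self.compartment_mask(f, label)] = int(label)
        return out

    def tissue_class(self, f: dict) -> np.ndarray:
        cls = np.full(f["body"].shape, _AIR, dtype=np.int8)
        cls[f["body"]] = _ORGAN          # unspecified interior: water tissue
        cls[f["sat"]] = _FAT
        cls[f["wall"]] = _MUSCLE
        cls[f["body"] & ~f["sat"] & (f["provider"] > 0)] = _MUSCLE  # thigh muscle
        cls[self.compartment_mask(f, Label.VAT)] = _FAT
        cls[f["lungs"]] = _AIR
        cls[f["trachea"]] = _AIR
        return cls

    def signals(self, cls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Noise- and bias-free (water, fat) channel values per tissue class."""
        s = self.spec
        water = np.zeros(cls.shape, dtype=np.float32)
        fat = np.zeros(cls.shape, dtype=np.float32)
        fat[cls == _FAT] = s.s_fat
        water[cls == _FAT] = s.fat_water_epsilon * s.s_fat
        water[cls == _MUSCLE] = (1 - s.muscle_fat_fraction) * s.s_muscle
        fat[cls == _MUSCLE] = s.muscle_fat_fraction * s.s_muscle
        water[cls == _ORGAN] = (1 - s.organ_fat_fraction) * s.s_organ
        fat[cls == _ORGAN] = s.organ_fat_fraction * s.s_organ
        return water, fat

    # -- landmarks ------------------------------------------------------------
    def landmarks(self) -> dict:
        tan = math.tan(math.radians(self.tilt_deg))
        def world(x, y, z_anat):
            shear = tan * max(TILT_PIVOT - z_anat, 0.0)
            return (x + shear, y, z_anat + self.shift)
        off = self.spec.thigh_offset_x
        return {
            "epicondyle_left": world(-off, 0.0, KNEE_Z),
            "epicondyle_right": world(off, 0.0, KNEE_Z),
            "t9": world(0.0, 0.0, T9_Z),
            "femoral_head_top_z": FEMHEAD_TOP + self.shift,
            "abdomen_z": (TORSO_Z[0] + self.shift, T9_Z + self.shift + 20.0),
            "thigh_z": (THIGH_BOTTOM + self.shift, THIGH_TOP + self.shift),
            "liver_zone_z": (LIVER_Z[0] + self.shift, LIVER_Z[1] + self.shift),
        }

    # -- artifact region masks -------------------------------------------------
    def region_mask(self, kind: str, params: dict, x, y, z) -> np.ndarray:
        """Boolean mask of the region an artifact operates on."""
        f = self.fields(x, y, z)
        za = f["z_anat"]
        if kind == "swap_separate_island":
            target = params.get("target", "right_thigh")
            if target in ("left_thigh", "right_thigh"):
                side = 1 if target == "left_thigh" else 2
                return f["body"] & (f["provider"] == side) & (za < THIGH_TOP)
            if target == "abdomen":
                return f["body"] & (f["provider"] == 0) & (za >= TORSO_Z[0]) & (
                    za <= TORSO_Z[1]
                )
            raise ValidationError(f"unknown island target {target!r}")
        if kind == "swap_liver_top":
            return f["liver"]
        if kind == "swap_sat":
            cx, cy, cz = params.get("center", (0.0, -self.spec.torso_b + 15.0, 700.0))
            rad = params.get("radius", 55.0)
            xe, ye2, _ = self._anat(x, y, z)
            ball = (xe - cx) ** 2 + (np.broadcast_to(y, za.shape) - cy) ** 2 + (
                za - cz
            ) ** 2 < rad**2
            return f["sat"] & (f["provider"] == 0) & ball
        if kind == "swap_thigh":
            cx, cy, cz = params.get("center", (self.spec.thigh_offset_x, 0.0, 250.0))
            rad = params.get("radius", 50.0)
            xe, _, _ = self._anat(x, y, z)
            ball = (xe - cx) ** 2 + (np.broadcast_to(y, za.shape) - cy) ** 2 + (
                za - cz
            ) ** 2 < rad**2
            return f["body"] & ~f["sat"] & ball
        if kind == "outer_fov_inhomogeneity":
            rind = params.get("rind_mm", 30.0)
            half_z = params.get("half_height_mm", 80.0)
            z_c = params.get("z_center", 700.0)
            fx, _ = self.grid.fov_half
            side = params.get("side", 1)  # +1 right edge, -1 left edge
            X = np.broadcast_to(x, za.shape)
            near = side * X > (fx - rind)
            return f["body"] & near & (np.abs(za - z_c) < half_z)
        if kind == "metal_void":
            cx, cy, cz = params.get("center", (self.spec.thigh_offset_x, 0.0, 250.0))
            rad = params.get("radius", 30.0)
            X = np.broadcast_to(x, za.shape)
            Y = np.broadcast_to(y, za.shape)
            return (X - (cx + self.shift * 0)) ** 2 + (Y - cy) ** 2 + (
                z - (cz + self.shift)
            ) ** 2 < rad**2
        raise ValidationError(f"artifact kind {kind!r} has no region")


@dataclass
class PhantomResult:
    """Everything :func:`generate_phantom` knows about one synthetic subject."""

    slabs: list
    labels: LabelMap
    volumes: CompartmentVolumes
    bias: np.ndarray          # ground-truth bias field on the composite grid
    geometry: PhantomGeometry
    landmarks: dict

    @property
    def fat_free_volumes(self) -> CompartmentVolumes:
        """Ground truth on the scale the pipeline reports: fat compartments
        anatomical, muscle compartments fat-free (scaled by 1 - intramuscular
        fat fraction)."""
        k = 1.0 - self.geometry.spec.muscle_fat_fraction
        v = self.volumes
        return CompartmentVolumes(
            vat_l=v.vat_l, asat_l=v.asat_l,
            lat_l=k * v.lat_l, rat_l=k * v.rat_l,
            lpt_l=k * v.lpt_l, rpt_l=k * v.rpt_l,
        )


def _composite_grid(geometry: PhantomGeometry):
    slabs = geometry.grid.slab_geometry()
    z0, dz, n = composite_z_grid(
        [s["z_offset"] for s in slabs],
        [s["n_slices"] for s in slabs],
        [s["dz"] for s in slabs],
    )
    return z0, dz, n


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Render one synthetic acquisition with ground truth.

    Returns the slab list (artifacts applied), ground-truth labels and
    compartment volumes on the composite grid, the ground-truth bias
    field, and the phantom geometry (landmarks, thresholds, regions).
    Identical specs (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)

    # positioning artifacts act on the anatomy before rendering
    shift = _HEIGHT_SHIFT[spec.subject_height_class] + spec.landmark_offset_mm
    tilt = spec.tilt_deg
    signal_artifacts = []
    for art in spec.artifact_list:
        if art.kind not in ARTIFACT_KINDS:
            raise ValidationError(f"unknown artifact kind {art.kind!r}")
        if art.kind == "tall_subject":
            shift += art.params.get("shift_mm", -80.0)
        elif art.kind == "invalid_landmark":
            shift += art.params.get("shift_mm", -80.0)
        elif art.kind == "tilted_subject":
            tilt += art.params.get("tilt_deg", 10.0)
        else:
            signal_artifacts.append(art)

    geom = PhantomGeometry(spec, shift, tilt, rng)
    grid = geom.grid
    x, y = grid.in_plane_coords()
    z0, dzc, nzc = _composite_grid(geom)
    zc = z0 + np.arange(nzc) * dzc
    voxvol = grid.dxy * grid.dxy * dzc

    X = x[:, None, None]
    Y = y[None, :, None]
    Zc = zc[None, None, :]
    f = geom.fields(X, Y, Zc)
    geom.compute_thresholds(f, voxvol)

    label_arr = geom.labels_from_fields(f)
    labels = LabelMap(labels=label_arr, voxel_size=(grid.dxy, grid.dxy, dzc),
                      z_offset=z0)
    counts = {lab: int((label_arr == int(lab)).sum()) for lab in spec.targets}
    volumes = CompartmentVolumes(
        vat_l=counts[Label.VAT] * voxvol / 1e6,
        asat_l=counts[Label.ASAT] * voxvol / 1e6,
        lat_l=counts[Label.LEFT_ANTERIOR_THIGH] * voxvol / 1e6,
        rat_l=counts[Label.RIGHT_ANTERIOR_THIGH] * voxvol / 1e6,
        lpt_l=counts[Label.LEFT_POSTERIOR_THIGH] * voxvol / 1e6,
        rpt_l=counts[Label.RIGHT_POSTERIOR_THIGH] * voxvol / 1e6,
    )
    bias_composite = geom.bias(X, Y, Zc).astype(np.float32)

    slabs = []
    for sg in grid.slab_geometry():
        zs = sg["z_offset"] + np.arange(sg["n_slices"]) * sg["dz"]
        Zs = zs[None, None, :]
        fs = geom.fields(X, Y, Zs)
        cls = geom.tissue_class(fs)
        water, fat = geom.signals(cls)
        b = geom.bias(X, Y, Zs).astype(np.float32)
        water *= b
        fat *= b
        if spec.noise_sd > 0:
            gw = rng.standard_normal(water.shape).astype(np.float32)
            gf = rng.standard_normal(fat.shape).astype(np.float32)
            water = np.maximum(water * (1 + spec.noise_sd * gw), 0.0)
            fat = np.maximum(fat * (1 + spec.noise_sd * gf), 0.0)
        slabs.append(
            DixonSlab(
                water=water, fat=fat,
                voxel_size=(grid.dxy, grid.dxy, sg["dz"]),
                z_offset=sg["z_offset"], slab_index=sg["slab_index"],
                breath_hold=sg["breath_hold"],
            )
        )

    for art in signal_artifacts:
        slabs = inject_artifact(slabs, art, geometry=geom)

    return PhantomResult(
        slabs=slabs, labels=labels, volumes=volumes, bias=bias_composite,
        geometry=geom, landmarks=geom.landmarks(),
    )


def inject_artifact(slabs: list, artifact: ArtifactSpec, *, geometry: PhantomGeometry) -> list:
    """Apply one artifact to a slab list, returning a new list.

    Swap-type artifacts interchange water and fat over their region and are
    exact involutions; ``metal_void`` zeroes both channels in a ball;
    ``respiratory_ghosting`` adds a shifted, attenuated copy of a
    breath-hold slab to itself along the phase (y) axis; ``missing_slab``
    drops a slab.  Positioning kinds (tall subject, invalid landmark) are
    best expressed at generation time via :class:`PhantomSpec`; applied
    here they translate the rendered anatomy axially (landmarks in
    ``geometry`` are not updated).
    """
    kind = artifact.kind
    if kind not in ARTIFACT_KINDS:
        raise ValidationError(f"unknown artifact kind {kind!r}")
    params = artifact.params

    if kind == "missing_slab":
        index = int(params.get("index", 3))
        out = [s for s in slabs if s.slab_index != index]
        if len(out) == len(slabs):
            raise ValidationError(f"no slab with index {index} to remove")
        return out

    if kind == "respiratory_ghosting":
        amp = float(params.get("amplitude", 0.2))
        offset = float(params.get("offset_mm", 60.0))
        index = int(params.get("slab_index", 3))
        out = []
        for s in slabs:
            if s.slab_index != index:
                out.append(s)
                continue
            k = max(1, int(round(offset / s.voxel_size[1])))
            ghost_w = np.roll(s.water, k, axis=1)
            ghost_f = np.roll(s.fat, k, axis=1)
            out.append(replace(s, water=s.water + amp * ghost_w,
                               fat=s.fat + amp * ghost_f))
        return out

    if kind in ("tall_subject", "invalid_landmark"):
        shift = float(params.get("shift_mm", -80.0))
        out = []
        for s in slabs:
            k = int(round(shift / s.voxel_size[2]))
            w = np.zeros_like(s.water)
            f_ = np.zeros_like(s.fat)
            if k >= 0:
                w[:, :, k:] = s.water[:, :, : s.n_slices - k]
                f_[:, :, k:] = s.fat[:, :, : s.n_slices - k]
            else:
                w[:, :, :k] = s.water[:, :, -k:]
                f_[:, :, :k] = s.fat[:, :, -k:]
            out.append(replace(s, water=w, fat=f_))
        return out

    if kind == "tilted_subject":
        raise ValidationError(
            "tilted_subject must be injected at generation time (PhantomSpec)"
        )

    # region-based kinds
    grid = geometry.grid
    x, y = grid.in_plane_coords()
    X, Y = x[:, None, None], y[None, :, None]
    out = []
    for s in slabs:
        Z = s.z_positions[None, None, :]
        mask = geometry.region_mask(kind, params, X, Y, Z)
        if not mask.any():
            out.append(s)
            continue
        w, f_ = s.water.copy(), s.fat.copy()
        if kind == "metal_void":
            w[mask] = 0.0
            f_[mask] = 0.0
        else:  # swap kinds: exact channel interchange
            w[mask], f_[mask] = s.fat[mask], s.water[mask]
        out.append(replace(s, water=w, fat=f_))
    return out


def generate_atlas_set(
    base_spec: PhantomSpec,
    n_atlases: int,
    seed: int,
    spread: float = 1.0,
    calibrated: bool = True,
) -> list:
    """Draw atlas prototypes as randomized perturbations of ``base_spec``.

    Each prototype is an artifact-free phantom with its rendered
    ground-truth label map, merged to a composite volume and (by default)
    bias-corrected and calibrated so it can be used directly as a
    registration prior.  ``spread`` scales the perturbation amplitude;
    ``spread=0`` with ``n_atlases=1`` reproduces the base phantom exactly.
    """
    from . import preprocess  # deferred: preprocess does not import phantom

    if n_atlases < 1:
        raise ValidationError("n_atlases must be >= 1")
    rng = np.random.default_rng(seed)
    atlases = []
    for i in range(n_atlases):
        if spread == 0:
            spec = replace(base_spec, artifact_list=(), tilt_deg=0.0,
                           landmark_offset_mm=0.0)
        else:
            u = lambda lo, hi: float(rng.uniform(lo, hi))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(
                base_spec,
                torso_a=base_spec.torso_a * (1 + spread * u(-0.08, 0.08)),
                torso_b=base_spec.torso_b * (1 + spread * u(-0.08, 0.08)),
                thigh_radius=base_spec.thigh_radius * (1 + spread * u(-0.06, 0.06)),
                sat_torso_mm=base_spec.sat_torso_mm * (1 + spread * u(-0.1, 0.1)),
                vat_l=base_spec.vat_l * (1 + spread * u(-0.15, 0.15)),
                asat_l=base_spec.asat_l * (1 + spread * u(-0.15, 0.15)),
                lat_l=base_spec.lat_l * (1 + spread * u(-0.1, 0.1)),
                rat_l=base_spec.rat_l * (1 + spread * u(-0.1, 0.1)),
                lpt_l=base_spec.lpt_l * (1 + spread * u(-0.1, 0.1)),
                rpt_l=base_spec.rpt_l * (1 + spread * u(-0.1, 0.1)),
                tilt_deg=0.0,
                landmark_offset_mm=0.0,
                artifact_list=(),
                seed=sub_seed,
            )
        result = generate_phantom(spec)
        volume = preprocess.merge_slabs(result.slabs)
        if calibrated:
            volume = preprocess.calibrate_volume(volume)
        from .types import AtlasPrototype

        atlases.append(
            AtlasPrototype(
                volume=volume,
                labels=result.labels,
                sex="F" if i % 2 == 0 else "M",
                prototype_id=f"atlas{i:02d}",
            )
        )
    return atlases


# ---------------------------------------------------------------------------
# flag-level cohort fixtures


def _expand_reasons(reason_counts: dict, total: int, default: str) -> list:
    if not reason_counts:
        return [default] * total
    items = []
    for reason, count in reason_counts.items():
        items.extend([reason] * int(count))
    if len(items) != total:
        raise ValidationError(
            f"reason counts sum to {len(items)}, expected {total}"
        )
    return items


def generate_cohort_fixture(counts_config: dict, n: int, seed: int) -> list:
    """Build n raw QA records whose per-criterion totals exactly match config.

    ``counts_config`` keys (all optional):

    * ``analysable``: ``{"fat": int, "fat_one_thigh": int, "fat_both_thighs": int}``
      — nested analysability tiers (at-least-one-thigh convention).
    * ``fat_reasons`` / ``thigh_both_reasons`` / ``thigh_one_reasons``:
      reason -> count, summing to the implied number of affected subjects.
      Reasons: ``missing_slabs``, ``landmark_invalid``, ``tilted`` (one-thigh
      only), ``other:<subcode>``.
    * ``flags``: prevalence counts for reported (non-rejecting) artifact
      flags, e.g. ``{"respiratory_artifact": 134}``.

    Flag-to-record assignment is randomized under ``seed`` subject to the
    configured totals.  Records are returned with raw fields only; run
    ``qa.apply_acceptance_protocol`` to decide analysability.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    tiers = counts_config.get("analysable", {})
    n_fat = int(tiers.get("fat", n))
    n_one = int(tiers.get("fat_one_thigh", n_fat))
    n_both = int(tiers.get("fat_both_thighs", n_one))
    if not (0 <= n_both <= n_one <= n_fat <= n):
        raise ValidationError(
            "analysability tiers must satisfy both <= one <= fat <= n"
        )
    n_fat_bad = n - n_fat
    n_both_bad = n_fat - n_one     # fat-ok subjects with both thighs rejected
    n_one_bad = n_one - n_both     # fat-ok subjects with exactly one thigh rejected

    rng = np.random.default_rng(seed)
    records = [QARecord(subject_id=f"S{i:05d}") for i in range(n)]
    order = rng.permutation(n)
    fat_bad = list(order[:n_fat_bad])
    both_bad = list(order[n_fat_bad : n_fat_bad + n_both_bad])
    one_bad = list(order[n_fat_bad + n_both_bad : n_fat_bad + n_both_bad + n_one_bad])

    fat_reasons = _expand_reasons(
        counts_config.get("fat_reasons", {}), n_fat_bad, "landmark_invalid"
    )
    both_reasons = _expand_reasons(
        counts_config.get("thigh_both_reasons", {}), n_both_bad, "landmark_invalid"
    )
    one_reasons = _expand_reasons(
        counts_config.get("thigh_one_reasons", {}), n_one_bad, "tilted"
    )
    rng.shuffle(fat_reasons)
    rng.shuffle(both_reasons)
    rng.shuffle(one_reasons)

    def _apply_fat(r: QARecord, reason: str) -> QARecord:
        if reason == "missing_slabs":
            return replace(r, missing_slabs=r.missing_slabs | {3})
        if reason == "landmark_invalid":
            return replace(r, landmark_valid_abdomen=False)
        if reason.startswith("other"):
            sub = reason.split(":", 1)[1] if ":" in reason else "unspecified"
            extra = {}
            if sub == "metal":
                extra = dict(metal_contamination=True,
                             metal_regions=r.metal_regions | {"abdomen"})
            if sub == "motion":
                extra = dict(respiratory_artifact=True)
            return replace(r, other_reason_fat=sub, **extra)
        raise ValidationError(f"unknown fat rejection reason {reason!r}")

    def _apply_thigh(r: QARecord, reason: str, sides) -> QARecord:
        if reason == "missing_slabs":
            return replace(r, missing_slabs=r.missing_slabs | {6})
        if reason == "landmark_invalid":
            return replace(r, landmark_valid_thigh=False,
                           incomplete_knee_coverage=True)
        if reason == "tilted":
            return replace(r, tilted_subject=True,
                           tilt_clipped_sides=r.tilt_clipped_sides | set(sides))
        if reason.startswith("other"):
            sub = reason.split(":", 1)[1] if ":" in reason else "unspecified"
            extra = {}
            if sub == "metal":
                regions = {f"{s}_thigh" for s in sides}
                extra = dict(metal_contamination=True,
                             metal_regions=r.metal_regions | regions)
            kw = {}
            for s in sides:
                kw[f"other_reason_{s}_thigh"] = sub
            return replace(r, **kw, **extra)
        raise ValidationError(f"unknown thigh rejection reason {reason!r}")

    for idx, reason in zip(fat_bad, fat_reasons):
        records[idx] = _apply_fat(records[idx], reason)
    for idx, reason in zip(both_bad, both_reasons):
        records[idx] = _apply_thigh(records[idx], reason, ("left", "right"))
    for idx, reason in zip(one_bad, one_reasons):
        side = "left" if rng.random() < 0.5 else "right"
        records[idx] = _apply_thigh(records[idx], reason, (side,))

    # prevalence flags that report but do not reject
    for flag, count in counts_config.get("flags", {}).items():
        count = int(count)
        if count > n:
            raise ValidationError(f"flag count for {flag} exceeds cohort size")
        already = [i for i, r in enumerate(records) if getattr(r, flag)]
        if len(already) > count:
            raise ValidationError(
                f"flag {flag}: rejection reasons already imply "
                f"{len(already)} > configured {count}"
            )
        remaining = [i for i in range(n) if not getattr(records[i], flag)]
        pick = rng.choice(len(remaining), size=count - len(already), replace=False)
        for j in pick:
            records[remaining[j]] = replace(records[remaining[j]], **{flag: True})
    return records
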