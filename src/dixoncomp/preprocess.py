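"""Composite merging, adipose-referenced calibration, and swap handling.

The slabs of one acquisition are merged into a composite water/fat volume
with linear feathering over the overlaps.  Intensity inhomogeneity is then
corrected using pure adipose tissue as an internal signal reference: a
smooth positive field is fitted to the fat-channel intensities over a
pure-fat mask and both channels are divided by it, so that in the
calibrated fat channel pure adipose tissue has a value of ~1 (a
dimensionless fat content per voxel).

Water-fat swaps that affect a whole disconnected region ("separate-island
swaps", e.g. one thigh) are detected from channel-statistics plausibility
and corrected by interchanging the channels over the region; a swapped
liver-top is not channel-corrected but reported for exclusion from the
visceral fat segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import RBFInterpolator

from .errors import (
    AdiposeReferenceError,
    BiasFieldError,
    StructuralError,
    ValidationError,
)
from .phantom import composite_z_grid
from .types import DixonSlab, DixonVolume

logger = logging.getLogger(__name__)

__all__ = [
    "FatFractionImage",
    "BiasField",
    "SwapComponent",
    "merge_slabs",
    "compute_fat_fraction",
    "detect_pure_adipose",
    "estimate_bias_field",
    "calibrate",
    "calibrate_volume",
    "detect_separate_island_swaps",
    "correct_swap",
    "default_noise_floor",
    "foreground_depth",
]


@dataclass
class FatFractionImage:
    """Magnitude fat fraction ff = F / (F + W), defined above the noise floor."""

    ff: np.ndarray
    valid_mask: np.ndarray
    voxel_size: tuple[float, float, float]
    z_offset: float = 0.0


@dataclass
class BiasField:
    """Smooth, strictly positive multiplicative field on the composite grid.

    Normalized so that the field equals the fat-channel signal of pure
    adipose tissue; dividing the channels by it calibrates the volume.
    """

    field: np.ndarray
    control_scale: float
    voxel_size: tuple[float, float, float]
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        if (self.field <= 0).any():
            raise ValidationError("bias field must be strictly positive")


@dataclass
class SwapComponent:
    """A connected region flagged as water-fat swapped."""

    mask: np.ndarray
    subtype: str              # "island" or "liver_top"
    description: str = ""

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# merging


def merge_slabs(slabs: list[DixonSlab]) -> DixonVolume:
    """Merge overlapping slabs into a composite volume.

    Overlaps are blended with linear feathering: each slab's weight ramps
    down towards its own edges, and weights are normalized per slice, so
    constant images merge to the same constant.  Slabs are resampled to
    the common z-grid (the finest slab spacing) by taking each slab's
    nearest native slice.  Interior coverage gaps (e.g. a missing slab) are recorded,
    never interpolated across.
    """
    if not slabs:
        raise ValidationError("merge requires at least one slab")
    shape0 = slabs[0].shape[:2]
    inplane0 = slabs[0].voxel_size[:2]
    for s in slabs:
        if s.shape[:2] != shape0:
            raise StructuralError(
                f"in-plane grid mismatch: {s.shape[:2]} vs {shape0}"
            )
        if any(abs(a - b) > 1e-6 for a, b in zip(s.voxel_size[:2], inplane0)):
            raise StructuralError("in-plane voxel size mismatch between slabs")
    indices = [s.slab_index for s in slabs]
    if len(set(indices)) != len(indices):
        raise ValidationError("duplicate slab indices")

    z0, dz, nz = composite_z_grid(
        [s.z_offset for s in slabs],
        [s.n_slices for s in slabs],
        [s.voxel_size[2] for s in slabs],
    )
    zc = z0 + np.arange(nz) * dz

    nx, ny = shape0
    acc_w = np.zeros((nx, ny, nz), dtype=np.float64)
    acc_f = np.zeros((nx, ny, nz), dtype=np.float64)
    weight = np.zeros(nz, dtype=np.float64)
    contributors: list[set] = [set() for _ in range(nz)]

    for s in slabs:
        dzi = s.voxel_size[2]
        lo, hi = s.z_extent
        inside = (zc >= lo) & (zc <= hi)
        if not inside.any():
            continue
        idx = np.nonzero(inside)[0]
        # nearest native slice: slabs are the acquired data, so no
        # intermediate slices are invented (keeps tissue interfaces crisp)
        f0 = np.clip(np.round((zc[idx] - s.z_offset) / dzi).astype(int),
                     0, s.n_slices - 1)
        # feather: distance (mm) to the nearer slab edge
        w = np.minimum(zc[idx] - lo, hi - zc[idx]) + dzi / 2
        interp_w = s.water[:, :, f0]
        interp_f = s.fat[:, :, f0]
        acc_w[:, :, idx] += interp_w * w
        acc_f[:, :, idx] += interp_f * w
        weight[idx] += w
        for k in idx:
            contributors[k].add(s.slab_index)

    covered = weight > 0
    out_w = np.zeros((nx, ny, nz), dtype=np.float32)
    out_f = np.zeros((nx, ny, nz), dtype=np.float32)
    out_w[:, :, covered] = (acc_w[:, :, covered] / weight[covered]).astype(np.float32)
    out_f[:, :, covered] = (acc_f[:, :, covered] / weight[covered]).astype(np.float32)

    gaps = [int(k) for k in np.nonzero(~covered)[0]]
    if gaps:
        logger.warning("composite has %d uncovered slices (coverage gap)", len(gaps))
    provenance = [tuple(sorted(c)) for c in contributors]
    return DixonVolume(
        water=out_w, fat=out_f,
        voxel_size=(inplane0[0], inplane0[1], dz),
        z_offset=z0, provenance=provenance, coverage_gaps=gaps,
    )


# ---------------------------------------------------------------------------
# fat fraction and calibration


def default_noise_floor(volume: DixonVolume) -> float:
    """Heuristic noise floor: 5% of the 99th percentile of total signal."""
    total = volume.total()
    ref = np.percentile(total[total > 0], 99) if (total > 0).any() else 0.0
    return 0.05 * float(ref)


def compute_fat_fraction(volume: DixonVolume, noise_floor: float | None = None) -> FatFractionImage:
    """ff = fat / (fat + water) where total signal exceeds the noise floor."""
    if noise_floor is None:
        noise_floor = default_noise_floor(volume)
    if noise_floor < 0:
        raise ValidationError("noise_floor must be non-negative")
    total = volume.total()
    valid = total > noise_floor
    ff = np.zeros_like(total, dtype=np.float32)
    np.divide(volume.fat, total, out=ff, where=valid)
    return FatFractionImage(
        ff=ff, valid_mask=valid, voxel_size=volume.voxel_size,
        z_offset=volume.z_offset,
    )


def detect_pure_adipose(
    ff: FatFractionImage,
    volume: DixonVolume,
    threshold: float = 0.9,
    erode_voxels: int | None = None,
    erode_mm: float = 2.5,
    min_component_voxels: int = 50,
) -> np.ndarray:
    """Mask of pure adipose tissue usable as the internal signal reference.

    Voxels with ff >= threshold, eroded by one voxel per ``erode_mm`` of
    in-plane resolution to shave partial-volume rims (at coarse desk-scale
    grids a one-voxel erosion would swallow thin subcutaneous rinds and
    leave whole limbs without reference, so no erosion is applied there),
    restricted to connected components above a minimum size.
    """
    if erode_voxels is None:
        erode_voxels = int(erode_mm // min(volume.voxel_size[:2]))
    mask = ff.valid_mask & (ff.ff >= threshold)
    if erode_voxels > 0 and mask.any():
        padded = np.pad(mask, ((0, 0), (0, 0), (erode_voxels, erode_voxels)),
                        mode="edge")
        padded = ndimage.binary_erosion(padded, iterations=erode_voxels)
        mask = padded[:, :, erode_voxels:-erode_voxels]
    if mask.any() and min_component_voxels > 1:
        lab, n = ndimage.label(mask)
        sizes = np.bincount(lab.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes[1:] >= min_component_voxels
        mask = keep[lab]
    if not mask.any():
        raise AdiposeReferenceError(
            "no adipose reference found; calibration cannot proceed"
        )
    return mask


def estimate_bias_field(
    volume: DixonVolume,
    pure_fat_mask: np.ndarray,
    control_scale: float = 60.0,
    min_cells: int = 4,
    smoothing: float = 1e-3,
) -> BiasField:
    """Fit a smooth positive field to fat intensities over the adipose mask.

    The mask is binned into cubic control cells of ``control_scale`` mm;
    the per-cell median fat intensity (a robust average) is interpolated
    with a thin-plate spline in the log domain and evaluated on the whole
    grid.  The result approximates the fat-channel signal of pure adipose
    tissue everywhere, i.e. (pure-fat signal) x (multiplicative bias).
    """
    if not pure_fat_mask.any():
        raise AdiposeReferenceError("empty adipose mask")
    dx, dy, dz = volume.voxel_size
    ix, iy, iz = np.nonzero(pure_fat_mask)
    nxv, nyv, nzv = volume.shape
    # world coordinates (in-plane centred, z from the inferior edge)
    px = (ix - (nxv - 1) / 2) * dx
    py = (iy - (nyv - 1) / 2) * dy
    pz = volume.z_offset + iz * dz
    vals = volume.fat[ix, iy, iz].astype(np.float64)
    if (vals <= 0).any():
        # guard against exact zeros from noise clipping inside the mask
        vals = np.maximum(vals, np.percentile(vals[vals > 0], 1))

    cells = np.stack(
        [np.floor(px / control_scale), np.floor(py / control_scale),
         np.floor(pz / control_scale)], axis=1
    ).astype(np.int64)
    _, inverse = np.unique(cells, axis=0, return_inverse=True)
    n_cells = inverse.max() + 1
    if n_cells < min_cells:
        raise BiasFieldError(
            f"adipose mask spans only {n_cells} control cells "
            f"(< {min_cells}); field is unconstrained at {control_scale} mm"
        )
    centers = np.zeros((n_cells, 3))
    medians = np.zeros(n_cells)
    logv = np.log(vals)
    pts = np.stack([px, py, pz], axis=1)
    for c in range(n_cells):
        sel = inverse == c
        centers[c] = pts[sel].mean(axis=0)
        medians[c] = np.median(logv[sel])

    rbf = RBFInterpolator(
        centers, medians, kernel="thin_plate_spline",
        smoothing=smoothing * n_cells,
    )
    gx = (np.arange(nxv) - (nxv - 1) / 2) * dx
    gy = (np.arange(nyv) - (nyv - 1) / 2) * dy
    gz = volume.z_offset + np.arange(nzv) * dz
    field = np.empty(volume.shape, dtype=np.float32)
    # evaluate slab-wise to bound memory
    XY = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
    for k in range(nzv):
        q = np.column_stack([XY, np.full(len(XY), gz[k])])
        field[:, :, k] = np.exp(rbf(q)).reshape(nxv, nyv)
    return BiasField(
        field=field, control_scale=control_scale,
        voxel_size=volume.voxel_size, z_offset=volume.z_offset,
    )


def calibrate(volume: DixonVolume, bias: BiasField) -> DixonVolume:
    """Divide both channels by the bias field.

    In the calibrated fat channel pure adipose tissue is ~1.0, a
    dimensionless fat content per voxel; integrating it over a label
    yields a partial-volume-aware fat volume.
    """
    if bias.field.shape != volume.shape:
        raise StructuralError("bias field grid does not match volume")
    if (bias.field <= 0).any():
        raise ValidationError("bias field must be strictly positive")
    return replace(
        volume,
        water=(volume.water / bias.field).astype(np.float32),
        fat=(volume.fat / bias.field).astype(np.float32),
        provenance=list(volume.provenance),
        coverage_gaps=list(volume.coverage_gaps),
    )


def calibrate_volume(
    volume: DixonVolume,
    noise_floor: float | None = None,
    pure_fat_threshold: float = 0.9,
    control_scale: float = 60.0,
    min_component_voxels: int = 50,
) -> DixonVolume:
    """Convenience: fat fraction -> adipose reference -> bias fit -> calibrate."""
    ff = compute_fat_fraction(volume, noise_floor)
    mask = detect_pure_adipose(
        ff, volume, threshold=pure_fat_threshold,
        min_component_voxels=min_component_voxels,
    )
    bias = estimate_bias_field(volume, mask, control_scale=control_scale)
    return calibrate(volume, bias)


# ---------------------------------------------------------------------------
# swap detection / correction


def foreground_depth(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Distance (mm) to the outer body surface.

    Depth is measured to the air surrounding the body (background
    connected to the transverse image border), not to interior air spaces
    (airways, signal voids): those are anatomically inside the body.
    Axial grid-cut faces are edge-padded so they do not count as surface.
    """
    pad = 4
    padded = np.pad(mask, ((0, 0), (0, 0), (pad, pad)), mode="edge")
    background = ~padded
    lab, n = ndimage.label(background)
    border = np.zeros(n + 1, dtype=bool)
    for face in (lab[0], lab[-1], lab[:, 0], lab[:, -1]):
        border[np.unique(face)] = True
    border[0] = False
    outer_air = border[lab]
    depth = ndimage.distance_transform_edt(~outer_air, sampling=voxel_size)
    return depth[:, :, pad:-pad]


def _slice_component_count(fg: np.ndarray, min_area_voxels: int) -> np.ndarray:
    """Number of sufficiently large in-plane components per axial slice."""
    counts = np.zeros(fg.shape[2], dtype=int)
    for k in range(fg.shape[2]):
        lab, n = ndimage.label(fg[:, :, k])
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        counts[k] = int((sizes >= min_area_voxels).sum())
    return counts


def _zone_masks(volume: DixonVolume, fg: np.ndarray):
    """Split slices into thigh zone (two body components) and torso zone."""
    dx, dy, _ = volume.voxel_size
    min_area = max(8, int(20e2 / (dx * dy)))  # 20 cm^2
    counts = _slice_component_count(fg, min_area)
    thigh_slices = counts >= 2
    torso_slices = counts == 1
    return thigh_slices, torso_slices


def _abdominal_run(interior: np.ndarray, torso_slices: np.ndarray,
                   voxel_size, enclosed_air: np.ndarray | None = None) -> np.ndarray:
    """Boolean z-mask of the abdominal interior: the contiguous run of
    torso slices with a large deep cross-section containing its maximum.

    Slices with substantial enclosed air (the lungs) cap the run from
    above, so the chest does not count as abdomen."""
    dx, dy, _ = voxel_size
    area = interior.sum(axis=(0, 1)) * dx * dy / 100.0  # cm^2
    area[~torso_slices] = 0.0
    big = area >= 150.0
    if enclosed_air is not None:
        air_area = enclosed_air.sum(axis=(0, 1)) * dx * dy / 100.0
        big &= air_area < 50.0
    if not big.any():
        return np.zeros_like(big)
    k0 = int(np.argmax(area))
    run = np.zeros_like(big)
    k = k0
    while k >= 0 and big[k]:
        run[k] = True
        k -= 1
    k = k0 + 1
    while k < len(big) and big[k]:
        run[k] = True
        k += 1
    return run


def detect_separate_island_swaps(
    volume: DixonVolume,
    noise_floor: float | None = None,
    deep_mm: float = 35.0,
    liver_core_mm: float = 55.0,
    water_plausibility: float = 0.2,
    liver_cap_mm: float = 60.0,
    min_liver_ml: float = 80.0,
) -> list[SwapComponent]:
    """Flag connected regions whose channel statistics are implausible.

    A limb or the abdomen always contains substantial water-dominant
    muscle/organ tissue in its interior; a region whose interior is almost
    entirely fat-dominant (interior water-dominant fraction below the
    plausibility threshold) has its channels swapped.  A fat-dominant
    component capping the abdominal interior superiorly is reported with
    the distinct ``liver_top`` subtype (it is excluded from the visceral
    fat segmentation rather than channel-corrected).
    """
    if noise_floor is None:
        noise_floor = default_noise_floor(volume)
    fg = volume.total() > noise_floor
    if not fg.any():
        return []
    depth = foreground_depth(fg, volume.voxel_size)
    deep = fg & (depth > deep_mm)
    fat_dom = volume.fat > volume.water
    thigh_slices, torso_slices = _zone_masks(volume, fg)
    voxvol_ml = volume.voxel_volume_mm3 / 1000.0

    nx = volume.shape[0]
    xsign = np.arange(nx) < nx / 2  # left half of the image (x < 0)
    components: list[SwapComponent] = []

    # thigh islands: one whole thigh assigned to the wrong channel
    for left, name in ((True, "left_thigh"), (False, "right_thigh")):
        side = xsign if left else ~xsign
        zone = deep & side[:, None, None] & thigh_slices[None, None, :]
        n = int(zone.sum())
        if n < 20:
            continue
        water_frac = 1.0 - float(fat_dom[zone].mean())
        if water_frac < water_plausibility:
            mask = fg & side[:, None, None] & thigh_slices[None, None, :]
            components.append(
                SwapComponent(mask=mask, subtype="island",
                              description=f"{name} island swap "
                                          f"(interior water fraction {water_frac:.2f})")
            )

    interior = deep & torso_slices[None, None, :]
    # in-plane enclosed air (lungs/airways vent axially, so fill per slice)
    enclosed_air = np.zeros_like(fg)
    for k in range(fg.shape[2]):
        enclosed_air[:, :, k] = ndimage.binary_fill_holes(fg[:, :, k]) & ~fg[:, :, k]
    run = _abdominal_run(interior, torso_slices, volume.voxel_size, enclosed_air)
    if run.any():
        abd = interior & run[None, None, :]
        n_abd = int(abd.sum())
        water_frac = 1.0 - float(fat_dom[abd].mean()) if n_abd else 1.0
        if n_abd and water_frac < 0.5:
            # whole-abdomen island swap (interior mostly fat-dominant)
            mask = fg & run[None, None, :] & torso_slices[None, None, :]
            components.append(
                SwapComponent(mask=mask, subtype="island",
                              description=f"abdominal island swap "
                                          f"(interior water fraction {water_frac:.2f})")
            )
        elif not volume.coverage_gaps:
            # liver-top: fat-dominant cap at the top of the abdominal
            # interior; not assessed across coverage gaps (a truncated
            # abdomen puts ordinary visceral fat at the apparent top, and
            # missing slabs already reject the subject)
            zrun = np.nonzero(run)[0]
            z_top = volume.z_offset + zrun[-1] * volume.voxel_size[2]
            cap = abd & (
                volume.z_positions[None, None, :] > z_top - liver_cap_mm
            )
            blobs, nb = ndimage.label(fat_dom & cap)
            for b in range(1, nb + 1):
                bm = blobs == b
                # a swapped liver-top is a massive interior cap; thick
                # subcutaneous flanks graze the depth cut but have no core
                if (bm.sum() * voxvol_ml >= min_liver_ml
                        and depth[bm].max() >= liver_core_mm):
                    components.append(
                        SwapComponent(
                            mask=bm, subtype="liver_top",
                            description="fat-dominant cap over abdominal interior",
                        )
                    )
    return components


def correct_swap(volume: DixonVolume, component: SwapComponent):
    """Interchange water and fat over a flagged component.

    Returns ``(volume, exclusion_mask)``.  Island swaps are corrected by
    exchanging the channels on the component (an exact involution); the
    liver-top subtype is left unchanged and returned as an exclusion
    region for the visceral fat quantification.
    """
    if component.mask.shape != volume.shape:
        raise StructuralError("swap component grid does not match volume")
    if component.subtype == "liver_top":
        return volume, component.mask
    if not component.mask.any():
        logger.warning("swap component empty; no-op")
        return volume, None
    w = volume.water.copy()
    f = volume.fat.copy()
    w[component.mask], f[component.mask] = (
        volume.fat[component.mask],
        volume.water[component.mask],
    )
    return replace(volume, water=w, fat=f,
                   provenance=list(volume.provenance),
                   coverage_gaps=list(volume.coverage_gaps)), None
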