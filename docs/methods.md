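# Methods

This note documents the models and numerical choices behind the
package: what the synthetic phantoms emulate, how each pipeline stage is
defined, which parameters matter, and what the validation studies do and
do not demonstrate.

## Phantom model

The phantom renders a parametric body into the six-slab axial
acquisition geometry (slice counts 64/44/44/44/72/64, slice spacings
3/4.5/4.5/4.5/3.5/4 mm, in-plane 2.23 mm on a 224×174 matrix, ~1.1 m
total coverage, adjacent slabs overlapping by 8 slices of the lower
slab — the overlap is not published for this protocol and is a
configurable choice).

**Geometry.** Stacked superellipse cross-sections: a torso (half-axes
230×135 mm, exponent 2.5) tapering through shoulders into a neck; two
circular thigh cylinders (radius 100 mm, centres ±115 mm). Tissue
shells: subcutaneous fat rind (28 mm torso, 20 mm thigh, plus fat pads
on the exposed axial surfaces at groin and knee level — real bodies
carry fat there, and without the pads bare muscle would sit on the body
surface and mimic a swap), an abdominal muscle wall (15 mm), a visceral
cavity with water-dominant organs, a liver-like organ capping the
cavity, and air-filled lungs vented through a trachea (so that interior
air is anatomically "inside" and enclosed-void detection has a
principled enclosure test). Anatomical realism is explicitly not the
goal; the contract is volumetric ground truth.

**Exact-volume rendering.** Each target compartment (VAT, ASAT, four
thigh muscle groups) is the sublevel set of a continuous placement key
(an anisotropic distance for VAT, axial-centrality for ASAT, radial
distance with an anterior/posterior split plane at y = +20 mm for the
thigh muscles, each with a tiny deterministic symmetry-breaking term so
keys are unique). The threshold is the N-th smallest key value over the
composite grid with N = round(target / voxel volume), so the rendered
volume matches the target to within half a voxel. Because the key is a
continuous function of position, the same compartment is rendered
consistently on the slab grids and the composite grid.

**Signal model.** Piecewise-constant class means (fat 600 au with 2%
residual water; muscle 500 au at 10% fat fraction; organs 550 au at 5%;
air 0), multiplied by a smooth bias field 1 + A·mean of three seeded
plane-wave cosines (default amplitude A = 0.2, length scale 150 mm), and
multiplicative Gaussian noise (default SD 2.5% of the voxel's signal —
an SNR ~40 typical of magnitude gradient-echo data; multiplicative so
air stays exactly zero, and Rician statistics are deliberately not
modelled). Artifact injection covers every QA category; all swap-type
artifacts are exact channel interchanges and therefore involutions.

**Desk scale.** `PhantomSpec.scale` coarsens the axial sampling and
`scale_xy` the in-plane matrix (defaulting to `scale`); the native
protocol is itself anisotropic. Study sizes used by the test-suite and
the acceptance script, chosen as the package's own working points:
geometry and I/O tests at scale 2–4; the calibration suite at scale 3
(the subcutaneous rind must remain a few voxels thick); the detector
suite at scale 4; registration-heavy studies at axial scale 4–5 with
in-plane scale 5. Full-resolution grids remain available.

## Preprocessing

**Merging.** The composite grid uses the finest slab spacing; each slab
contributes its nearest native slice (slabs are the acquired data, so no
intermediate slices are invented and tissue interfaces stay crisp) with
a linear feathering weight that ramps down towards the slab edges;
weights are normalized, so constant images merge exactly. Coverage gaps
(missing slabs) are recorded and propagated to QA, never interpolated.

**Calibration.** Fat fraction ff = F/(F+W) on magnitude signals (no
formula is standard-free here; this is ordinary two-point Dixon
practice), defined where total signal exceeds a noise floor (default:
5% of the 99th percentile of total signal). The pure-adipose reference
is ff ≥ 0.9, eroded by one voxel per 2.5 mm of in-plane resolution (no
erosion at coarse desk scales, where it would swallow thin rinds and
leave the thighs unconstrained), components ≥ 50 voxels. The bias field
is fitted by binning the mask into 60 mm control cells, taking per-cell
medians of the fat signal, and interpolating a thin-plate spline in the
log domain (positivity by construction, linear extrapolation). This is
the package's own formulation of "smooth positive fit to the adipose
reference"; its contract is the recovery property (median relative error
< 3% against the known ground-truth field), not any particular
published algorithm. Calibration divides both channels by the field and
is scale-invariant by construction.

**Swap handling.** Body foreground is split into thigh-zone slices (two
large in-plane components) and torso slices. A thigh whose deep interior
(depth > 35 mm from the *outer* body surface; interior air does not
count as surface) is mostly fat-dominant is an island swap; the
abdominal interior is flagged likewise when its water-dominant fraction
drops below 0.5 (clean abdomens carry VAT, so the plausibility bar is
laxer than the limb default of 0.2). A fat-dominant blob capping the
abdominal interior from above (the run of large-interior slices bounded
by the lungs), reaching depth ≥ 55 mm and ≥ 80 ml, is reported as the
liver-top subtype — excluded from the VAT integral rather than
corrected. Island corrections interchange the channels on the component
and are exact involutions. Liver-top detection is skipped when coverage
gaps truncate the abdomen (ordinary visceral fat would sit at the
apparent top, and missing slabs already reject the subject).

## Segmentation

**Registration.** SimpleITK, deterministic (full-sampling metric, no
stochastic sampling): a centred affine initialization refined by
regular-step gradient descent on a correlation metric (one pyramid
level, shrink 4), then a B-spline stage (control spacing 160 mm, LBFGSB,
at shrink 3 — on these smooth composites the metric gains nothing at
full resolution and the full-grid stage would dominate runtime). The
feature image is the signed contrast fat − water: both channels enter
jointly, and unlike their sum (nearly flat across tissues) the
difference has strong gradients at every fat/lean interface — exactly
the boundaries the compartments follow. The registration internals are
not a reproduction of any published engine; conformance is defined by
behavioural properties (sub-voxel self-registration, recovery of known
translations within 1 mm, Dice > 0.9 per compartment under a known
smooth deformation).

**Fusion.** Per-voxel vote counting over the warped atlas labels; a
voxel is assigned the winning label only when its count strictly exceeds
the vote threshold (default 5, i.e. "more than five atlases agree"),
ties broken to the lowest label code with a warning. The threshold is
absolute, not a fraction of the atlas count — with a full prototype
library (up to 31) it acts as a ~20% quorum rather than a majority.
Small atlas sets should scale it down (the config exposes it); with 15
atlases the default corresponds to a 40% quorum, which the recovery
study shows is well calibrated, while a strict majority of a small set
systematically under-segments thin structures.

**Quantification.** VAT/ASAT: sum of calibrated fat over the fused label
(minus any liver-top exclusion) × voxel volume. Thigh muscles: fat-free
volume, ∑(1 − ff)·voxel volume over the label; a binary variant
(count voxels with ff < 0.5) is available behind a flag. Compartment
definitions (the VAT cavity, the ASAT axial bounds between femoral head
and T9, the four thigh groups) are encoded in the atlas label maps, not
re-derived at segmentation time.

## QA and acceptance

Detectors are automated counterparts of a visual QA checklist:

* *Missing slabs*: protocol indices absent from the acquisition, mapped
  to regions (slabs 2–4 abdomen, 4–6 thigh, 1 neck).
* *Coverage*: femoral epicondyles and T9 landmark positions against the
  grid (phantom-provided here; atlas-propagated in production — "unknown"
  fails closed). Tilt is estimated from per-slice centroids of lower-body
  components that do not touch the x boundary (a clipped thigh's
  centroid saturates at the FOV edge and would mask the tilt); the flag
  requires both a tilt above threshold (default 5°) and a thigh touching
  the transverse boundary.
* *Metal*: low-signal regions fully enclosed by tissue in 3D (≥ 5 ml).
  Lungs escape via the trachea and are not enclosed; background air is
  never flagged.
* *Respiratory ghosting*: worst-slice fraction of phase-axis projected
  signal outside the body's dilated support over the breath-hold slabs;
  exactly zero on ghost-free data, threshold 1%.
* *Swap scans*: water-dominant blobs in the subcutaneous shell
  (depth ≤ 12 mm) are swaps; within 30 mm of the transverse FOV edge
  they are outer-FOV inhomogeneities ("dog-bites"), otherwise SAT swaps.
  Fat-dominant blobs deep in a thigh that fall short of a whole-limb
  island are thigh swaps.

The acceptance protocol is a pure function of the raw flags: fat is
rejected only for missing abdominal slabs, an invalid abdominal landmark
(T9 absent / abdomen out of FOV) or an abdominal blocker (metal void,
recorded "other" such as severe motion); each thigh analogously, with
tilt rejecting only the clipped side. Respiratory artifacts, corrected
island swaps, liver-top swaps and outer-FOV inhomogeneities are reported
but do not reject — in the cohorts this protocol mirrors, those scans
remained analysable. Cohort aggregation reports counts with percentages
rounded half-up to two decimals, nested tiers (fat; fat + at least one
thigh; fat + both thighs), and primary rejection reasons with precedence
missing slabs > landmark invalid > tilt > other. Descriptive statistics
use sample SD (zero for a single record) and list-wise exclusion.

## What the validation shows — and what it does not

The phantoms share the pipeline's geometric vocabulary (superellipse
bodies, crisp class interfaces, spatially smooth bias, no motion between
slabs, no chemical-shift or relaxation effects). Passing the studies
demonstrates the *machinery* is correct and internally calibrated:
merging preserves signal, calibration recovers a known field to < 3%
median error, fusion is exactly the strict-threshold tally, detectors
separate every injected artifact class from clean data, and the full
chain recovers known compartment volumes to a few percent (median
< 5% per compartment over ten subjects with realistic anatomical
spread: VAT ±30%, ASAT ±20%, muscles ±15%, body size ±5%). It does not
demonstrate performance on real anatomy, real swap topologies, or real
motion; the published cohort's volume statistics require the original
images and are out of reach by construction — the cohort-aggregation
study instead verifies the reporting arithmetic on flag-level fixtures
that match the published counts.

Two published inconsistencies surfaced while building those fixtures:
the second sub-cohort's per-side thigh counts cannot be reconciled with
the combined analysability tiers, and the rejection-reason shares imply
47 affected subjects where the tier arithmetic of the first sub-cohort
gives 19. The fixtures follow the tier numbers (which the abstract
quotes) and treat reason shares as shares over subjects with any
rejection.

## Known limitations

* Detectors are tuned to the phantom's contrast regime; thresholds are
  config-exposed but have not seen scanner data.
* The liver-top/abdomen heuristics assume a lung signal gap above the
  abdominal cavity.
* SAT swaps smaller than the shell-scan blob minimum (15 ml) go
  undetected; only detection, not correction, is implemented for
  non-island SAT swaps.
* At coarse desk scales, slab-to-composite resampling introduces a
  partial-volume bias of 1–3% in compartment integrals; study scales
  were chosen so the validated tolerances hold with margin, and the
  effect shrinks with voxel size.
* The interactive manual-adjustment step used by production analysts is
  replaced by automated QA gates; atypical anatomies beyond the atlas
  span are not specially handled.
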