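# dixoncomp

Automated body-composition analysis for large-cohort neck-to-knee Dixon
MRI, with a synthetic phantom generator, a technical quality-assurance
(QA) suite, and a reduced data-acceptance protocol.

Population imaging studies acquire water-fat separated (Dixon) MRI from
tens of thousands of participants. At that scale nobody can segment
visceral adipose tissue (VAT), abdominal subcutaneous adipose tissue
(ASAT) and thigh muscles by hand, and nobody can visually audit every
scan. This package implements the automated pipeline such studies rely
on, end to end, and exercises it entirely on synthetic phantoms with
exact volumetric ground truth — so every stage can be validated
quantitatively without patient data.

## The method

**Acquisition model.** Six overlapping axial slabs cover neck to knees
(~1.1 m): 64 slices at 3 mm over the neck, three 44-slice 4.5 mm
breath-hold slabs over the abdomen, 72 slices at 3.5 mm and 64 slices at
4 mm over the thighs; in-plane 2.23 mm. The phantom module renders
synthetic subjects into exactly this geometry (optionally coarsened by a
desk-scale factor) with known compartment volumes, a smooth
multiplicative bias field b(x), multiplicative noise, and injectable
artifacts for every QA category.

**Pipeline.** For each subject:

1. *Merge*: slabs are blended into a composite volume with linear
   feathering over the overlaps; coverage gaps are recorded, never
   interpolated.
2. *Calibrate*: pure adipose tissue is an internal signal reference.
   With magnitude fat fraction ff = F/(F+W), voxels with ff ≥ 0.9 form
   the reference mask; a smooth positive field fitted to the fat signal
   over that mask estimates s_fat·b(x), and dividing both channels by it
   makes pure fat ≈ 1.0 — a dimensionless fat content per voxel.
3. *Swap handling*: a connected region whose interior is almost entirely
   fat-dominant (a "limb made of fat") is a separate-island water-fat
   swap and is corrected by interchanging the channels; a fat-dominant
   cap over the abdominal interior is a swapped liver-top, which is not
   corrected but excluded from the VAT integral.
4. *Segment*: up to 31 atlas prototypes with ground-truth labels are
   non-rigidly registered to the target (affine + B-spline on the
   fat−water contrast image); each warped atlas votes per voxel, and a
   voxel is labelled only if **more than five** atlases agree (strict
   majority quorum, config-exposed).
5. *Quantify*: VAT and ASAT in litres by integrating the calibrated fat
   image over the fused labels, ∑ F̂(x)·v; thigh muscles as fat-free
   volume, ∑ (1 − ff(x))·v over each of the four muscle labels.
6. *QA and acceptance*: detectors flag respiratory ghosting, metal
   voids, water-fat swaps (SAT / liver-top / thigh / island), outer-FOV
   "dog-bite" inhomogeneities, missing slabs, incomplete knee coverage,
   invalid landmarks and tilt. The reduced acceptance protocol decides
   per-compartment analysability (fat, left thigh, right thigh); only
   hard coverage failures reject, reported artifacts alone do not.
7. *Report*: cohort summaries with counts and two-decimal percentages,
   nested analysability tiers, rejection-reason shares, and descriptive
   statistics with list-wise exclusion.

## Worked example

`examples/` holds one short script per capability. For instance:

```bash
$ python examples/04_qa_and_cohort_report.py
first 1,000: n=1000
  analysable fat              997   99.70%
  analysable fat + 1 thigh    986   98.60%
  analysable fat + 2 thighs   981   98.10%
next 2,000: n=2000
  analysable fat             1998   99.90%
  ...
combined 3,000: n=3000
  analysable fat             2995   99.83%
  analysable fat + 1 thigh   2828   94.27%
  analysable fat + 2 thighs  2775   92.50%
...
rejected subjects: 47; primary reasons:
  missing_slabs        6   12.77%
  landmark_invalid    39   82.98%
```

The tiers are nested: a subject analysable for fat and both thighs is
also analysable for fat and at least one thigh. `examples/03_...` runs
the multi-atlas segmentation on one phantom and prints the recovered
compartment volumes next to the known ground truth (errors of a few
percent at desk scale).

A `dixoncomp` command-line tool wraps the same library:
`dixoncomp phantom|preprocess|qa|segment|cohort-report|run`, all taking
`--config cfg.yaml` and `--seed`.

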