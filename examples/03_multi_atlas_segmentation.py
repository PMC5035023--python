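"""Segment one subject with the multi-atlas voting pipeline.

Registers a set of atlas prototypes to a calibrated target, fuses the
warped labels with the strict "more than N atlases agree" rule, and
quantifies all six compartments against the known ground truth.
Runs in about a minute on one CPU at a coarse desk scale.
"""

from dixoncomp import PhantomSpec, generate_atlas_set, generate_phantom
from dixoncomp import preprocess as pp
from dixoncomp import segmentation as seg

spec = PhantomSpec(scale=4, scale_xy=5, seed=3)
result = generate_phantom(spec)
target = pp.calibrate_volume(pp.merge_slabs(result.slabs))

atlases = generate_atlas_set(spec, n_atlases=8, seed=99)
fused, volumes, votes = seg.segment_subject(target, atlases,
                                            vote_threshold=3)

truth = result.fat_free_volumes.as_dict()
print(f"{len(atlases)} atlases, vote threshold 3 (a voxel needs >3 votes)")
print("compartment        truth [L]  estimate [L]  error")
for key, est in volumes.as_dict().items():
    t = truth[key]
    err = f"{100*(est-t)/t:+5.1f}%" if t else "   -"
    print(f"  {key:18s} {t:7.2f}   {est:8.2f}    {err}")
print("\nFat compartments integrate the calibrated fat image over the")
print("fused labels; thigh muscles are fat-free volumes (each voxel")
print("weighted by 1 - fat fraction), hence ~10% below the anatomical")
print("label volume at 10% intramuscular fat.")
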