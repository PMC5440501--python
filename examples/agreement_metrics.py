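"""The agreement metrics on hand-checkable masks.

Two small masks with |S1| = 8, |S2| = 12 and 6 shared voxels give
Dice = 2*6/(8+12) = 0.6 exactly; a 10-vs-10 pair overlapping on 8 voxels has
FNR = FDR = 0.2. The cohort-level Pearson r of lesion volumes is 1 for a
perfectly proportional rater.
"""

import numpy as np

from cascade_wmh import VoxelMask, cohort_volume_correlation, compare_masks

aff = np.eye(4)

s1 = np.zeros((4, 4, 4), bool); s1.ravel()[0:8] = True
s2 = np.zeros((4, 4, 4), bool); s2.ravel()[2:14] = True
report = compare_masks(VoxelMask(affine=aff, data=s1), VoxelMask(affine=aff, data=s2))
print(f"Dice(|S1|=8, |S2|=12, overlap 6) = {report.dice:.3f}")

r = np.zeros((4, 4, 4), bool); r.ravel()[0:10] = True
t = np.zeros((4, 4, 4), bool); t.ravel()[2:12] = True
rep = compare_masks(VoxelMask(affine=aff, data=r), VoxelMask(affine=aff, data=t))
print(f"FNR = {rep.fnr:.3f}, FDR = {rep.fdr:.3f}  (10 vs 10 voxels, 8 shared)")

volumes = [(1.2, 2.4), (5.0, 10.1), (9.7, 19.2), (20.5, 41.3)]
print(f"Pearson r of cohort volumes  = {cohort_volume_correlation(volumes):.4f}")
print()
print("Dice rewards overlap symmetrically; FNR counts missed reference")
print("voxels, FDR counts spurious predicted ones; volume correlation asks")
print("only whether subjects are ranked consistently, not matched exactly.")
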