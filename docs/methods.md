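# Methods

## The statistical lesion definition

A voxel is declared WMH when its local intensity distribution is
significantly displaced, in the lesion direction, from the subject's own
normal-tissue distribution. Concretely, for each provided sequence:

1. Intensities are normalized to [0, 1] by mapping the 1st/99th in-brain
   percentiles to 0/1 (robust to outliers; no scanner scale assumed).
2. `F1` at a voxel is the cumulative histogram (64 equal-width bins over
   [0, 1]) of the intensities inside a 3 mm Euclidean ball around it.
3. `F2` is the binwise mean of `F1` over a seeded sample of evidently-normal
   voxels of the same subject, sequence and tissue class.
4. The one-tailed Kolmogorov–Smirnov statistics are
   `D+ = max_i (F1 − F2)` and `D− = max_i (F2 − F1)`, floored at 0. The
   lesion tail is `D−` for T2/FLAIR/PD (a hyperintense region right-shifts
   the local histogram, leaving `F1` below `F2`) and `D+` for T1.
5. The null is the empirical distribution of **all** test statistics —
   both tails pooled — at a seeded sample of evidently-normal voxels;
   `p = (1 + #{null ≥ d}) / (1 + n)`. The pooling matters: the
   evidently-normal population is selected on the dark side of each
   sequence, so its lesion-tail statistics alone are truncated; the
   opposite tail of the selected population mirrors the lesion-side
   deviations of unselected tissue and keeps the null honest.
6. Per-sequence p-values are combined into one per voxel. The default is
   `max_p`: a voxel must be abnormal on *every* provided sequence, which is
   the conjunctive reading of the clinical definition (bright on T2/FLAIR
   *and* dark on T1). Fisher's chi-square pooling and `min_p` are
   available, but Fisher flags any voxel extreme on a single sequence —
   with T1 in the input set that turns all of cortex and CSF into
   detections, which is incompatible with how the method behaves on
   clinical data.
7. Confidence is `1 − p`, thresholded at the significance level
   (`α = 0.05`) to produce the binary mask.

Only candidate voxels are tested: voxels of the (refined) WM class outside
the evidently-normal mask. WMH is a white-matter pathology, and the tissue
restriction is also what the bright-GM→WM refinement step exists for: it
pulls juxtacortical lesion voxels into the tested class. Setting
`RunConfig.test_region = "brain"` tests every brain voxel outside the
normal mask instead.

### Tissue-conditional histograms

All histogram content — `F1`, `F2` and the null — is restricted to the
tested tissue class (WM by default). Without this, the ball around an
interface voxel ingests bright cortical GM or bright-on-T2 ventricular CSF
and manufactures a partial-volume "lesion" along every boundary; with it,
interface voxels are compared against equally truncated normal
neighborhoods. In `brain` mode this reduces to plain in-brain masking.

### The reference population

`F2` and the null are drawn from each sequence's own evidently-normal side
— the raw (unsmoothed) percentile rule (bottom 45% FLAIR / 50% T2 / 65% PD,
top 15% T1) restricted to the tested class — rather than from the final
cross-sequence normal mask. Two measured failure modes motivate this. The
intersected mask is so selective (the T1 rule alone caps it at 15% of the
brain) that its per-sequence intensity content is far from that of ordinary
tissue, displacing `F2` for every tested voxel at once. And selection by
*smoothed* intensity is spatially coherent at the scale of the histogram
ball, so smooth-selected centers carry their own selection into their local
histograms; a raw cut selects on voxel noise, which dilutes to nothing
among a ball's ~70 voxels. Lesions still never enter the reference: they
sit on the wrong side of the cut by polarity.

## The evidently-normal brain

1. Per sequence, the percentile rule is applied three times after Gaussian
   smoothing at 1, 2 and 3 mm ("size" is read as sigma; a FWHM switch is
   provided since the convention is ambiguous) and the masks intersected.
   Smoothing is renormalized inside the brain mask so the zero background
   cannot drag boundary voxels across the cut.
2. The intersected labeling trains an RBF-kernel SVM on per-voxel intensity
   features (taken at the median smoothing scale; raw-noise features shred
   the mask into salt) with balanced class weights, on a seeded subsample
   of at most `svm_subsample` voxels. The SVM is reduced to a single kernel
   node `beta·exp(−gamma‖x − z‖²) + b` by the fixed-point pre-image
   iteration `z ← Σ αᵢyᵢ k(xᵢ, z) xᵢ / Σ αᵢyᵢ k(xᵢ, z)`, started at the
   positive-class mean. On noisy, overlapping classes the raw iteration can
   leave the data domain, so iterates are clamped to the padded support
   bounding box and the final center is chosen among the converged iterate,
   the best-objective iterate and the initial center by training agreement;
   `beta`/`b` maximize agreement with the full SVM's decisions.
3. The conjunction of step 1 and the SVM-positive region is cleaned with a
   2-mm spherical structuring element rasterized on the grid (anisotropic
   in voxels on anisotropic grids). The default filter is a plain closing,
   which fills small holes and missing voxels — the stated purpose of the
   cleanup stage. The strict anti-extensive form
   `M ∧ open(close(open(M)))` is implemented and selectable
   (`fill_holes="proper"`), but on a porous mask its leading opening can
   erase almost everything (observed collapses of 10×–100× between seeds),
   which contradicts the hole-filling intent.
4. A mask smaller than `min_normal_voxels` (default 1000) raises an error:
   the candidate definition would be meaningless. An externally produced
   normal mask can be supplied to the pipeline instead, which also lets
   other normal-brain detectors drive the same statistics.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | significance level of the final threshold |
| `neighborhood_radius_mm` | 3 | local-histogram ball; lesion-scale locality, ~70 voxels at 1×1×2 mm |
| `histogram_bins` | 64 | equal-width bins over the normalized range |
| `smoothing_scales_mm` | 1, 2, 3 | multi-scale thresholding (sigma) |
| `percentiles` | 45/50/65/15 | evidently-normal side per sequence |
| `structuring_radius_mm` | 2 | spherical element of the cleanup filter |
| `null_sample_size` | 10000 | sampled normal centers for `F2` and the null |
| `combine_method` | `max_p` | per-sequence p-value fusion |
| `test_region` | `wm` | candidate tissue class |
| `seed` | 0 | feeds every random stage via per-stage child streams |

Determinism: each random stage draws from a child generator keyed by
(seed, stage name), so identical inputs, configuration and seed give
byte-identical confidence maps and masks, and adding a stage never
perturbs the others.

## The phantom

The generator emulates exactly the image properties the definition relies
on, at the point in the pipeline where the method operates — after
registration, skull stripping and bias correction:

- layered geometry: an ellipsoidal brain (44×44×60 mm radii) with a 4-mm
  cortical GM ribbon, deep WM, and two ellipsoidal CSF ventricles, on a
  96×96×64 grid at 1×1×2 mm;
- per-sequence class means in scanner-like arbitrary units with clinical
  contrast ordering (CSF dark on T1/FLAIR, bright on T2/PD; GM slightly
  brighter than WM on FLAIR, clearly darker on T1); additive Gaussian noise
  of SD 50 (Rician optional); a smooth within-class texture field (SD 5,
  8-mm scale) shared across sequences with opposite sign on T1, standing in
  for myelination; a per-sequence residual multiplicative bias field of
  amplitude 1% — the post-correction residual, since the pipeline consumes
  bias-corrected inputs;
- ten spherical lesions with radii U(4, 11) mm clipped to WM (≈19 cc, the
  typical load of an elderly memory-clinic cohort), hyperintense by 3 WM-SD
  on T2/FLAIR/PD and hypointense by the same on T1, with 1-mm blurred
  boundaries as partial-volume stand-ins;
- a tissue label map that mimics an intensity-driven upstream segmenter:
  partial-volume voxels at the WM interface are assigned to GM, as FSL FAST
  does — an exact geometric map would put mixed-signal voxels in the tested
  class that no real segmentation would;
- `degrade_tissue_map` flips an exact fraction of GM/WM boundary labels to
  stress robustness to imperfect upstream segmentation.

What the phantom does *not* contain: gyral folding, sulcal CSF, vessels and
perivascular spaces, MR physics (k-space, motion, ghosting), and any
regional heterogeneity beyond the 1% texture and bias fields. Passing
phantom tests therefore shows the statistics behave as designed under
controlled conditions; it does not certify clinical accuracy.

## Behavior, calibration, and known limitations

- **False positives concentrate where the model is weakest.** On the
  default lesion phantom the method recovers essentially every lesion voxel
  (FNR ≈ 0) while the FDR (~0.45) is dominated by partial-volume voxels at
  lesion borders — voxels whose neighborhoods genuinely contain lesion
  tissue — and by interface WM. Partial volume is the acknowledged open
  problem of histogram-based lesion definitions.
- **The aggregate false-positive rate runs near 2α, not α.** The candidate
  set is by construction the complement of the evidently-normal selection,
  i.e. selected toward the lesion side of the very axis the statistic
  measures, while the null can only be built from the selected-normal side.
  With a single global `F2` per sequence and class (a spatially varying
  reference is deliberately out of scope), this asymmetry is structural:
  measured over five lesion-free phantoms the flagged fraction of tested
  voxels at α = 0.05 is ≈ 0.10–0.11. The significance level is therefore
  an ordering parameter, not an exact error rate — consistent with using a
  fixed α as a convention rather than calibrating it per dataset.
- **Cross-sequence reproducibility is lesion-load dependent.** Masks from
  different single sequences share the true lesions but not the
  noise-driven part of their false positives; at the default ≈19 cc load
  the FLAIR-only vs T2-only Dice is ≈ 0.66–0.72 across seeds, and it rises
  with lesion load.
- **T1-only input is weak.** The top-15% T1 rule yields the most selective
  reference; T1-only masks diverge most from the others. Multi-sequence
  input with conjunctive fusion is the intended operating mode.
- Numerical choices: bin index is `min(floor(64·v), 63)` everywhere, so the
  scalar and vectorized histogram paths agree exactly; percentile cuts
  include ties with a 1e-9 relative epsilon; the add-one p-value estimator
  never returns 0, keeping Fisher defined; empty-mask metric conventions
  (`Dice(∅, ∅) = 1`, empty-test FDR = 0) avoid NaNs in cohort tables.
- Grid contracts: all inputs must share one grid (shape, spacing, affine
  within 1e-4); mismatch is an error, never an implicit resample.
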