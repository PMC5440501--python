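"""Evidently-normal brain extraction.

The statistical lesion definition needs a conservative set of voxels assumed
lesion-free. It is built in two steps: (1) per-sequence multi-scale
percentile thresholding that keeps the hypo-intense side on hyper-polarity
sequences (and vice versa on T1), intersected over scales and sequences;
(2) consolidation by a Gaussian-kernel SVM reduced to a single kernel node,
whose positive region is intersected with step 1. A "proper closing"
(M AND opening(closing(opening(M)))) with a 2-mm spherical element cleans the
result. A tissue-map refinement relabels bright cortical GM that is mostly
WM-surrounded, pulling juxtacortical lesion candidates into the WM class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.svm import SVC

from .core import (
    BACKGROUND,
    GM,
    WM,
    RunConfig,
    SequenceVolume,
    Study,
    TissueMap,
    VoxelMask,
    gaussian_smooth,
    require_same_grid,
    sphere_offsets,
    sphere_structure,
)
from .errors import DegenerateVolumeError, InputError, UnusableNormalModelError

__all__ = [
    "StructuringElement",
    "SingleNodeSVM",
    "refine_tissue_map",
    "percentile_mask",
    "multiscale_threshold",
    "train_single_node_svm",
    "proper_closing",
    "evident_normal_mask",
]


@dataclass
class StructuringElement:
    """Spherical structuring element rasterized on the reference grid."""

    radius_mm: float
    spacing: tuple

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        self.offsets = sphere_offsets(self.radius_mm, self.spacing)
        self.structure = sphere_structure(self.radius_mm, self.spacing)


# ---------------------------------------------------------------------------
# tissue-map refinement
# ---------------------------------------------------------------------------

_KERNEL_26 = np.ones((3, 3, 3), dtype=np.float64)
_KERNEL_26[1, 1, 1] = 0.0


def _neighbor_count(mask: np.ndarray) -> np.ndarray:
    return ndimage.correlate(
        mask.astype(np.float64), _KERNEL_26, mode="constant", cval=0.0
    )


def refine_tissue_map(tissue: TissueMap, study: Study) -> TissueMap:
    """Relabel GM voxels that are bright on FLAIR or T2.

    GM voxels in the top 15% of the GM-restricted intensity histogram on
    either FLAIR or T2 are "suspicious". A suspicious voxel becomes WM when a
    strict majority of its non-suspicious, non-background 26-neighbors is WM,
    becomes (stays) GM when the strict majority is GM, and stays GM otherwise.
    Only GM labels ever change.
    """
    kinds = [k for k in ("FLAIR", "T2") if k in study.volumes]
    if not kinds:
        return tissue.copy()
    gm = tissue.labels == GM
    if not gm.any():
        warnings.warn("tissue map has no GM voxels; refinement skipped")
        return tissue.copy()

    suspicious = np.zeros(tissue.shape, dtype=bool)
    for kind in kinds:
        vol = study.volumes[kind]
        require_same_grid(vol, tissue)
        cut = np.percentile(vol.data[gm], 85.0)
        suspicious |= gm & (vol.data >= cut)
    if not suspicious.any():
        return tissue.copy()

    eligible = (tissue.labels != BACKGROUND) & ~suspicious
    n_eligible = _neighbor_count(eligible)
    n_wm = _neighbor_count(eligible & (tissue.labels == WM))

    out = tissue.copy()
    to_wm = suspicious & (2.0 * n_wm > n_eligible)
    out.labels[to_wm] = WM
    # strict GM majority (or tie / no eligible neighbor) leaves the label GM
    return out


# ---------------------------------------------------------------------------
# multi-scale percentile thresholding
# ---------------------------------------------------------------------------

def percentile_mask(
    vol: SequenceVolume, brain: VoxelMask, percentile: float, polarity: str | None = None
) -> VoxelMask:
    """Evidently-normal side of a per-sequence percentile threshold.

    Hyper-polarity sequences keep the bottom ``percentile`` % of in-brain
    voxels (lesions are bright there); T1 keeps the top ``percentile`` %.
    Ties at the cut value are all included.
    """
    if not 0.0 < percentile < 100.0:
        raise InputError(f"percentile must be in (0, 100), got {percentile}")
    require_same_grid(vol, brain)
    if brain.count() == 0:
        raise DegenerateVolumeError("empty brain mask")
    polarity = vol.polarity if polarity is None else polarity
    values = vol.data[brain.data]
    # ties at the cut are included; the epsilon absorbs float jitter (e.g.
    # renormalized smoothing of a constant region) without affecting data
    # whose values differ by more than ~1e-9 of their magnitude
    if polarity == "hyper":
        cut = np.percentile(values, percentile)
        keep = vol.data <= cut + 1e-9 * max(1.0, abs(cut))
    else:
        cut = np.percentile(values, 100.0 - percentile)
        keep = vol.data >= cut - 1e-9 * max(1.0, abs(cut))
    return brain.with_data(brain.data & keep)


def multiscale_threshold(
    vol: SequenceVolume,
    brain: VoxelMask,
    cfg: RunConfig,
    percentile: float | None = None,
) -> VoxelMask:
    """Intersection of percentile masks after smoothing at each scale.

    Smoothing is renormalized inside the brain mask so the zero background
    cannot drag boundary voxels across the percentile cut.
    """
    if percentile is None:
        percentile = cfg.percentiles[vol.kind]
    out = np.ones(vol.shape, dtype=bool)
    for scale in cfg.smoothing_scales_mm:
        smoothed = gaussian_smooth(vol, cfg.sigma_mm(scale), mask=brain)
        out &= percentile_mask(smoothed, brain, percentile, vol.polarity).data
    return brain.with_data(out & brain.data)


# ---------------------------------------------------------------------------
# single-node SVM (reduced-set approximation of a Gaussian-kernel SVM)
# ---------------------------------------------------------------------------

@dataclass
class SingleNodeSVM:
    """One-kernel-node approximation of an RBF SVM decision function.

    Decision: positive iff beta * exp(-gamma * ||x - z||^2) + b > 0, i.e. a
    ball (beta > 0) or ball-complement (beta < 0) in feature space.
    """

    z: np.ndarray
    beta: float
    b: float
    gamma: float

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        d2 = ((X - self.z[None, :]) ** 2).sum(axis=1)
        return self.beta * np.exp(-self.gamma * d2) + self.b

    def decide(self, X: np.ndarray) -> np.ndarray:
        return self.score(X) > 0.0


def _reduce_to_single_node(
    support: np.ndarray, alpha_y: np.ndarray, gamma: float, z0: np.ndarray
) -> list[np.ndarray]:
    """Fixed-point pre-image iteration for the SVM weight vector.

    z <- sum_i alpha_i y_i k(x_i, z) x_i / sum_i alpha_i y_i k(x_i, z),
    started at the positive-class mean, run to ||dz|| < 1e-6 or 100 steps.
    On noisy data the mixed-sign weights can push the iterate out of the
    data domain, so iterates are clamped to the (slightly padded) support
    bounding box and candidate centers are returned for empirical selection:
    the converged iterate, the iterate with the largest |sum alpha_y k|
    objective, and the initial center itself.
    """
    lo = support.min(axis=0)
    hi = support.max(axis=0)
    pad = 0.1 * (hi - lo + 1e-12)
    lo, hi = lo - pad, hi + pad

    z = np.clip(z0.astype(np.float64).copy(), lo, hi)
    best_obj, z_best = -np.inf, z.copy()
    for _ in range(100):
        d2 = ((support - z[None, :]) ** 2).sum(axis=1)
        w = alpha_y * np.exp(-gamma * d2)
        denom = w.sum()
        if abs(denom) > best_obj:
            best_obj, z_best = abs(denom), z.copy()
        if abs(denom) < 1e-12:
            break
        z_new = np.clip((w[:, None] * support).sum(axis=0) / denom, lo, hi)
        if np.linalg.norm(z_new - z) < 1e-6:
            z = z_new
            break
        z = z_new
    return [z, z_best, np.clip(z0.astype(np.float64), lo, hi)]


def _best_threshold(scores: np.ndarray, targets: np.ndarray) -> tuple[float, float]:
    """(beta, b) maximizing agreement of sign(beta*s + b) with binary targets."""
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    t = targets[order].astype(np.int64)
    n = len(s)
    pos_left = np.concatenate([[0], np.cumsum(t)])  # positives among s[:i]
    total_pos = pos_left[-1]
    best = (-1, 1.0, 0.0)
    # cut after index i-1: predict positive for s >= s_cut (beta=+1) or s < s_cut
    for i in range(n + 1):
        acc_hi = (total_pos - pos_left[i]) + (i - pos_left[i])  # positive = right side
        acc_lo = pos_left[i] + ((n - i) - (total_pos - pos_left[i]))
        if i == 0:
            cut = s[0] - 1.0
        elif i == n:
            cut = s[-1] + 1.0
        else:
            cut = 0.5 * (s[i - 1] + s[i])
        if acc_hi > best[0]:
            best = (acc_hi, 1.0, -cut)
        if acc_lo > best[0]:
            best = (acc_lo, -1.0, cut)
    _, beta, b = best
    return beta, b


def train_single_node_svm(
    features: np.ndarray, labels: np.ndarray, cfg: RunConfig
) -> SingleNodeSVM:
    """Fit an RBF SVM on a seeded subsample and reduce it to one kernel node.

    The node center z is the fixed point of the reduced-set pre-image
    iteration; beta and b are chosen to maximize agreement with the full
    SVM's decisions on the training subsample.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if X.ndim != 2 or len(X) != len(y):
        raise InputError("features must be (n, d) with one label per row")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateVolumeError("single-class training set")
    if n_pos < 10 or n_neg < 10:
        raise DegenerateVolumeError("need at least 10 samples per class")

    rng = cfg.rng("single-node-svm")
    if len(X) > cfg.svm_subsample:
        idx = rng.choice(len(X), size=cfg.svm_subsample, replace=False)
        Xs, ys = X[idx], y[idx]
        if ys.all() or not ys.any():  # resample kept one class only
            raise DegenerateVolumeError("subsample lost one class; increase svm_subsample")
    else:
        Xs, ys = X, y

    gamma = 1.0 / (X.shape[1] * X.var())
    # balanced class weights: the step-1 labeling is deliberately
    # conservative (a small positive class), and the consolidation step must
    # generalize it, not shrink toward the majority class
    svm = SVC(C=1.0, kernel="rbf", gamma=gamma, class_weight="balanced")
    svm.fit(Xs, ys.astype(int))

    alpha_y = svm.dual_coef_[0]
    candidates = _reduce_to_single_node(
        svm.support_vectors_, alpha_y, gamma, Xs[ys].mean(axis=0)
    )
    target = svm.predict(Xs).astype(bool)
    best = None
    for z in candidates:
        scores = np.exp(-gamma * ((Xs - z[None, :]) ** 2).sum(axis=1))
        beta, b = _best_threshold(scores, target)
        agree = np.mean((beta * scores + b > 0) == target)
        if best is None or agree > best[0]:
            best = (agree, SingleNodeSVM(z=z, beta=beta, b=b, gamma=gamma))
    return best[1]


# ---------------------------------------------------------------------------
# proper closing
# ---------------------------------------------------------------------------

def proper_closing(mask: VoxelMask, se: StructuringElement) -> VoxelMask:
    """M AND opening(closing(opening(M))): anti-extensive cleanup.

    Structures smaller than the element vanish under the first opening;
    the conjunction with M guarantees result <= M.
    """
    m = mask.data
    s = se.structure
    inner = ndimage.binary_opening(m, structure=s)
    inner = ndimage.binary_closing(inner, structure=s)
    inner = ndimage.binary_opening(inner, structure=s)
    return mask.with_data(m & inner)


def closing_only(mask: VoxelMask, se: StructuringElement) -> VoxelMask:
    """Plain morphological closing (extensive hole filling), offered as the
    ``fill_holes='closing-only'`` alternative to the anti-extensive default."""
    return mask.with_data(ndimage.binary_closing(mask.data, structure=se.structure))


# ---------------------------------------------------------------------------
# the evidently-normal mask
# ---------------------------------------------------------------------------

def evident_normal_mask(
    study: Study,
    cfg: RunConfig,
    return_intermediate: bool = False,
):
    """Conservative lesion-free voxel set for one subject.

    AND of per-sequence multi-scale percentile masks, AND the positive region
    of the single-node SVM trained on that step-1 labeling over per-voxel
    intensity features, then proper closing with the configured spherical
    element. Background is always excluded. Volumes are expected to be
    intensity-normalized to [0, 1].
    """
    brain = study.tissue.brain_mask()
    step1 = np.ones(brain.shape, dtype=bool)
    per_sequence = {}
    for kind, vol in study.volumes.items():
        m = multiscale_threshold(vol, brain, cfg)
        per_sequence[kind] = m
        step1 &= m.data
    step1 &= brain.data

    # SVM features: per-voxel intensities at the median configured scale.
    # Raw-noise features shred the consolidated mask into salt that the
    # proper closing then erases wholesale; the median smoothing scale keeps
    # the decision per-voxel while matching the scale family the training
    # labels were derived at.
    feat_sigma = cfg.sigma_mm(float(np.median(cfg.smoothing_scales_mm)))
    feats = np.stack(
        [
            gaussian_smooth(study.volumes[k], feat_sigma, mask=brain).data[brain.data]
            for k in study.kinds
        ],
        axis=1,
    )
    model = train_single_node_svm(feats, step1[brain.data], cfg)
    step2 = np.zeros(brain.shape, dtype=bool)
    step2[brain.data] = model.decide(feats)

    combined = brain.with_data(step1 & step2)
    se = StructuringElement(cfg.structuring_radius_mm, tuple(brain.spacing))
    if cfg.fill_holes == "closing-only":
        closed = closing_only(combined, se)
    else:
        closed = proper_closing(combined, se)
    result = brain.with_data(closed.data & brain.data)

    if result.count() < cfg.min_normal_voxels and not return_intermediate:
        raise UnusableNormalModelError(
            f"evidently-normal mask has {result.count()} voxels "
            f"(< {cfg.min_normal_voxels}); cannot support the null estimation"
        )
    if not return_intermediate:
        return result
    intermediate = {
        "step1_per_sequence": per_sequence,
        "step1": brain.with_data(step1),
        "step1_candidates": brain.with_data(brain.data & ~step1),
        "step2_svm": brain.with_data(step2),
        "svm": model,
    }
    return result, intermediate
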