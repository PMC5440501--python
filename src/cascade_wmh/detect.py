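"""The statistical lesion definition.

A voxel is called WMH when the cumulative histogram of intensities in its
local spherical neighborhood (F1) differs significantly from the expected
normal local histogram (F2) under a one-tailed Kolmogorov-Smirnov test:

    D+ = sup_i (F1(i) - F2(i))        D- = sup_i (F2(i) - F1(i))

F2 is the average of the local cumulative histograms of evidently-normal
voxels of the same subject and sequence. The null distribution of the
directional statistic (D- on hyper-polarity sequences, D+ on T1) is the
empirical distribution of that statistic over evidently-normal voxels;
p-values use the add-one estimator p = (1 + #{null >= d}) / (1 + n), so the
test is exact-level without any parametric assumption. Per-sequence p-values
are fused into one combined p, and confidence = 1 - p is thresholded at the
significance level to give the binary lesion mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .core import (
    WM,
    RunConfig,
    SequenceVolume,
    Study,
    VoxelMask,
    require_same_grid,
    sphere_offsets,
)
from .errors import DegenerateVolumeError, InputError

__all__ = [
    "CumulativeHistogram",
    "KSResult",
    "EmpiricalNull",
    "ConfidenceMap",
    "local_cumulative_histogram",
    "expected_normal_histogram",
    "ks_statistic",
    "directional_statistic",
    "build_empirical_null",
    "p_value",
    "combine_pvalues",
    "confidence_map",
    "threshold_confidence",
]


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def _bin_index(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin index on n_bins equal-width bins over [0, 1]; 1.0 falls in the last."""
    idx = (np.asarray(values) * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


@dataclass
class CumulativeHistogram:
    """Normalized cumulative intensity histogram on equal-width [0, 1] bins."""

    bin_edges: np.ndarray
    F: np.ndarray
    support_count: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.F = np.asarray(self.F, dtype=np.float64)
        if len(self.bin_edges) != len(self.F) + 1:
            raise InputError("bin_edges must have one more entry than F")
        if np.any(np.diff(self.F) < -1e-12):
            raise InputError("cumulative histogram must be nondecreasing")
        if self.support_count > 0 and abs(self.F[-1] - 1.0) > 1e-9:
            raise InputError("cumulative histogram must end at 1")

    @property
    def n_bins(self) -> int:
        return len(self.F)


@dataclass
class KSResult:
    """One-tailed KS statistics: both tails, each floored at 0."""

    d_plus: float
    d_minus: float


@dataclass
class EmpiricalNull:
    """Sorted pooled KS statistics at evidently-normal voxels.

    The container accepts any non-empty statistic list; the adequacy
    requirement (at least 100 usable normal centers) is enforced where the
    null is estimated from image data, in build_empirical_null.
    """

    statistics: np.ndarray

    def __post_init__(self) -> None:
        self.statistics = np.sort(np.asarray(self.statistics, dtype=np.float64))
        if self.n == 0:
            raise DegenerateVolumeError("empirical null needs at least one statistic")
        if self.statistics[0] < -1e-12 or self.statistics[-1] > 1 + 1e-12:
            raise InputError("null statistics must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.statistics)


@dataclass
class ConfidenceMap:
    """Per-voxel lesion confidence 1 - combined p on the tested region.

    Per-sequence p-value grids are retained for audit; voxels outside the
    tested region carry confidence 0 (combined p 1).
    """

    affine: np.ndarray
    values: np.ndarray
    p_combined: np.ndarray
    tested: np.ndarray
    p_per_sequence: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.values.shape


def local_cumulative_histogram(
    vol: SequenceVolume, brain: VoxelMask, center, cfg: RunConfig
) -> CumulativeHistogram:
    """Cumulative histogram of in-brain intensities around one voxel.

    The neighborhood is the Euclidean ball of cfg.neighborhood_radius_mm
    around the center, clipped to the grid and to the brain mask.
    """
    require_same_grid(vol, brain)
    center = np.asarray(center, dtype=np.int64)
    if not brain.data[tuple(center)]:
        raise InputError(f"center {tuple(center)} is not inside the brain mask")
    offs = sphere_offsets(cfg.neighborhood_radius_mm, vol.spacing)
    pts = center[None, :] + offs
    inside = np.all((pts >= 0) & (pts < np.array(vol.shape)[None, :]), axis=1)
    pts = pts[inside]
    sel = brain.data[pts[:, 0], pts[:, 1], pts[:, 2]]
    pts = pts[sel]
    if len(pts) == 0:
        raise DegenerateVolumeError("neighborhood entirely outside the brain")
    values = vol.data[pts[:, 0], pts[:, 1], pts[:, 2]]
    counts = np.bincount(_bin_index(values, cfg.histogram_bins), minlength=cfg.histogram_bins)
    F = np.cumsum(counts) / len(values)
    edges = np.linspace(0.0, 1.0, cfg.histogram_bins + 1)
    return CumulativeHistogram(bin_edges=edges, F=F, support_count=len(values))


def _cumulative_count_maps(
    vol: SequenceVolume, brain: VoxelMask, cfg: RunConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized local histograms for every voxel at once.

    Returns (C, n): C[b, x, y, z] is the number of in-brain neighbors of
    (x, y, z) with bin index <= b, n the number of in-brain neighbors.
    Exactly matches local_cumulative_histogram at every in-brain center.
    """
    B = cfg.histogram_bins
    shape = vol.shape
    bidx = _bin_index(vol.data, B)
    bidx[~brain.data] = B  # sentinel: never counted
    offs = sphere_offsets(cfg.neighborhood_radius_mm, vol.spacing)

    counts = np.zeros((B,) + shape, dtype=np.float32)
    onehot = np.empty(shape, dtype=np.float32)
    for b in range(B):
        onehot[...] = (bidx == b)
        acc = counts[b]
        for dz, dy, dx in offs:
            src = tuple(
                slice(max(-d, 0), s - max(d, 0)) for d, s in zip((dz, dy, dx), shape)
            )
            dst = tuple(
                slice(max(d, 0), s - max(-d, 0)) for d, s in zip((dz, dy, dx), shape)
            )
            acc[dst] += onehot[src]
    np.cumsum(counts, axis=0, out=counts)
    n = counts[-1].copy()
    return counts, n


def expected_normal_histogram(
    vol: SequenceVolume,
    normal: VoxelMask,
    brain: VoxelMask,
    cfg: RunConfig,
    _maps=None,
) -> CumulativeHistogram:
    """Binwise mean of local cumulative histograms over normal voxels.

    Averaged over a seeded uniform subsample of at most cfg.null_sample_size
    evidently-normal centers; the mean of nondecreasing [0, 1] CDFs ending at
    1 retains all three properties.
    """
    require_same_grid(vol, normal)
    if normal.count() < cfg.min_normal_voxels:
        raise DegenerateVolumeError(
            f"normal mask too small ({normal.count()} voxels) for the reference histogram"
        )
    centers = _sample_mask_voxels(normal, cfg.null_sample_size, cfg.rng(f"f2:{vol.kind}"))
    C, n = _maps if _maps is not None else _cumulative_count_maps(vol, brain, cfg)
    cz, cy, cx = centers[:, 0], centers[:, 1], centers[:, 2]
    F1 = C[:, cz, cy, cx] / n[cz, cy, cx][None, :]
    F = F1.mean(axis=1).astype(np.float64)
    F[-1] = 1.0  # guard float accumulation
    edges = np.linspace(0.0, 1.0, cfg.histogram_bins + 1)
    return CumulativeHistogram(
        bin_edges=edges, F=F, support_count=int(n[cz, cy, cx].sum())
    )


def _sample_mask_voxels(mask: VoxelMask, size: int, rng: np.random.Generator) -> np.ndarray:
    coords = np.argwhere(mask.data)
    if len(coords) > size:
        coords = coords[rng.choice(len(coords), size=size, replace=False)]
    return coords


# ---------------------------------------------------------------------------
# KS statistics and p-values
# ---------------------------------------------------------------------------

def ks_statistic(F1: CumulativeHistogram, F2: CumulativeHistogram) -> KSResult:
    """Both one-tailed KS statistics of two cumulative histograms."""
    if F1.n_bins != F2.n_bins or not np.allclose(F1.bin_edges, F2.bin_edges):
        raise InputError("cumulative histograms must share bin edges")
    diff = F1.F - F2.F
    return KSResult(
        d_plus=float(max(diff.max(), 0.0)),
        d_minus=float(max((-diff).max(), 0.0)),
    )


def directional_statistic(ks: KSResult, polarity: str) -> float:
    """The tail that detects lesions of the given polarity.

    A hyperintense region right-shifts the local histogram so F1 falls below
    F2: D-. A hypointense region (T1) does the opposite: D+.
    """
    return ks.d_minus if polarity == "hyper" else ks.d_plus


def build_empirical_null(
    vol: SequenceVolume,
    normal: VoxelMask,
    F2: CumulativeHistogram,
    cfg: RunConfig,
    brain: VoxelMask | None = None,
    _maps=None,
) -> EmpiricalNull:
    """Pooled KS statistics at a seeded subsample of normal voxels.

    The null is the empirical distribution of all test statistics over the
    evidently-normal brain: both tails (D+ and D-) of every sampled normal
    center enter the pool. Because the normal mask is selected on intensity
    (e.g. the dark side of FLAIR), its one-sided deviations from F2 are
    asymmetric; the opposite tail of the selected population mirrors the
    lesion-side deviations of the tested population, so the pooled null
    absorbs the selection effect instead of understating it.
    """
    require_same_grid(vol, normal)
    brain = normal if brain is None else brain
    centers = _sample_mask_voxels(normal, cfg.null_sample_size, cfg.rng(f"null:{vol.kind}"))
    if len(centers) < 100:
        raise DegenerateVolumeError(
            f"only {len(centers)} usable normal centers for the null (need >= 100)"
        )
    C, n = _maps if _maps is not None else _cumulative_count_maps(vol, brain, cfg)
    cz, cy, cx = centers[:, 0], centers[:, 1], centers[:, 2]
    F1 = C[:, cz, cy, cx] / n[cz, cy, cx][None, :]
    diff = F2.F[:, None] - F1
    d_minus = np.maximum(diff.max(axis=0), 0.0)
    d_plus = np.maximum((-diff).max(axis=0), 0.0)
    return EmpiricalNull(statistics=np.concatenate([d_plus, d_minus]))


def p_value(d, null: EmpiricalNull):
    """Add-one empirical p-value: p = (1 + #{null >= d}) / (1 + n).

    Monotone nonincreasing in d with floor 1/(n+1); never exactly 0, so
    Fisher combination is always defined.
    """
    d = np.asarray(d, dtype=np.float64)
    exceed = null.n - np.searchsorted(null.statistics, d, side="left")
    p = (1.0 + exceed) / (1.0 + null.n)
    return float(p) if p.ndim == 0 else p


def combine_pvalues(ps, method: str = "max_p"):
    """Fuse per-sequence p-values into one.

    ``max_p`` requires every sequence to be abnormal (conjunction of the
    hyper-on-T2/FLAIR and hypo-on-T1 appearance); ``fisher`` pools evidence
    via chi-square on -2*sum(log p); ``min_p`` takes the strongest sequence.
    All methods are the identity on a single sequence.
    """
    ps = np.asarray(ps, dtype=np.float64)
    if ps.ndim == 0 or ps.shape[0] == 0:
        raise InputError("need at least one p-value")
    if ps.ndim == 1 and not 1 <= len(ps) <= 4:
        raise InputError("expected 1-4 per-sequence p-values")
    if method == "fisher":
        x = -2.0 * np.log(ps).sum(axis=0)
        out = sstats.chi2.sf(x, df=2 * ps.shape[0])
    elif method == "max_p":
        out = ps.max(axis=0)
    elif method == "min_p":
        out = ps.min(axis=0)
    else:
        raise InputError(f"unknown combination method {method!r}")
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# confidence map and thresholding
# ---------------------------------------------------------------------------

def confidence_map(study: Study, normal: VoxelMask, cfg: RunConfig) -> ConfidenceMap:
    """Test every candidate voxel against the statistical lesion definition.

    Candidates are the voxels outside the evidently-normal mask, restricted
    to the (refined) WM class by default (cfg.test_region='brain' tests the
    whole brain instead). Voxels inside the normal mask or outside the
    candidate region get confidence exactly 0.

    Each sequence's expected-normal histogram and empirical null are drawn
    from that sequence's own evidently-normal side -- the raw (unsmoothed)
    percentile rule -- restricted to the tested tissue class. Three reasons:
    the cross-sequence intersection that defines the final normal mask is so
    selective that its per-sequence intensity content is unrepresentative;
    an unmatched reference (e.g. CSF mass inside a WM comparison) would
    displace the expected histogram for every tested voxel alike; and the
    multi-scale smoothed selection is spatially coherent at the neighborhood
    scale, so smooth-selected centers carry their own selection into their
    local histograms, while a raw percentile cut selects on voxel noise that
    dilutes to nothing inside the neighborhood. Lesion voxels still never
    enter the reference: they sit on the wrong side of the cut by polarity.
    """
    from .normal import percentile_mask

    brain = study.tissue.brain_mask()
    require_same_grid(brain, normal)
    if cfg.test_region == "wm":
        region = study.tissue.labels == WM
    else:
        region = brain.data
    tested = region & brain.data & ~normal.data

    # All histogram content is restricted to the tested tissue class: the
    # lesion definition compares white-matter neighborhoods, and letting
    # bright cortical GM or CSF enter an interface voxel's histogram would
    # manufacture partial-volume "lesions" along every boundary. In
    # test_region='brain' mode this reduces to plain in-brain masking.
    content = brain.with_data(region & brain.data)

    shape = brain.shape
    p_seq = {}
    p_stack = []
    for kind in study.kinds:
        vol = study.volumes[kind]
        cut = percentile_mask(vol, brain, cfg.percentiles[kind], vol.polarity)
        reference = cut.with_data(cut.data & region)
        maps = _cumulative_count_maps(vol, content, cfg)
        F2 = expected_normal_histogram(vol, reference, content, cfg, _maps=maps)
        null = build_empirical_null(vol, reference, F2, cfg, brain=content, _maps=maps)
        C, n = maps
        # directional statistic for every voxel, streaming over bins
        d = np.full(shape, -np.inf, dtype=np.float32)
        sign = 1.0 if vol.polarity == "hyper" else -1.0
        for b in range(cfg.histogram_bins):
            F1_b = C[b] / np.maximum(n, 1.0)
            np.maximum(d, sign * (F2.F[b] - F1_b), out=d)
        d = np.maximum(d, 0.0)
        p = np.ones(shape, dtype=np.float64)
        p[tested] = p_value(d[tested].astype(np.float64), null)
        p_seq[kind] = p
        p_stack.append(p[tested])
        del C, n, maps, d

    p_comb = np.ones(shape, dtype=np.float64)
    p_comb[tested] = combine_pvalues(np.stack(p_stack, axis=0), cfg.combine_method)
    values = np.zeros(shape, dtype=np.float64)
    values[tested] = 1.0 - p_comb[tested]
    return ConfidenceMap(
        affine=brain.affine,
        values=values,
        p_combined=p_comb,
        tested=tested,
        p_per_sequence=p_seq,
    )


def threshold_confidence(cm: ConfidenceMap, alpha: float) -> VoxelMask:
    """Binary lesion mask: tested voxels with combined p <= alpha."""
    if not 0.0 < alpha < 1.0:
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    return VoxelMask(affine=cm.affine, data=cm.tested & (cm.p_combined <= alpha))
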