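"""Imaging substrate: volumes, masks, tissue maps, configuration, and I/O.

All spatial objects live on a single reference voxel grid (shape, spacing and
affine agree within a small tolerance); registration is upstream of this
package, so a grid mismatch is an error, never an implicit resample.
Intensities are normalized to [0, 1] with robust percentiles before any
histogramming so that bins are comparable across subjects and scanners.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    ConfigError,
    DegenerateVolumeError,
    GridMismatchError,
    InputError,
)

SEQUENCE_KINDS = ("T1", "T2", "FLAIR", "PD")

#: WMH polarity per sequence: lesions are hyperintense on T2/FLAIR/PD and
#: hypointense on T1.
POLARITY = {"T1": "hypo", "T2": "hyper", "FLAIR": "hyper", "PD": "hyper"}

#: Tissue label codes used throughout.
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3

GRID_TOL = 1e-4

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# deterministic per-stage randomness
# ---------------------------------------------------------------------------

def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named pipeline stage.

    The child stream is a pure function of (seed, stage name), so adding or
    reordering stages never perturbs the randomness of the others.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def grids_match(shape_a, affine_a, shape_b, affine_b, tol: float = GRID_TOL) -> bool:
    return tuple(shape_a) == tuple(shape_b) and bool(
        np.allclose(affine_a, affine_b, atol=tol)
    )


def require_same_grid(a: "_Gridded", b: "_Gridded") -> None:
    if not grids_match(a.shape, a.affine, b.shape, b.affine):
        raise GridMismatchError(
            f"objects do not share one grid: {a.shape} vs {b.shape}"
        )


@dataclass
class _Gridded:
    affine: np.ndarray

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm per axis, derived from the affine."""
        return _spacing_from_affine(self.affine)


@dataclass
class SequenceVolume(_Gridded):
    """One co-registered, skull-stripped 3-D MRI volume.

    ``polarity`` is a pure function of the sequence kind: WMH are dark on T1
    and bright on T2/FLAIR/PD.
    """

    data: np.ndarray = None
    kind: str = "FLAIR"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.kind not in SEQUENCE_KINDS:
            raise InputError(f"unknown sequence kind {self.kind!r}")
        if self.data.ndim != 3:
            raise InputError(f"expected a 3-D volume, got shape {self.data.shape}")
        if np.any(self.spacing <= 0):
            raise InputError("voxel spacing must be positive")

    @property
    def shape(self):
        return self.data.shape

    @property
    def polarity(self) -> str:
        return POLARITY[self.kind]

    def with_data(self, data: np.ndarray) -> "SequenceVolume":
        return SequenceVolume(affine=self.affine, data=data, kind=self.kind)


@dataclass
class VoxelMask(_Gridded):
    """Binary mask on the reference grid."""

    data: np.ndarray = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise InputError(f"expected a 3-D mask, got shape {self.data.shape}")

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "VoxelMask":
        return VoxelMask(affine=self.affine, data=data)


@dataclass
class TissueMap(_Gridded):
    """CSF/GM/WM labeling; background (0) marks out-of-brain voxels."""

    labels: np.ndarray = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.labels.ndim != 3:
            raise InputError(f"expected a 3-D label map, got {self.labels.shape}")
        if self.labels.max(initial=0) > WM:
            raise InputError("tissue labels must be in {0:bg, 1:CSF, 2:GM, 3:WM}")

    @property
    def shape(self):
        return self.labels.shape

    def brain_mask(self) -> VoxelMask:
        return VoxelMask(affine=self.affine, data=self.labels != BACKGROUND)

    def class_mask(self, label: int) -> VoxelMask:
        return VoxelMask(affine=self.affine, data=self.labels == label)

    def copy(self) -> "TissueMap":
        return TissueMap(affine=self.affine.copy(), labels=self.labels.copy())


@dataclass
class Study:
    """All aligned inputs for one subject.

    The reference grid is FLAIR's if present, else T2's, else the first
    provided sequence; every volume and the tissue map must share it.
    """

    volumes: dict  # kind -> SequenceVolume
    tissue: TissueMap
    reference_kind: str = None

    def __post_init__(self) -> None:
        if not self.volumes:
            raise InputError("a study needs at least one sequence volume")
        for kind, vol in self.volumes.items():
            if vol.kind != kind:
                raise InputError(f"volume registered under {kind!r} has kind {vol.kind!r}")
        if self.reference_kind is None:
            for cand in ("FLAIR", "T2"):
                if cand in self.volumes:
                    self.reference_kind = cand
                    break
            else:
                self.reference_kind = next(iter(self.volumes))
        ref = self.volumes[self.reference_kind]
        for vol in self.volumes.values():
            require_same_grid(ref, vol)
        require_same_grid(ref, self.tissue)

    @property
    def reference(self) -> SequenceVolume:
        return self.volumes[self.reference_kind]

    @property
    def kinds(self):
        return tuple(self.volumes)

    def subset(self, kinds: Sequence[str]) -> "Study":
        """Same subject restricted to a subset of sequences."""
        missing = [k for k in kinds if k not in self.volumes]
        if missing:
            raise InputError(f"study has no {missing} volume(s)")
        return Study(
            volumes={k: self.volumes[k] for k in kinds},
            tissue=self.tissue,
        )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_PERCENTILES = {"FLAIR": 45.0, "T2": 50.0, "PD": 65.0, "T1": 15.0}


@dataclass
class RunConfig:
    """Tunable parameters of the whole pipeline.

    alpha
        Significance level for the final threshold; 0.05 throughout.
    neighborhood_radius_mm
        Radius of the spherical window of the local histogram.
    histogram_bins
        Equal-width bins over the normalized [0, 1] intensity range.
    smoothing_scales_mm
        Gaussian scales of the multi-scale percentile thresholding; the
        kernel "size" is read as sigma by default (``smoothing_kernel``
        switches to FWHM).
    percentiles
        Per-sequence evidently-normal percentile: the bottom p% on
        hyper-polarity sequences (FLAIR 45, T2 50, PD 65), the top p% on T1
        (15).
    combine_method
        Fusion of per-sequence p-values: ``max_p`` (default; a voxel must be
        abnormal on every provided sequence), ``fisher`` or ``min_p``.
    test_region
        ``wm``: test refined-WM voxels outside the normal mask (default);
        ``brain``: test every brain voxel outside the normal mask.
    """

    alpha: float = 0.05
    neighborhood_radius_mm: float = 3.0
    histogram_bins: int = 64
    smoothing_scales_mm: tuple = (1.0, 2.0, 3.0)
    smoothing_kernel: str = "sigma"  # or "fwhm"
    structuring_radius_mm: float = 2.0
    percentiles: dict = field(default_factory=lambda: dict(DEFAULT_PERCENTILES))
    null_sample_size: int = 10000
    combine_method: str = "max_p"
    min_normal_voxels: int = 1000
    svm_subsample: int = 8000
    fill_holes: str = "closing-only"  # or "proper" (the strict anti-extensive form)
    test_region: str = "wm"  # or "brain"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.neighborhood_radius_mm <= 0 or self.structuring_radius_mm <= 0:
            raise ConfigError("radii must be positive")
        if self.histogram_bins < 2:
            raise ConfigError("need at least 2 histogram bins")
        if not self.smoothing_scales_mm:
            raise ConfigError("smoothing_scales_mm must be non-empty")
        if any(s <= 0 for s in self.smoothing_scales_mm):
            raise ConfigError("smoothing scales must be positive")
        for kind, p in self.percentiles.items():
            if kind not in SEQUENCE_KINDS:
                raise ConfigError(f"unknown sequence kind {kind!r} in percentiles")
            if not 0.0 < p < 100.0:
                raise ConfigError(f"percentile for {kind} must be in (0, 100)")
        if self.combine_method not in ("fisher", "max_p", "min_p"):
            raise ConfigError(f"unknown combine_method {self.combine_method!r}")
        if self.smoothing_kernel not in ("sigma", "fwhm"):
            raise ConfigError("smoothing_kernel must be 'sigma' or 'fwhm'")
        if self.fill_holes not in ("proper", "closing-only"):
            raise ConfigError("fill_holes must be 'proper' or 'closing-only'")
        if self.test_region not in ("wm", "brain"):
            raise ConfigError("test_region must be 'wm' or 'brain'")
        if self.null_sample_size < 100:
            raise ConfigError("null_sample_size must be at least 100")
        self.smoothing_scales_mm = tuple(float(s) for s in self.smoothing_scales_mm)

    def sigma_mm(self, scale_mm: float) -> float:
        """Gaussian sigma in mm for a configured smoothing scale."""
        if self.smoothing_kernel == "fwhm":
            return float(scale_mm) * FWHM_TO_SIGMA
        return float(scale_mm)

    def rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.seed, stage)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["smoothing_scales_mm"] = list(self.smoothing_scales_mm)
        return d

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(text)
        elif path.suffix == ".json":
            data = json.loads(text)
        else:
            raise ConfigError(f"unsupported config format: {path.suffix!r}")
        if not isinstance(data, Mapping):
            raise ConfigError("config file must contain a mapping")
        return cls.from_mapping(data)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path, kind: str, brain: VoxelMask | None = None) -> SequenceVolume:
    """Read a scalar NIfTI-1/2 image as a SequenceVolume.

    Raises InputError for unreadable files, 4-D/non-scalar images, or
    non-finite values inside a declared brain mask.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise InputError(f"cannot read NIfTI file {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise InputError(f"{path}: expected a 3-D scalar image, got shape {img.shape}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    vol = SequenceVolume(affine=np.asarray(img.affine), data=data, kind=kind)
    if brain is not None:
        require_same_grid(vol, brain)
        if not np.all(np.isfinite(data[brain.data])):
            raise InputError(f"{path}: non-finite values inside the brain mask")
    return vol


def write_volume(vol: SequenceVolume, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    nib.save(img, str(path))


def read_mask(path) -> VoxelMask:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise InputError(f"cannot read NIfTI mask {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise InputError(f"{path}: expected a 3-D mask, got shape {img.shape}")
    return VoxelMask(affine=np.asarray(img.affine), data=np.asarray(img.dataobj) > 0)


def write_mask(mask: VoxelMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def read_tissue_map(path) -> TissueMap:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise InputError(f"cannot read NIfTI label map {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise InputError(f"{path}: expected a 3-D label map, got shape {img.shape}")
    labels = np.rint(np.asarray(img.dataobj)).astype(np.int64)
    if labels.min() < 0 or labels.max() > WM:
        raise InputError(f"{path}: labels outside {{0, 1, 2, 3}}")
    return TissueMap(affine=np.asarray(img.affine), labels=labels)


def write_tissue_map(tissue: TissueMap, path) -> None:
    img = nib.Nifti1Image(tissue.labels.astype(np.uint8), tissue.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# intensity normalization and smoothing
# ---------------------------------------------------------------------------

def normalize_intensities(vol: SequenceVolume, brain: VoxelMask) -> SequenceVolume:
    """Map in-brain intensities to [0, 1] with 1st/99th robust percentiles.

    The 1st percentile maps to 0 and the 99th to 1, then values are clipped;
    out-of-brain voxels are set to 0. Monotone on in-brain voxels, so
    percentile thresholds commute with it.
    """
    require_same_grid(vol, brain)
    if brain.count() == 0:
        raise DegenerateVolumeError("empty brain mask")
    values = vol.data[brain.data]
    lo, hi = np.percentile(values, [1.0, 99.0])
    if hi - lo <= 0:
        raise DegenerateVolumeError(
            f"{vol.kind}: constant in-brain image (zero robust range)"
        )
    out = np.zeros_like(vol.data)
    out[brain.data] = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    return vol.with_data(out)


def gaussian_smooth(
    vol: SequenceVolume, sigma_mm: float, mask: VoxelMask | None = None
) -> SequenceVolume:
    """Separable Gaussian filtering with sigma given in millimetres.

    Per-axis voxel sigma is sigma_mm / spacing_axis, so anisotropic grids are
    smoothed isotropically in physical space. With ``mask``, smoothing is
    renormalized inside the mask (smooth(v*m)/smooth(m)) so zero-filled
    background never dilutes intensities at the brain edge; outside-mask
    voxels are left at 0.
    """
    if sigma_mm <= 0:
        raise ConfigError(f"sigma_mm must be positive, got {sigma_mm}")
    sigmas = sigma_mm / vol.spacing
    if mask is None:
        return vol.with_data(
            ndimage.gaussian_filter(vol.data, sigma=sigmas, mode="nearest")
        )
    require_same_grid(vol, mask)
    m = mask.data.astype(np.float64)
    num = ndimage.gaussian_filter(vol.data * m, sigma=sigmas, mode="constant")
    den = ndimage.gaussian_filter(m, sigma=sigmas, mode="constant")
    out = np.zeros_like(vol.data)
    inside = mask.data
    out[inside] = num[inside] / den[inside]
    return vol.with_data(out)


# ---------------------------------------------------------------------------
# spherical neighborhoods in physical units
# ---------------------------------------------------------------------------

def sphere_offsets(radius_mm: float, spacing) -> np.ndarray:
    """Integer voxel offsets within Euclidean radius_mm given the spacing.

    Contains the origin and is symmetric under negation; on anisotropic grids
    the voxel footprint is anisotropic while the physical ball is not.
    """
    spacing = np.asarray(spacing, dtype=float)
    if radius_mm <= 0:
        raise ConfigError("radius must be positive")
    half = np.floor(radius_mm / spacing).astype(int)
    axes = [np.arange(-h, h + 1) for h in half]
    dz, dy, dx = np.meshgrid(*axes, indexing="ij")
    offs = np.stack([dz.ravel(), dy.ravel(), dx.ravel()], axis=1)
    dist2 = ((offs * spacing) ** 2).sum(axis=1)
    return offs[dist2 <= radius_mm**2 + 1e-9]


def sphere_structure(radius_mm: float, spacing) -> np.ndarray:
    """Boolean structuring-element array for the same physical ball."""
    offs = sphere_offsets(radius_mm, spacing)
    half = np.abs(offs).max(axis=0)
    shape = 2 * half + 1
    struct = np.zeros(shape, dtype=bool)
    struct[tuple((offs + half).T)] = True
    return struct
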