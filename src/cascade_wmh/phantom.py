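"""Seeded multi-sequence brain phantom with ground-truth lesions.

The phantom emulates the image properties the lesion definition relies on:
layered tissue geometry (an ellipsoidal brain with a cortical GM ribbon,
deep WM, and two ellipsoidal CSF ventricles), per-sequence tissue intensity
distributions with lesions hyperintense on FLAIR/T2/PD and hypointense on
T1, partial-volume-like blurred boundaries, a smooth residual multiplicative
bias field per sequence (inputs are assumed bias-corrected upstream, so the
default amplitude is the small post-correction residual; a session-shared
field is available via ``shared_bias``), and additive noise. It makes no
claim to
anatomical realism (no gyri, no sulcal CSF, no MR physics); it exists so the
entire pipeline is testable with no external data.

Intensities are generated in scanner-like arbitrary units and emitted
unnormalized; the pipeline's robust [0, 1] normalization is exercised, not
bypassed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    BACKGROUND,
    CSF,
    GM,
    WM,
    SequenceVolume,
    Study,
    TissueMap,
    VoxelMask,
    stage_rng,
)
from .errors import ConfigError, InputError

__all__ = ["PhantomSpec", "generate_phantom", "degrade_tissue_map"]


#: Per-sequence tissue means in arbitrary scanner-like units. Contrasts
#: follow clinical appearance: CSF dark on T1/FLAIR and bright on T2/PD,
#: cortical GM brighter than WM on FLAIR/T2/PD and darker on T1.
DEFAULT_INTENSITY_MEANS = {
    "FLAIR": {CSF: 160.0, GM: 510.0, WM: 480.0},
    "T2": {CSF: 800.0, GM: 540.0, WM: 490.0},
    "T1": {CSF: 220.0, GM: 480.0, WM: 600.0},
    "PD": {CSF: 720.0, GM: 600.0, WM: 560.0},
}

#: Within-tissue standard deviation (one value for all classes/sequences);
#: realized as a smooth anatomical texture field, distinct from the additive
#: voxel noise whose SD defaults to the same scale.
DEFAULT_TISSUE_SD = 50.0


@dataclass
class PhantomSpec:
    """Geometry, contrast and degradation parameters of one phantom.

    ``lesion_contrast`` is the separation of the lesion mean from the WM mean
    in units of the WM standard deviation (positive on hyper sequences,
    applied with opposite sign on T1).
    """

    grid_shape: tuple = (96, 96, 64)
    spacing_mm: tuple = (1.0, 1.0, 2.0)
    sequences: tuple = ("FLAIR", "T1", "T2", "PD")
    brain_radii_mm: tuple = (44.0, 44.0, 60.0)
    ventricle_radii_mm: tuple = (8.0, 20.0, 10.0)
    ventricle_offset_mm: float = 11.0
    cortical_thickness_mm: float = 4.0
    intensity_means: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INTENSITY_MEANS.items()}
    )
    tissue_sd: float = DEFAULT_TISSUE_SD
    texture_sd: float = 5.0
    texture_scale_mm: float = 8.0
    lesion_count: int = 10
    lesion_radius_range_mm: tuple = (4.0, 11.0)
    lesion_contrast: float = 3.0
    bias_amplitude: float = 0.01
    bias_scale_mm: float = 24.0
    shared_bias: bool = False
    noise_sd: float = DEFAULT_TISSUE_SD
    noise_model: str = "gaussian"  # or "rician"
    boundary_blur_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ConfigError("grid_shape must be 3-D and at least 8 voxels per axis")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigError("spacing must be positive")
        for kind in self.sequences:
            if kind not in self.intensity_means:
                raise ConfigError(f"no intensity row for sequence {kind!r}")
        if self.lesion_count < 0:
            raise ConfigError("lesion_count must be >= 0")
        r0, r1 = self.lesion_radius_range_mm
        if not 0 < r0 <= r1:
            raise ConfigError("lesion radius range must satisfy 0 < lo <= hi")
        if self.noise_model not in ("gaussian", "rician"):
            raise ConfigError("noise_model must be 'gaussian' or 'rician'")
        if not 0 <= self.bias_amplitude < 1:
            raise ConfigError("bias_amplitude must be in [0, 1)")

    def lesion_mean(self, kind: str) -> float:
        wm = self.intensity_means[kind][WM]
        delta = self.lesion_contrast * self.tissue_sd
        return wm - delta if kind == "T1" else wm + delta

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing_mm
        return aff

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("grid_shape", "spacing_mm", "sequences", "brain_radii_mm",
                    "ventricle_radii_mm", "lesion_radius_range_mm"):
            d[key] = list(d[key])
        d["intensity_means"] = {
            k: {int(c): float(m) for c, m in row.items()}
            for k, row in self.intensity_means.items()
        }
        return d


def _physical_coords(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    idx = np.indices(spec.grid_shape, dtype=np.float64)
    return tuple(
        idx[a] * spec.spacing_mm[a] - (spec.grid_shape[a] - 1) * spec.spacing_mm[a] / 2.0
        for a in range(3)
    )


def _ellipsoid(coords, center, radii) -> np.ndarray:
    return sum(
        ((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, radii)
    ) <= 1.0


def _tissue_geometry(spec: PhantomSpec) -> np.ndarray:
    x, y, z = _physical_coords(spec)
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    brain = _ellipsoid((x, y, z), (0, 0, 0), spec.brain_radii_mm)
    inner_radii = tuple(
        max(r - spec.cortical_thickness_mm, 1.0) for r in spec.brain_radii_mm
    )
    inner = _ellipsoid((x, y, z), (0, 0, 0), inner_radii)
    labels[brain] = GM
    labels[inner] = WM
    for side in (-1.0, 1.0):
        vent = _ellipsoid(
            (x, y, z), (side * spec.ventricle_offset_mm, 0, 0), spec.ventricle_radii_mm
        )
        labels[vent & inner] = CSF

    # The emitted label map mimics an intensity-driven upstream segmenter:
    # partial-volume voxels at the WM interface (mixed signal) are assigned
    # to GM, as e.g. FSL FAST does, rather than to the geometric WM side.
    blur_sigma = np.asarray(spec.boundary_blur_mm) / np.asarray(spec.spacing_mm)
    w_wm = ndimage.gaussian_filter((labels == WM).astype(np.float64), sigma=blur_sigma)
    labels[(labels == WM) & (w_wm < 0.55)] = GM
    return labels


def _lesion_truth(spec: PhantomSpec, labels: np.ndarray) -> np.ndarray:
    """Union of random spheres with centers in WM, clipped to WM."""
    truth = np.zeros(spec.grid_shape, dtype=bool)
    if spec.lesion_count == 0:
        return truth
    rng = stage_rng(spec.seed, "lesions")
    wm_voxels = np.argwhere(labels == WM)
    if len(wm_voxels) == 0:
        raise InputError("phantom geometry has no WM; cannot place lesions")
    x, y, z = _physical_coords(spec)
    r0, r1 = spec.lesion_radius_range_mm
    centers = wm_voxels[rng.choice(len(wm_voxels), size=spec.lesion_count, replace=False)]
    radii = rng.uniform(r0, r1, size=spec.lesion_count)
    for (ci, cj, ck), r in zip(centers, radii):
        sphere = _ellipsoid((x, y, z), (x[ci, cj, ck], y[ci, cj, ck], z[ci, cj, ck]),
                            (r, r, r))
        truth |= sphere
    truth &= labels == WM
    wm_count = int((labels == WM).sum())
    if truth.sum() > 0.5 * wm_count:
        raise InputError("lesion load exceeds half of the WM compartment")
    return truth


def _smooth_field(
    spec: PhantomSpec, rng: np.random.Generator, scale_mm: float, brain: np.ndarray
) -> np.ndarray:
    """Smooth Gaussian random field, zero-mean and unit-SD over the brain."""
    noise = rng.standard_normal(spec.grid_shape)
    sigma = np.asarray(scale_mm) / np.asarray(spec.spacing_mm)
    fieldv = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
    fieldv -= fieldv[brain].mean()
    sd = fieldv[brain].std()
    if sd > 0:
        fieldv /= sd
    return fieldv


def _bias_field(spec: PhantomSpec, rng: np.random.Generator, brain: np.ndarray) -> np.ndarray:
    fieldv = _smooth_field(spec, rng, spec.bias_scale_mm, brain)
    peak = np.abs(fieldv[brain]).max()
    if peak > 0:
        fieldv = fieldv / peak
    return 1.0 + spec.bias_amplitude * fieldv


def generate_phantom(spec: PhantomSpec) -> tuple[Study, VoxelMask]:
    """Build a Study (requested sequences + exact tissue map) and truth mask.

    Fully reproducible from spec.seed: geometry is deterministic and every
    random stage (lesions, bias, per-sequence noise) draws from a named child
    stream of the seed.
    """
    labels = _tissue_geometry(spec)
    truth = _lesion_truth(spec, labels)
    brain = labels != BACKGROUND
    affine = spec.affine()
    blur_sigma = np.asarray(spec.boundary_blur_mm) / np.asarray(spec.spacing_mm)

    # partial-volume class weights: blurred indicators, renormalized in-brain
    weights = {}
    for cls in (CSF, GM, WM):
        w = ndimage.gaussian_filter((labels == cls).astype(np.float64), sigma=blur_sigma)
        weights[cls] = w
    wsum = sum(weights.values())
    wsum[wsum == 0] = 1.0
    lesion_w = ndimage.gaussian_filter(truth.astype(np.float64), sigma=blur_sigma)
    lesion_w = np.clip(lesion_w, 0.0, 1.0)

    shared_bias = None
    if spec.shared_bias and spec.bias_amplitude > 0:
        shared_bias = _bias_field(spec, stage_rng(spec.seed, "bias"), brain)

    # Smooth within-class anatomical texture, one field per tissue class,
    # shared across sequences with T1-opposite polarity: denser/more
    # myelinated tissue is brighter on T1 and darker on T2/FLAIR/PD.
    texture = {
        cls: _smooth_field(
            spec, stage_rng(spec.seed, f"texture:{cls}"), spec.texture_scale_mm, brain
        )
        for cls in (CSF, GM, WM)
    }

    volumes = {}
    for kind in spec.sequences:
        means = spec.intensity_means[kind]
        sign = 1.0 if kind == "T1" else -1.0
        class_img = {
            c: means[c] + sign * spec.texture_sd * texture[c] for c in (CSF, GM, WM)
        }
        tissue_mean = sum(weights[c] * class_img[c] for c in (CSF, GM, WM)) / wsum
        mean_img = (1.0 - lesion_w) * tissue_mean + lesion_w * spec.lesion_mean(kind)
        if spec.bias_amplitude > 0:
            bias = shared_bias if shared_bias is not None else _bias_field(
                spec, stage_rng(spec.seed, f"bias:{kind}"), brain
            )
            mean_img = mean_img * bias
        rng = stage_rng(spec.seed, f"noise:{kind}")
        if spec.noise_model == "rician":
            n1 = rng.standard_normal(spec.grid_shape) * spec.noise_sd
            n2 = rng.standard_normal(spec.grid_shape) * spec.noise_sd
            img = np.sqrt((mean_img + n1) ** 2 + n2**2)
        else:
            img = mean_img + rng.standard_normal(spec.grid_shape) * spec.noise_sd
        img[~brain] = 0.0
        volumes[kind] = SequenceVolume(affine=affine, data=img, kind=kind)

    study = Study(volumes=volumes, tissue=TissueMap(affine=affine, labels=labels))
    return study, VoxelMask(affine=affine, data=truth)


def degrade_tissue_map(tissue: TissueMap, flip_rate: float, seed: int) -> TissueMap:
    """Flip a fraction of GM/WM boundary labels, emulating an imperfect
    upstream tissue segmentation.

    Boundary voxels are GM voxels with a WM 6-neighbor or vice versa; exactly
    round(flip_rate * n_boundary) of them, chosen with the seeded generator,
    swap their label.
    """
    if not 0.0 <= flip_rate < 0.5:
        raise ConfigError(f"flip_rate must be in [0, 0.5), got {flip_rate}")
    out = tissue.copy()
    if flip_rate == 0.0:
        return out
    struct = ndimage.generate_binary_structure(3, 1)
    gm = tissue.labels == GM
    wm = tissue.labels == WM
    boundary = (gm & ndimage.binary_dilation(wm, structure=struct)) | (
        wm & ndimage.binary_dilation(gm, structure=struct)
    )
    coords = np.argwhere(boundary)
    n_flip = int(round(flip_rate * len(coords)))
    if n_flip == 0:
        return out
    rng = stage_rng(seed, "degrade-tissue")
    chosen = coords[rng.choice(len(coords), size=n_flip, replace=False)]
    cz, cy, cx = chosen[:, 0], chosen[:, 1], chosen[:, 2]
    current = out.labels[cz, cy, cx]
    out.labels[cz, cy, cx] = np.where(current == GM, WM, GM).astype(np.uint8)
    return out
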