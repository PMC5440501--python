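"""End-to-end orchestration of the four-step pipeline.

Steps per subject: tissue refinement -> evidently-normal mask -> confidence
map -> threshold. Every stage draws its randomness from a named child stream
of the single run seed, all stage outputs can be written to disk, and a
provenance record captures the configuration, seed, software version and
per-stage voxel counts so a run is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    RunConfig,
    Study,
    VoxelMask,
    normalize_intensities,
    read_mask,
    read_tissue_map,
    read_volume,
    write_mask,
    write_tissue_map,
    write_volume,
)
from .detect import ConfidenceMap, confidence_map, threshold_confidence
from .errors import InputError
from .evaluate import cross_combination_matrix
from .normal import evident_normal_mask, refine_tissue_map

log = logging.getLogger("cascade")

__all__ = ["SubjectResult", "RunManifest", "run_subject", "run_combination_study",
           "load_study", "content_hash"]


@dataclass
class SubjectResult:
    confidence: ConfidenceMap
    mask: VoxelMask
    normal: VoxelMask
    provenance: dict


@dataclass
class RunManifest:
    """Cohort run description: one entry per subject plus shared overrides."""

    subjects: list
    config: dict = field(default_factory=dict)
    output_dir: str = "cascade-out"

    def __post_init__(self) -> None:
        labels = [s.get("label") for s in self.subjects]
        if len(labels) != len(set(labels)):
            raise InputError("subject labels must be unique")
        for s in self.subjects:
            if not s.get("volumes"):
                raise InputError(f"subject {s.get('label')!r} lists no sequences")

    @classmethod
    def from_file(cls, path) -> "RunManifest":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            subjects=data.get("subjects", []),
            config=data.get("config", {}),
            output_dir=data.get("output_dir", "cascade-out"),
        )


def load_study(volume_paths: dict, tissue_path) -> Study:
    """Read a subject's co-registered volumes and tissue map from disk."""
    tissue = read_tissue_map(tissue_path)
    brain = tissue.brain_mask()
    volumes = {
        kind: read_volume(path, kind, brain=brain)
        for kind, path in volume_paths.items()
    }
    return Study(volumes=volumes, tissue=tissue)


def content_hash(study: Study, cfg: RunConfig) -> str:
    """Hash of all inputs and configuration, for cache keys and provenance."""
    h = hashlib.sha256()
    h.update(json.dumps(cfg.to_dict(), sort_keys=True).encode())
    h.update(np.ascontiguousarray(study.tissue.labels).tobytes())
    for kind in sorted(study.kinds):
        h.update(kind.encode())
        h.update(np.ascontiguousarray(study.volumes[kind].data).tobytes())
    return h.hexdigest()


def _stage(provenance: dict, name: str, started: float, **counts) -> None:
    elapsed = time.perf_counter() - started
    provenance["stages"].append({"stage": name, "seconds": round(elapsed, 3), **counts})
    log.info("stage %-18s %6.2fs %s", name, elapsed,
             " ".join(f"{k}={v}" for k, v in counts.items()))


def run_subject(
    study: Study,
    cfg: RunConfig,
    out_dir=None,
    normal_mask: VoxelMask | None = None,
) -> SubjectResult:
    """Run the full pipeline on one subject.

    An externally supplied evidently-normal mask (e.g. from a different
    normal-brain detector) overrides the built-in extraction.
    """
    provenance = {
        "version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "sequences": list(study.kinds),
        "stages": [],
    }
    brain = study.tissue.brain_mask()
    provenance["input_hash"] = content_hash(study, cfg)

    t0 = time.perf_counter()
    normalized = Study(
        volumes={k: normalize_intensities(v, brain) for k, v in study.volumes.items()},
        tissue=study.tissue,
        reference_kind=study.reference_kind,
    )
    _stage(provenance, "normalize", t0, brain_voxels=brain.count())

    t0 = time.perf_counter()
    refined = refine_tissue_map(study.tissue, normalized)
    changed = int((refined.labels != study.tissue.labels).sum())
    normalized = Study(
        volumes=normalized.volumes, tissue=refined,
        reference_kind=normalized.reference_kind,
    )
    _stage(provenance, "refine-tissue", t0, relabeled=changed)

    t0 = time.perf_counter()
    if normal_mask is None:
        normal = evident_normal_mask(normalized, cfg)
    else:
        normal = normal_mask
    _stage(provenance, "normal-mask", t0, normal_voxels=normal.count())

    t0 = time.perf_counter()
    cm = confidence_map(normalized, normal, cfg)
    _stage(provenance, "confidence-map", t0, tested_voxels=int(cm.tested.sum()))

    t0 = time.perf_counter()
    mask = threshold_confidence(cm, cfg.alpha)
    _stage(provenance, "threshold", t0, lesion_voxels=mask.count())

    result = SubjectResult(confidence=cm, mask=mask, normal=normal,
                           provenance=provenance)
    if out_dir is not None:
        _write_outputs(result, refined, out_dir)
    return result


def _write_outputs(result: SubjectResult, refined_tissue, out_dir) -> None:
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm = result.confidence
    nib.save(nib.Nifti1Image(cm.values.astype(np.float32), cm.affine),
             str(out / "confidence.nii.gz"))
    write_mask(result.mask, out / "wmh_mask.nii.gz")
    write_mask(result.normal, out / "normal_mask.nii.gz")
    write_tissue_map(refined_tissue, out / "tissue_refined.nii.gz")
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2))


def run_combination_study(
    study: Study, cfg: RunConfig, out_dir=None, cache_dir=None
) -> pd.DataFrame:
    """Segment every non-empty subset of the provided sequences and return
    the cross-combination Dice matrix (15 subsets for four sequences).

    Masks are cached on disk keyed by a content hash of inputs+config when a
    cache directory is given, so re-runs are cheap.
    """
    kinds = sorted(study.kinds)
    if len(kinds) < 2:
        raise InputError("combination study needs at least two sequences")
    masks = {}
    for r in range(1, len(kinds) + 1):
        for subset in combinations(kinds, r):
            label = "+".join(subset)
            sub = study.subset(subset)
            cached = None
            if cache_dir is not None:
                key = content_hash(sub, cfg)
                cache_path = Path(cache_dir) / f"{key}.nii.gz"
                if cache_path.exists():
                    cached = read_mask(cache_path)
            if cached is not None:
                masks[label] = cached
                log.info("combination %-16s (cached)", label)
                continue
            log.info("combination %-16s", label)
            res = run_subject(sub, cfg)
            masks[label] = res.mask
            if cache_dir is not None:
                Path(cache_dir).mkdir(parents=True, exist_ok=True)
                write_mask(res.mask, cache_path)
            if out_dir is not None:
                Path(out_dir).mkdir(parents=True, exist_ok=True)
                write_mask(res.mask, Path(out_dir) / f"wmh_{label.replace('+', '_')}.nii.gz")
    matrix = cross_combination_matrix(masks)
    if out_dir is not None:
        matrix.to_csv(Path(out_dir) / "cross_dice.csv")
    return matrix
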