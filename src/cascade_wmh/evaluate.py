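"""Segmentation agreement metrics: Dice, FNR/FDR, volumes, correlations.

Conventions for empty masks (never produced by the clinical workflow but
possible on phantoms and in cohort tables): Dice of two empty masks is 1;
an empty test mask has FDR 0; an empty reference mask has FNR 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import VoxelMask, require_same_grid
from .errors import DegenerateVolumeError, InputError

__all__ = [
    "ComparisonReport",
    "dice",
    "error_rates",
    "mask_volume_cc",
    "compare_masks",
    "cohort_volume_correlation",
    "cross_combination_matrix",
]


@dataclass
class ComparisonReport:
    """Agreement summary for a (reference, test) mask pair."""

    dice: float
    fnr: float
    fdr: float
    volume_ref_cc: float
    volume_test_cc: float

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "fnr": self.fnr,
            "fdr": self.fdr,
            "volume_ref_cc": self.volume_ref_cc,
            "volume_test_cc": self.volume_test_cc,
        }


def dice(s1: VoxelMask, s2: VoxelMask) -> float:
    """2 |S1 and S2| / (|S1| + |S2|); 1.0 when both masks are empty."""
    require_same_grid(s1, s2)
    n1, n2 = s1.count(), s2.count()
    if n1 + n2 == 0:
        return 1.0
    inter = int((s1.data & s2.data).sum())
    return 2.0 * inter / (n1 + n2)


def error_rates(reference: VoxelMask, test: VoxelMask) -> tuple[float, float]:
    """(FNR, FDR) with the reference mask as truth.

    FNR = FN / (FN + TP), FDR = FP / (FP + TP); an empty test mask gives
    FNR 1 (when the reference is non-empty) and FDR 0, an empty reference
    gives FNR 0.
    """
    require_same_grid(reference, test)
    tp = int((reference.data & test.data).sum())
    fn = int((reference.data & ~test.data).sum())
    fp = int((~reference.data & test.data).sum())
    fnr = 0.0 if fn + tp == 0 else fn / (fn + tp)
    fdr = 0.0 if fp + tp == 0 else fp / (fp + tp)
    return fnr, fdr


def mask_volume_cc(mask: VoxelMask) -> float:
    """Voxel count times voxel volume, in cubic centimetres."""
    voxel_mm3 = float(np.prod(mask.spacing))
    return mask.count() * voxel_mm3 / 1000.0


def compare_masks(reference: VoxelMask, test: VoxelMask) -> ComparisonReport:
    fnr, fdr = error_rates(reference, test)
    return ComparisonReport(
        dice=dice(reference, test),
        fnr=fnr,
        fdr=fdr,
        volume_ref_cc=mask_volume_cc(reference),
        volume_test_cc=mask_volume_cc(test),
    )


def cohort_volume_correlation(pairs) -> float:
    """Pearson r between reference and test volumes across subjects."""
    pairs = np.asarray(pairs, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 3:
        raise InputError("need >= 3 (ref_cc, test_cc) pairs")
    ref, test = pairs[:, 0], pairs[:, 1]
    if np.var(ref) == 0 or np.var(test) == 0:
        raise DegenerateVolumeError("volume correlation undefined: zero variance")
    return float(np.corrcoef(ref, test)[0, 1])


def cross_combination_matrix(masks: dict) -> pd.DataFrame:
    """Symmetric Dice matrix across sequence-combination labels.

    Entry (a, b) is the Dice coefficient of the two labeled masks; the
    diagonal is 1 by definition.
    """
    if len(masks) < 2:
        raise InputError("need at least two labeled masks")
    labels = list(masks)
    out = np.eye(len(labels))
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            out[i, j] = out[j, i] = dice(masks[a], masks[labels[j]])
    return pd.DataFrame(out, index=labels, columns=labels)
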