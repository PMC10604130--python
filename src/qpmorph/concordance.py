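"""Classification concordance between modalities and against a-priori grading.

Note the positive class: this validation asks how well the stain-free
modality *detects abnormal cells*, so sensitivity is the fraction of
reference-abnormal cells also called abnormal by qpm — the inverse of
the usual "normal = positive" diagnostic convention.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError


def _as_abnormal_bool(classes: Sequence) -> np.ndarray:
    arr = np.asarray(classes)
    if arr.dtype == bool:
        return arr
    out = np.empty(len(arr), dtype=bool)
    for i, v in enumerate(arr):
        if v not in ("normal", "abnormal"):
            raise ValueError(f"class labels must be 'normal'/'abnormal', got {v!r}")
        out[i] = v == "abnormal"
    return out


@dataclass
class ConcordanceResult:
    """2x2 agreement of per-cell normal/abnormal calls (positive = abnormal).

    ``both_abnormal`` = TP, ``both_normal`` = TN,
    ``qpm_normal_ref_abnormal`` = FN (a missed abnormal),
    ``qpm_abnormal_ref_normal`` = FP.
    """

    n: int
    both_normal: int
    both_abnormal: int
    qpm_normal_ref_abnormal: int
    qpm_abnormal_ref_normal: int
    sensitivity: float             # percent
    accuracy: float                # percent
    subgroup: str = "all"

    def __post_init__(self):
        total = (
            self.both_normal
            + self.both_abnormal
            + self.qpm_normal_ref_abnormal
            + self.qpm_abnormal_ref_normal
        )
        if total != self.n:
            raise ValueError("confusion counts do not sum to n")

    def to_dict(self) -> dict:
        return {
            "subgroup": self.subgroup,
            "n": self.n,
            "both_normal": self.both_normal,
            "both_abnormal": self.both_abnormal,
            "qpm_normal_ref_abnormal": self.qpm_normal_ref_abnormal,
            "qpm_abnormal_ref_normal": self.qpm_abnormal_ref_normal,
            "sensitivity_pct": self.sensitivity,
            "accuracy_pct": self.accuracy,
        }


def concordance_summary(
    qpm_classes: Sequence,
    ref_classes: Sequence,
    subgroup_mask: Optional[Sequence[bool]] = None,
    subgroup: str = "all",
) -> ConcordanceResult:
    """Confusion counts, sensitivity and accuracy of qpm vs reference calls.

    sensitivity = 100 * TP / (TP + FN) with abnormal as the positive
    class; accuracy = 100 * (TP + TN) / n.  ``subgroup_mask`` restricts
    the analysis (e.g. to a-priori-normal cells).
    """
    qpm = _as_abnormal_bool(qpm_classes)
    ref = _as_abnormal_bool(ref_classes)
    if len(qpm) != len(ref):
        raise ValueError("class vectors must have equal length")
    if subgroup_mask is not None:
        mask = np.asarray(subgroup_mask, dtype=bool)
        if len(mask) != len(qpm):
            raise ValueError("subgroup mask length mismatch")
        qpm, ref = qpm[mask], ref[mask]
    n = len(qpm)
    if n == 0:
        raise InsufficientDataError("no cells in subgroup")
    tp = int((qpm & ref).sum())
    tn = int((~qpm & ~ref).sum())
    fn = int((~qpm & ref).sum())
    fp = int((qpm & ~ref).sum())
    if tp + fn == 0:
        raise InsufficientDataError("no reference-abnormal cells; sensitivity undefined")
    return ConcordanceResult(
        n=n,
        both_normal=tn,
        both_abnormal=tp,
        qpm_normal_ref_abnormal=fn,
        qpm_abnormal_ref_normal=fp,
        sensitivity=100.0 * tp / (tp + fn),
        accuracy=100.0 * (tp + tn) / n,
        subgroup=subgroup,
    )


@dataclass
class ConversionResult:
    """How many a-priori-normal cells a modality confirms as normal."""

    n_a_priori_normal: int
    n_confirmed_normal: int
    pct: float                     # raw percent
    pct_rounded: int               # nearest integer, as reported

    def to_dict(self) -> dict:
        return {
            "n_a_priori_normal": self.n_a_priori_normal,
            "n_confirmed_normal": self.n_confirmed_normal,
            "pct": self.pct,
            "pct_rounded": self.pct_rounded,
        }


def a_priori_conversion(
    a_priori_classes: Sequence, modality_classes: Sequence
) -> ConversionResult:
    """Share of a-priori-normal cells the measured classification confirms.

    Reported rounded to the nearest integer percent.
    """
    apriori = np.asarray(a_priori_classes)
    measured = _as_abnormal_bool(modality_classes)
    if len(apriori) != len(measured):
        raise ValueError("vectors must have equal length")
    normal_mask = apriori == "normal"
    n_normal = int(normal_mask.sum())
    if n_normal == 0:
        raise InsufficientDataError("no a-priori-normal cells")
    confirmed = int((~measured[normal_mask]).sum())
    pct = 100.0 * confirmed / n_normal
    return ConversionResult(
        n_a_priori_normal=n_normal,
        n_confirmed_normal=confirmed,
        pct=pct,
        pct_rounded=int(round(pct)),
    )
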