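"""Exclusion gating and per-modality tally, in the style of a study's
"reasons for exclusion" table.

A record is excluded if its exclusion flag is already set (movement and
flatness are upstream human/video judgements, carried as input flags) or
if a computed gate fires (focus score below threshold; within-head
contrast below the floor).  When several reasons could apply, the first
in the fixed order movement -> focus -> borders -> flatness wins, because
movement is assessed before imaging in the acquisition workflow.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import pandas as pd

from .records import MODALITIES, as_frame

#: Gate precedence (first firing reason wins); "no_cell" last — it can only
#: arise after every other gate has passed.
REASON_ORDER = ("insufficient_movement", "inadequate_focus", "unclear_borders", "not_flat", "no_cell")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal-style half-up rounding (0.05 -> 0.1 at one digit)."""
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass
class GateConfig:
    """Computed gates applied on top of input flags (used when records carry
    focus scores, i.e. came from image measurement)."""

    focus_threshold: Optional[float] = None


@dataclass
class ModalityTally:
    """Exclusion bookkeeping for one modality."""

    modality: str
    total: int
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def excluded(self) -> int:
        return sum(self.counts.values())

    @property
    def excluded_pct(self) -> float:
        return round_half_up(100.0 * self.excluded / self.total, 1)

    def pct(self, reason: str) -> float:
        return round_half_up(100.0 * self.counts.get(reason, 0) / self.total, 1)

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "total": self.total,
            "excluded": self.excluded,
            "excluded_pct": self.excluded_pct,
            "reasons": {
                r: {"count": self.counts[r], "pct": self.pct(r)}
                for r in REASON_ORDER
                if r in self.counts
            },
        }


@dataclass
class ExclusionReport:
    per_modality: Dict[str, ModalityTally]

    def to_dict(self) -> dict:
        return {m: t.to_dict() for m, t in self.per_modality.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, tally in self.per_modality.items():
            for reason in REASON_ORDER:
                if reason in tally.counts:
                    rows.append(
                        {
                            "modality": m,
                            "reason": reason,
                            "count": tally.counts[reason],
                            "pct": tally.pct(reason),
                        }
                    )
            rows.append(
                {
                    "modality": m,
                    "reason": "total_excluded",
                    "count": tally.excluded,
                    "pct": tally.excluded_pct,
                }
            )
        return pd.DataFrame(rows, columns=["modality", "reason", "count", "pct"])


def _effective_reason(row, gates: Optional[GateConfig]) -> str:
    candidates = set()
    flag = row.get("exclusion_reason", "none")
    if isinstance(flag, str) and flag != "none":
        candidates.add(flag)
    if gates is not None and gates.focus_threshold is not None:
        score = row.get("focus_score", float("nan"))
        if isinstance(score, (int, float)) and not math.isnan(score):
            if score < gates.focus_threshold:
                candidates.add("inadequate_focus")
    if not candidates:
        return "none"
    for reason in REASON_ORDER:
        if reason in candidates:
            return reason
    return "none"


def apply_exclusions(
    records, gates: Optional[GateConfig] = None
) -> Tuple[pd.DataFrame, ExclusionReport]:
    """Partition records into (kept, excluded) and tally reasons per modality.

    Returns the kept records (exclusion_reason forced to "none" stays as
    is) and the :class:`ExclusionReport`; kept + excluded partition the
    input exactly.
    """
    df = as_frame(records)
    if df.empty:
        raise ValueError("empty record list")
    reasons = df.apply(lambda row: _effective_reason(row, gates), axis=1)
    tallies = {}
    for modality in MODALITIES:
        sub = reasons[df["modality"] == modality]
        if len(sub) == 0:
            continue
        counts = {
            r: int((sub == r).sum()) for r in REASON_ORDER if int((sub == r).sum()) > 0
        }
        tallies[modality] = ModalityTally(modality=modality, total=len(sub), counts=counts)
    kept = df[reasons == "none"].copy()
    return kept, ExclusionReport(per_modality=tallies)
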