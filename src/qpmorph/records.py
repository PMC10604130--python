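"""The pipeline's atomic row: one measurement of one cell by one modality/replicate."""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, List

import pandas as pd

#: Measurement modalities: stain-free quantitative phase vs stained bright-field reference.
MODALITIES = ("qpm", "reference")

#: Exclusion reasons, in gate-precedence order (movement is assessed before
#: imaging, so it fires first); "no_cell" is the distinct unmeasurable case
#: where segmentation finds nothing.
EXCLUSION_REASONS = (
    "insufficient_movement",
    "inadequate_focus",
    "unclear_borders",
    "not_flat",
    "no_cell",
)

#: Canonical CSV schema for measurement tables.
CSV_COLUMNS = [
    "subject_id",
    "cell_id",
    "modality",
    "replicate",
    "head_length_um",
    "head_width_um",
    "lw_ratio",
    "acrosome_pct",
    "a_priori_class",
    "exclusion_reason",
    "truncated_flag",
]


@dataclass
class MorphometryRecord:
    """One measurement of one cell by one modality and replicate.

    Excluded records (``exclusion_reason != "none"``) carry NaN endpoints;
    measured records satisfy ``lw_ratio == head_length_um / head_width_um``
    to 1e-9 relative.
    """

    subject_id: str
    cell_id: str
    modality: str
    replicate: int
    head_length_um: float = float("nan")
    head_width_um: float = float("nan")
    lw_ratio: float = float("nan")
    acrosome_pct: float = float("nan")
    a_priori_class: str = "unknown"
    exclusion_reason: str = "none"
    truncated_flag: bool = False
    focus_score: float = field(default=float("nan"), compare=False)

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")
        if self.exclusion_reason != "none" and self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.is_measured:
            rel = abs(self.lw_ratio - self.head_length_um / self.head_width_um)
            rel /= max(abs(self.lw_ratio), 1e-300)
            if rel > 1e-9:
                raise ValueError("lw_ratio inconsistent with head_length/head_width")
            if not 0.0 <= self.acrosome_pct <= 100.0:
                raise ValueError("acrosome_pct outside [0, 100]")

    @property
    def is_measured(self) -> bool:
        return self.exclusion_reason == "none" and not math.isnan(self.head_length_um)


def records_to_frame(records: Iterable[MorphometryRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame in the canonical column order."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=CSV_COLUMNS + ["focus_score"])
    return df[CSV_COLUMNS + ["focus_score"]]


def frame_to_records(df: pd.DataFrame) -> List[MorphometryRecord]:
    out = []
    for row in df.to_dict("records"):
        kwargs = {k: row[k] for k in CSV_COLUMNS}
        if "focus_score" in row and not pd.isna(row["focus_score"]):
            kwargs["focus_score"] = float(row["focus_score"])
        kwargs["replicate"] = int(kwargs["replicate"])
        kwargs["truncated_flag"] = bool(kwargs["truncated_flag"])
        out.append(MorphometryRecord(**kwargs))
    return out


def as_frame(records) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of records; return a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))
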