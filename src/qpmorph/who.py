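"""WHO2021 strict-criteria classification of sperm head morphometry.

The 2021 WHO laboratory manual publishes normal ranges for four head
endpoints: head length (3.7-4.7 um), head width (2.5-3.2 um),
length-to-width ratio (1.3-1.8) and acrosome-area-to-head-area ratio
(40-70%).  A cell is *normal* iff every endpoint lies inside its range.

Bounds are compared inclusively by default: reported population
characteristic values (e.g. 4.7 um length, 3.2 um width) sit exactly on
the upper bounds, and only an inclusive reading lets such cells be
compliant.  The switch is exposed for sensitivity analyses.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import math

from .errors import ConfigurationError, UnclassifiableError

#: Canonical endpoint column names, in reporting order.
ENDPOINTS = ("head_length_um", "head_width_um", "lw_ratio", "acrosome_pct")

#: Human-readable units per endpoint.
ENDPOINT_UNITS = {
    "head_length_um": "um",
    "head_width_um": "um",
    "lw_ratio": "",
    "acrosome_pct": "%",
}


@dataclass(frozen=True)
class EndpointRange:
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"endpoint range requires lower < upper, got ({self.lower}, {self.upper})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float, inclusive: bool = True) -> bool:
        if math.isnan(value):
            return False
        if inclusive:
            return self.lower <= value <= self.upper
        return self.lower < value < self.upper


def _default_ranges() -> dict:
    # WHO2021 strict normal ranges for the four head endpoints.
    return {
        "head_length_um": EndpointRange(3.7, 4.7),
        "head_width_um": EndpointRange(2.5, 3.2),
        "lw_ratio": EndpointRange(1.3, 1.8),
        "acrosome_pct": EndpointRange(40.0, 70.0),
    }


@dataclass(frozen=True)
class WHORanges:
    """Normal ranges for the four endpoints (default: WHO2021)."""

    ranges: Mapping[str, EndpointRange] = field(default_factory=_default_ranges)

    def __post_init__(self):
        missing = [e for e in ENDPOINTS if e not in self.ranges]
        if missing:
            raise ConfigurationError(f"missing ranges for endpoints: {missing}")

    def __getitem__(self, endpoint: str) -> EndpointRange:
        return self.ranges[endpoint]

    def to_dict(self) -> dict:
        return {e: [self.ranges[e].lower, self.ranges[e].upper] for e in ENDPOINTS}

    @classmethod
    def from_dict(cls, d: Mapping[str, tuple]) -> "WHORanges":
        return cls({k: EndpointRange(float(lo), float(hi)) for k, (lo, hi) in d.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "WHORanges":
        """Load ranges from a JSON file mapping endpoint -> [lower, upper]."""
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ClassificationResult:
    """Per-endpoint compliance flags and the overall call.

    ``overall`` is ``"normal"`` iff all four flags are True.
    """

    flags: Mapping[str, bool]
    overall: str

    def __post_init__(self):
        expected = "normal" if all(self.flags[e] for e in ENDPOINTS) else "abnormal"
        if self.overall != expected:
            raise ConfigurationError("overall class inconsistent with endpoint flags")


def classify_values(
    values: Mapping[str, float],
    ranges: WHORanges | None = None,
    inclusive: bool = True,
) -> ClassificationResult:
    """Classify a complete set of four endpoint values.

    Raises
    ------
    UnclassifiableError
        if any endpoint is missing or NaN.
    """
    ranges = ranges or WHORanges()
    flags = {}
    for endpoint in ENDPOINTS:
        if endpoint not in values or math.isnan(float(values[endpoint])):
            raise UnclassifiableError(f"endpoint '{endpoint}' missing or NaN")
        flags[endpoint] = ranges[endpoint].contains(float(values[endpoint]), inclusive)
    overall = "normal" if all(flags.values()) else "abnormal"
    return ClassificationResult(flags=flags, overall=overall)


def classify_cell(record, ranges: WHORanges | None = None, inclusive: bool = True) -> ClassificationResult:
    """Classify one measurement record (``MorphometryRecord`` or mapping).

    Excluded records are refused: an excluded cell carries no endpoint
    obligations and must not be silently classified.
    """
    get = record.get if isinstance(record, Mapping) else lambda k, d=None: getattr(record, k, d)
    reason = get("exclusion_reason", "none")
    if reason not in (None, "none", ""):
        raise UnclassifiableError(f"record excluded ({reason}); cannot classify")
    values = {e: get(e, float("nan")) for e in ENDPOINTS}
    return classify_values(values, ranges, inclusive)


def classify_frame(df, ranges: WHORanges | None = None, inclusive: bool = True):
    """Vectorised classification of a measurement table.

    Returns a copy of ``df`` with one boolean compliance column per
    endpoint (``<endpoint>_ok``) and a ``who_class`` column; rows that are
    excluded or incomplete get ``who_class = 'unclassifiable'``.
    """
    import numpy as np

    ranges = ranges or WHORanges()
    out = df.copy()
    eligible = np.ones(len(df), dtype=bool)
    if "exclusion_reason" in df.columns:
        eligible &= df["exclusion_reason"].fillna("none").eq("none").to_numpy()
    all_ok = np.ones(len(df), dtype=bool)
    for endpoint in ENDPOINTS:
        vals = df[endpoint].to_numpy(dtype=float)
        rng = ranges[endpoint]
        if inclusive:
            ok = (vals >= rng.lower) & (vals <= rng.upper)
        else:
            ok = (vals > rng.lower) & (vals < rng.upper)
        eligible &= ~np.isnan(vals)
        all_ok &= ok
        out[f"{endpoint}_ok"] = ok
    out["who_class"] = np.where(eligible, np.where(all_ok, "normal", "abnormal"), "unclassifiable")
    return out
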