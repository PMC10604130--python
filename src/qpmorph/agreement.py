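"""Bland-Altman agreement with maximum allowed limits, and two-interval
repeatability, per endpoint.

The agreement between the stain-free (qpm) and stained-reference
measurements of each endpoint is summarised Bland-Altman style on
per-cell differences d_i = qpm_mean_i - reference_mean_i (each side
averaged over its replicates first):

    bias = mean(d),  sd = SD(d, n-1),  LoA = bias +/- 1.96 * sd

On top of the LoA the study draws *maximum allowed limits*: an extra
tolerance band of half-width

    AL = sqrt(ref_repeat_sd^2 + 0.1 * sd^2)

built from the reference method's repeatability SD and the agreement SD
(0.1 down-weights the agreement variance).  The outer limits are
LoA -/+ AL.  Two alternate readings of the AL expression are selectable
(``variant``), since the printed formula is ambiguous.

Repeatability of one modality is the same construction on per-cell
replicate-1 minus replicate-2 differences; modalities are compared by
the ratio of their repeatability SDs with a bootstrap percentile
interval (the study asserts a significant difference without naming a
test; an interval excluding 1 is the criterion here).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedRatioError
from .records import as_frame
from .who import ENDPOINTS

Z95 = 1.96  # normal quantile the study uses for its 95% bands

AL_VARIANTS = ("rss_downweighted", "rss_scaled", "linear")


@dataclass
class DifferenceSet:
    """Per-cell differences for one endpoint, with bookkeeping."""

    endpoint: str
    mode: str                      # between_modalities | within_modality
    values: np.ndarray
    cell_ids: list
    n_dropped: int = 0             # cells missing one side
    modality: Optional[str] = None

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class AgreementResult:
    """Bland-Altman summary of one endpoint's between-modality differences."""

    endpoint: str
    n: int
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    al: Optional[float] = None
    outer_lower: Optional[float] = None
    outer_upper: Optional[float] = None
    differences: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)

    def to_dict(self) -> dict:
        d = {
            "endpoint": self.endpoint,
            "n": self.n,
            "bias": self.bias,
            "sd": self.sd,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
        }
        if self.al is not None:
            d.update(al=self.al, outer_lower=self.outer_lower, outer_upper=self.outer_upper)
        return d


@dataclass
class RepeatabilityResult:
    """Bland-Altman summary of one modality's replicate-1 - replicate-2 differences."""

    endpoint: str
    modality: str
    n: int
    bias: float
    sd: float
    ci_lower: float
    ci_upper: float
    differences: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "modality": self.modality,
            "n": self.n,
            "bias": self.bias,
            "sd": self.sd,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
        }


def _measured(df: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    ok = df["exclusion_reason"].fillna("none").eq("none") & df[endpoint].notna()
    return df[ok]


def per_cell_differences(
    records,
    endpoint: str,
    mode: str = "between_modalities",
    modality: Optional[str] = None,
) -> DifferenceSet:
    """One difference per eligible cell.

    ``between_modalities``: average each cell's replicates within each
    modality, then qpm_mean - reference_mean; cells missing either side
    are dropped and counted.  ``within_modality``: replicate 1 minus
    replicate 2 (first two replicates by index) for the given modality.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    df = _measured(as_frame(records), endpoint)
    if mode == "between_modalities":
        means = df.groupby(["cell_id", "modality"], sort=True)[endpoint].mean().unstack()
        for col in ("qpm", "reference"):
            if col not in means.columns:
                means[col] = np.nan
        eligible = means.dropna(subset=["qpm", "reference"])
        dropped = len(means) - len(eligible)
        diffs = (eligible["qpm"] - eligible["reference"]).to_numpy()
        cells = list(eligible.index)
    elif mode == "within_modality":
        if modality is None:
            raise ValueError("within_modality mode requires a modality")
        sub = df[df["modality"] == modality].sort_values(["cell_id", "replicate"])
        dropped = 0
        diffs_list, cells = [], []
        for cell_id, grp in sub.groupby("cell_id", sort=True):
            if len(grp) < 2:
                dropped += 1
                continue
            first_two = grp.head(2)[endpoint].to_numpy()
            diffs_list.append(first_two[0] - first_two[1])
            cells.append(cell_id)
        diffs = np.asarray(diffs_list, dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(diffs) == 0:
        raise InsufficientDataError(f"no eligible cells for endpoint {endpoint!r} ({mode})")
    return DifferenceSet(
        endpoint=endpoint,
        mode=mode,
        values=diffs,
        cell_ids=cells,
        n_dropped=int(dropped),
        modality=modality,
    )


def bland_altman(differences: Sequence[float] | DifferenceSet, endpoint: str = "") -> AgreementResult:
    """Bias, SD (n-1 denominator) and 95% limits of agreement.

    Requires at least two differences.
    """
    if isinstance(differences, DifferenceSet):
        endpoint = endpoint or differences.endpoint
        values = differences.values
    else:
        values = np.asarray(list(differences), dtype=float)
    if len(values) < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 differences")
    bias = float(values.mean())
    sd = float(values.std(ddof=1))
    return AgreementResult(
        endpoint=endpoint,
        n=len(values),
        bias=bias,
        sd=sd,
        loa_lower=bias - Z95 * sd,
        loa_upper=bias + Z95 * sd,
        differences=values,
    )


def max_allowed_limit(
    reference_repeat_sd: float, agreement_sd: float, variant: str = "rss_downweighted"
) -> float:
    """Half-width of the maximum-allowed-limit band.

    variants: ``rss_downweighted`` (default) sqrt(r^2 + 0.1*a^2);
    ``rss_scaled`` sqrt(r^2 + (0.1*a)^2); ``linear`` r + 0.1*a.
    Monotone nondecreasing in both arguments for every variant.
    """
    if reference_repeat_sd < 0 or agreement_sd < 0:
        raise ValueError("SDs must be >= 0")
    r, a = reference_repeat_sd, agreement_sd
    if variant == "rss_downweighted":
        return math.sqrt(r * r + 0.1 * a * a)
    if variant == "rss_scaled":
        return math.sqrt(r * r + (0.1 * a) ** 2)
    if variant == "linear":
        return r + 0.1 * a
    raise ValueError(f"unknown AL variant {variant!r}; choose from {AL_VARIANTS}")


def with_allowed_limit(
    result: AgreementResult, reference_repeat_sd: float, variant: str = "rss_downweighted"
) -> AgreementResult:
    """Attach the AL band and outer limits to an agreement result."""
    al = max_allowed_limit(reference_repeat_sd, result.sd, variant)
    return AgreementResult(
        endpoint=result.endpoint,
        n=result.n,
        bias=result.bias,
        sd=result.sd,
        loa_lower=result.loa_lower,
        loa_upper=result.loa_upper,
        al=al,
        outer_lower=result.loa_lower - al,
        outer_upper=result.loa_upper + al,
        differences=result.differences,
    )


def repeatability_summary(records, endpoint: str, modality: str) -> RepeatabilityResult:
    """Two-interval repeatability of one endpoint in one modality."""
    diffs = per_cell_differences(records, endpoint, mode="within_modality", modality=modality)
    if diffs.n < 2:
        raise InsufficientDataError("repeatability needs at least 2 cells with 2 replicates")
    ba = bland_altman(diffs)
    return RepeatabilityResult(
        endpoint=endpoint,
        modality=modality,
        n=ba.n,
        bias=ba.bias,
        sd=ba.sd,
        ci_lower=ba.loa_lower,
        ci_upper=ba.loa_upper,
        differences=ba.differences,
    )


@dataclass
class SdRatioResult:
    """Ratio of two repeatability SDs with a bootstrap percentile interval."""

    ratio: float
    ci_lower: float
    ci_upper: float
    significant: bool              # interval excludes 1
    bootstrap_reps: int


def compare_repeatability(
    result_a: RepeatabilityResult,
    result_b: RepeatabilityResult,
    bootstrap_reps: int = 2000,
    seed: int = 0,
) -> SdRatioResult:
    """sd_a / sd_b with a 95% bootstrap percentile interval.

    Each difference vector is resampled with replacement independently;
    'significantly different' iff the interval excludes 1.
    """
    if bootstrap_reps < 200:
        raise ValueError("bootstrap_reps must be >= 200")
    a, b = np.asarray(result_a.differences), np.asarray(result_b.differences)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("both difference vectors need n >= 2")
    sd_b = b.std(ddof=1)
    if sd_b == 0:
        raise UndefinedRatioError("denominator repeatability SD is zero")
    ratio = float(a.std(ddof=1) / sd_b)
    rng = np.random.default_rng(seed)
    ratios = np.empty(bootstrap_reps)
    for i in range(bootstrap_reps):
        ra = rng.choice(a, size=len(a), replace=True)
        rb = rng.choice(b, size=len(b), replace=True)
        denom = rb.std(ddof=1)
        ratios[i] = ra.std(ddof=1) / denom if denom > 0 else np.inf
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return SdRatioResult(
        ratio=ratio,
        ci_lower=float(lo),
        ci_upper=float(hi),
        significant=bool(hi < 1.0 or lo > 1.0),
        bootstrap_reps=bootstrap_reps,
    )


def characteristic_values(records) -> Dict[str, float]:
    """Cohort characteristic value per endpoint: the median over cells of the
    mean of the two modality means (cells measured by both modalities)."""
    df = as_frame(records)
    out = {}
    for endpoint in ENDPOINTS:
        sub = _measured(df, endpoint)
        means = sub.groupby(["cell_id", "modality"], sort=True)[endpoint].mean().unstack()
        if "qpm" not in means.columns or "reference" not in means.columns:
            raise InsufficientDataError("need both modalities for characteristic values")
        both = means.dropna(subset=["qpm", "reference"])
        if both.empty:
            raise InsufficientDataError("no cell measured by both modalities")
        out[endpoint] = float(((both["qpm"] + both["reference"]) / 2.0).median())
    return out


def bland_altman_plot_data(records, endpoint: str) -> pd.DataFrame:
    """Per-cell (mean, difference) pairs for a Bland-Altman plot, exported
    as a plain table so any plotting front-end can draw it."""
    df = _measured(as_frame(records), endpoint)
    means = df.groupby(["cell_id", "modality"], sort=True)[endpoint].mean().unstack()
    both = means.dropna(subset=["qpm", "reference"])
    return pd.DataFrame(
        {
            "cell_id": both.index,
            "mean": ((both["qpm"] + both["reference"]) / 2.0).to_numpy(),
            "difference": (both["qpm"] - both["reference"]).to_numpy(),
        }
    )
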