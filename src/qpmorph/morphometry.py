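"""Stain-free measurement of the four WHO2021 head endpoints from a phase image.

The measurement chain is deliberately parameter-light:

* foreground by Otsu's between-class-variance-maximising global threshold
  on the phase values, morphological opening to detach/remove the tail,
  then the largest connected component above an area floor is the head;
* head axes from the second-order central moments of the head mask —
  length = 4*sqrt(lambda_major), width = 4*sqrt(lambda_minor) of the
  covariance eigenvalues, which is exact for a solid ellipse;
* the acrosome by a second Otsu split of the phase values *within* the
  head: the acrosomal cap has lower optical-path density than the
  nucleus, so the lower-mean-density compartment is taken as the
  acrosome (the anterior-pole convention when no tail is available);
* a focus score (normalised Laplacian variance) gates blurry images
  before any measurement is attempted.

Coordinates are a row/column pixel grid, origin top-left, 0-based;
lengths are always reported in um.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk, opening

from .errors import LowContrastError, NoCellDetectedError
from .records import MorphometryRecord
from .synth import PhaseImage, SpermGroundTruth, render_phase_image


@dataclass
class MeasurementConfig:
    """Tunable parameters of the measurement chain.

    ``focus_threshold=None`` means "calibrate": the gate threshold is the
    focus score of a canonical noiseless render blurred at
    ``focus_calibration_sigma`` px — images blurrier than that are
    excluded as 'inadequate focus'.
    """

    min_area_um2: float = 2.0
    opening_radius_px: int = 2
    focus_threshold: Optional[float] = None
    focus_calibration_sigma: float = 2.0
    contrast_floor: float = 0.1


def segment_head(
    image: PhaseImage, min_area_um2: float = 2.0, opening_radius_px: int = 2
) -> np.ndarray:
    """Segment the sperm head; returns a boolean mask.

    Raises :class:`NoCellDetectedError` if no connected component of the
    opened foreground reaches ``min_area_um2``.
    """
    if min_area_um2 <= 0:
        raise ValueError("min_area_um2 must be positive")
    px = image.pixels.astype(np.float64)
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains non-finite values")
    if np.ptp(px) == 0:
        raise NoCellDetectedError("image is constant; no cell detected")
    fg = px > threshold_otsu(px)
    if opening_radius_px > 0:
        fg = opening(fg, disk(opening_radius_px))
    labels = label(fg)
    if labels.max() == 0:
        raise NoCellDetectedError("no foreground component after opening")
    min_area_px = min_area_um2 / image.pixel_size**2
    props = regionprops(labels)
    best = max(props, key=lambda p: p.area)
    if best.area < min_area_px:
        raise NoCellDetectedError(
            f"largest component {best.area * image.pixel_size ** 2:.2f} um^2 "
            f"below floor {min_area_um2} um^2"
        )
    return labels == best.label


def measure_head_axes(mask: np.ndarray, pixel_size: float) -> Tuple[float, float, float]:
    """Head length, width (um) and their ratio from mask moments.

    Uses the covariance eigenvalues of the pixel coordinates:
    length = 4*sqrt(lambda_major)*pixel_size, width likewise with the
    minor eigenvalue — exact for a solid ellipse.
    """
    if mask.sum() == 0:
        raise ValueError("empty mask")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    props = regionprops(mask.astype(np.uint8))[0]
    length = props.axis_major_length * pixel_size
    width = props.axis_minor_length * pixel_size
    if width == 0:
        raise ValueError("degenerate mask (zero minor axis)")
    return length, width, length / width


def measure_acrosome_pct(
    image: PhaseImage, head_mask: np.ndarray, contrast_floor: float = 0.1
) -> float:
    """Acrosome-area-to-head-area ratio x 100 (%).

    Within-head phase values are split by Otsu into low- and high-density
    compartments; the lower-mean compartment (the acrosomal cap, whose
    dry-mass density is below the nucleus) is the acrosome.

    Raises :class:`LowContrastError` when the relative mean contrast
    between the two compartments is below ``contrast_floor`` — the
    'unclear borders' exclusion.
    """
    if head_mask.sum() == 0:
        raise ValueError("empty head mask")
    values = image.pixels[head_mask].astype(np.float64)
    if np.ptp(values) == 0:
        raise LowContrastError("uniform density within head; borders unclear")
    thr = threshold_otsu(values)
    low = values <= thr
    n_low = int(low.sum())
    if n_low == 0 or n_low == values.size:
        raise LowContrastError("degenerate within-head split; borders unclear")
    mean_low = values[low].mean()
    mean_high = values[~low].mean()
    contrast = (mean_high - mean_low) / max(abs(mean_high), 1e-300)
    if contrast < contrast_floor:
        raise LowContrastError(
            f"within-head contrast {contrast:.3f} below floor {contrast_floor}"
        )
    return 100.0 * n_low / values.size


def focus_score(image: PhaseImage | np.ndarray) -> float:
    """Sharpness: variance of the 3x3 Laplacian response normalised by the
    squared mean foreground intensity.

    Monotonically decreasing under increasing Gaussian blur; invariant to
    positive rescaling of the image; 0 for a constant image.
    """
    px = (image.pixels if isinstance(image, PhaseImage) else image).astype(np.float64)
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains non-finite values")
    if np.ptp(px) == 0:
        return 0.0
    lap = ndimage.laplace(px)
    fg = px > threshold_otsu(px)
    denom = px[fg].mean() ** 2 if fg.any() else px.mean() ** 2
    if denom == 0:
        return 0.0
    return float(lap.var() / denom)


@functools.lru_cache(maxsize=32)
def calibrated_focus_threshold(pixel_size: float, sigma: float = 2.0) -> float:
    """Focus-gate threshold: the score of a canonical 4.5 x 3.0 um cell
    (50% cap) rendered noiselessly at ``pixel_size`` and blurred at
    ``sigma`` px.  Images scoring below are 'inadequate focus'."""
    truth = SpermGroundTruth(
        cell_id="calib",
        subject_id="calib",
        head_length_um=4.5,
        head_width_um=3.0,
        lw_ratio=1.5,
        acrosome_pct=50.0,
    )
    img = render_phase_image(truth, pixel_size=pixel_size, blur_sigma=sigma)
    return focus_score(img)


def measure_cell(
    image: PhaseImage, config: Optional[MeasurementConfig] = None
) -> MorphometryRecord:
    """Run the full gate -> segment -> axes -> acrosome chain on one image.

    Gate failures become exclusion reasons on the returned record rather
    than exceptions, mirroring how an automated device logs unmeasurable
    cells instead of crashing.
    """
    config = config or MeasurementConfig()
    meta = image.metadata or {}
    base = dict(
        subject_id=str(meta.get("subject_id", "unknown")),
        cell_id=str(meta.get("cell_id", "unknown")),
        modality="qpm",
        replicate=int(meta.get("replicate", 1)),
    )
    if np.ptp(image.pixels) == 0:
        # nothing to focus on or segment: unmeasurable, distinct reason
        return MorphometryRecord(**base, exclusion_reason="no_cell", focus_score=0.0)
    score = focus_score(image)
    threshold = (
        config.focus_threshold
        if config.focus_threshold is not None
        else calibrated_focus_threshold(image.pixel_size, config.focus_calibration_sigma)
    )
    if score < threshold:
        return MorphometryRecord(**base, exclusion_reason="inadequate_focus", focus_score=score)
    try:
        mask = segment_head(image, config.min_area_um2, config.opening_radius_px)
    except NoCellDetectedError:
        return MorphometryRecord(**base, exclusion_reason="no_cell", focus_score=score)
    length, width, ratio = measure_head_axes(mask, image.pixel_size)
    try:
        acro = measure_acrosome_pct(image, mask, config.contrast_floor)
    except LowContrastError:
        return MorphometryRecord(**base, exclusion_reason="unclear_borders", focus_score=score)
    return MorphometryRecord(
        **base,
        head_length_um=length,
        head_width_um=width,
        lw_ratio=ratio,
        acrosome_pct=acro,
        focus_score=score,
    )
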