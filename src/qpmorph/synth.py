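"""Ground-truthed synthetic study generator.

Emulates the structure of a multi-centre stain-free sperm morphometry
validation study: per subject, an embryologist selects 11 apparently
normal and 11 overtly abnormal cells; each cell is measured twice
("two intervals of the same recording") by each of two modalities —
stain-free quantitative phase microscopy (qpm) and the stained
bright-field reference — with modality-specific bias, between-cell
measurement noise and between-replicate noise on each endpoint.

The phase image model is a density phantom, not an interferometric
reconstruction: the head is a filled ellipse of unit nuclear density
whose anterior cap (cut by a chord perpendicular to the major axis, so
the cap area fraction is analytically solvable) has 0.6x the nuclear
density, optionally with a thin low-density tail, followed by Gaussian
blur and additive Gaussian noise.  That is enough to exercise every
downstream measurement stage against exact ground truth.

Everything is bitwise-reproducible under a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .errors import ConfigurationError, ResolutionError
from .records import MODALITIES, MorphometryRecord
from .who import ENDPOINTS, WHORanges

# Endpoints that receive direct noise; lw_ratio is always recomputed from
# the noisy length and width, so its error structure is emergent.
NOISY_ENDPOINTS = ("head_length_um", "head_width_um", "acrosome_pct")


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class SpermGroundTruth:
    """True head geometry and a-priori class behind one synthetic cell."""

    cell_id: str
    subject_id: str
    head_length_um: float
    head_width_um: float
    lw_ratio: float
    acrosome_pct: float
    orientation: float = 0.0          # radians, major axis vs. image x-axis
    center: Tuple[float, float] = (0.0, 0.0)   # um offset from canvas centre
    a_priori_class: str = "normal"

    def __post_init__(self):
        if not (self.head_length_um >= self.head_width_um > 0):
            raise ValueError("requires head_length >= head_width > 0")
        if abs(self.lw_ratio - self.head_length_um / self.head_width_um) > 1e-12 * max(self.lw_ratio, 1.0):
            raise ValueError("lw_ratio must equal head_length/head_width")
        if not 0.0 <= self.acrosome_pct <= 100.0:
            raise ValueError("acrosome_pct outside [0, 100]")

    def endpoint(self, name: str) -> float:
        return getattr(self, name)


def _violates(value: float, lo: float, hi: float, margin: float) -> bool:
    return value < lo - margin or value > hi + margin


def sample_ground_truth(
    n: int,
    normal_share: float = 0.61,
    seed: int = 0,
    ranges: Optional[WHORanges] = None,
    subject_id: str = "S000",
    start_index: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> List[SpermGroundTruth]:
    """Draw ``n`` ground-truth cells, ``round(n * normal_share)`` of them normal.

    Normal cells are uniform inside every WHO2021 range (length/width
    resampled until the implied ratio is also in range); abnormal cells
    are uniform over a +/-30%-of-width inflation of each range, rejected
    until at least one endpoint is outside its range by >= 5% of the
    range width.  Hence every normal truth violates no range and every
    abnormal truth clearly violates at least one.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= normal_share <= 1.0:
        raise ValueError("normal_share must be in [0, 1]")
    ranges = ranges or WHORanges()
    rng = rng if rng is not None else np.random.default_rng(seed)

    L = ranges["head_length_um"]
    W = ranges["head_width_um"]
    R = ranges["lw_ratio"]
    A = ranges["acrosome_pct"]
    n_normal = int(round(n * normal_share))

    def draw_normal() -> Tuple[float, float, float, float]:
        while True:
            length = rng.uniform(L.lower, L.upper)
            width = rng.uniform(W.lower, W.upper)
            ratio = length / width
            if R.lower <= ratio <= R.upper and length >= width:
                return length, width, ratio, rng.uniform(A.lower, A.upper)

    infl = {e: 0.3 * (ranges[e].upper - ranges[e].lower) for e in ENDPOINTS}
    margins = {e: 0.05 * (ranges[e].upper - ranges[e].lower) for e in ENDPOINTS}

    def draw_abnormal() -> Tuple[float, float, float, float]:
        while True:
            length = rng.uniform(L.lower - infl["head_length_um"], L.upper + infl["head_length_um"])
            width = rng.uniform(W.lower - infl["head_width_um"], W.upper + infl["head_width_um"])
            acro = rng.uniform(A.lower - infl["acrosome_pct"], A.upper + infl["acrosome_pct"])
            if not (length >= width > 0):
                continue
            ratio = length / width
            vals = dict(head_length_um=length, head_width_um=width, lw_ratio=ratio, acrosome_pct=acro)
            if any(
                _violates(vals[e], ranges[e].lower, ranges[e].upper, margins[e])
                for e in ENDPOINTS
            ):
                return length, width, ratio, acro

    truths = []
    for i in range(n):
        is_normal = i < n_normal
        length, width, ratio, acro = draw_normal() if is_normal else draw_abnormal()
        truths.append(
            SpermGroundTruth(
                cell_id=f"{subject_id}-C{start_index + i:04d}",
                subject_id=subject_id,
                head_length_um=length,
                head_width_um=width,
                lw_ratio=length / width,
                acrosome_pct=acro,
                orientation=rng.uniform(0.0, math.pi),
                a_priori_class="normal" if is_normal else "abnormal",
            )
        )
    return truths


# ---------------------------------------------------------------------------
# phase image rendering


@dataclass
class PhaseImage:
    """2-D optical-path-density map with pixel calibration.

    Values are in arbitrary units >= 0 after background subtraction (up to
    additive noise); ``pixel_size`` is um per pixel.
    """

    pixels: np.ndarray
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")


def cap_cut_fraction(t: float) -> float:
    """Area fraction of the ellipse beyond the chord u = t*a (perpendicular
    to the major axis), exact for any ellipse: (acos t - t*sqrt(1-t^2)) / pi."""
    t = float(np.clip(t, -1.0, 1.0))
    return (math.acos(t) - t * math.sqrt(1.0 - t * t)) / math.pi


def solve_cap_cut(fraction: float) -> float:
    """Invert :func:`cap_cut_fraction`: chord position t in [-1, 1] whose
    anterior segment has the requested area fraction (0 -> 1, 1 -> -1)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0.0:
        return 1.0
    if fraction == 1.0:
        return -1.0
    return brentq(lambda t: cap_cut_fraction(t) - fraction, -1.0, 1.0, xtol=1e-12)


def _cell_coordinates(truth: SpermGroundTruth, pixel_size: float, margin_um: float):
    a = truth.head_length_um / 2.0
    half = a + margin_um
    npx = int(math.ceil(2.0 * half / pixel_size))
    c0 = (npx - 1) / 2.0
    rows, cols = np.mgrid[0:npx, 0:npx]
    x = (cols - c0) * pixel_size - truth.center[0]
    y = (rows - c0) * pixel_size - truth.center[1]
    ct, st = math.cos(truth.orientation), math.sin(truth.orientation)
    u = ct * x + st * y          # along major axis (anterior = +u)
    v = -st * x + ct * y
    return u, v


def render_masks(
    truth: SpermGroundTruth,
    pixel_size: float,
    margin_um: float = 2.0,
    tail: bool = False,
    tail_length_um: float = 6.0,
    tail_width_um: float = 0.2,
) -> Dict[str, np.ndarray]:
    """Noise-free boolean masks (head, acrosomal cap, tail) on the canvas.

    Shared by the renderer and by pixel-counting oracles in tests.
    """
    a = truth.head_length_um / 2.0
    b = truth.head_width_um / 2.0
    u, v = _cell_coordinates(truth, pixel_size, margin_um)
    head = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    t = solve_cap_cut(truth.acrosome_pct / 100.0)
    cap = head & (u >= t * a)
    tail_mask = np.zeros_like(head)
    if tail:
        tail_mask = (
            (u <= -a)
            & (u >= -a - tail_length_um)
            & (np.abs(v) <= tail_width_um / 2.0)
        )
    return {"head": head, "cap": cap, "tail": tail_mask}


def render_phase_image(
    truth: SpermGroundTruth,
    pixel_size: float = 0.05,
    blur_sigma: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    tail: bool = False,
    margin_um: float = 2.0,
    nuclear_density: float = 1.0,
    cap_density_ratio: float = 0.6,
    tail_density_ratio: float = 0.3,
) -> PhaseImage:
    """Render one cell as a phase-density phantom.

    The head is a filled ellipse with semi-axes L/2 x W/2 at the truth's
    orientation; the anterior cap (the acrosome) is cut by a chord solved
    so its area fraction equals ``truth.acrosome_pct`` and carries
    ``cap_density_ratio`` times the nuclear density.  Gaussian blur
    (``blur_sigma`` px) then additive Gaussian noise (``noise_sigma``
    a.u.) are applied.

    Raises :class:`ResolutionError` if ``pixel_size > head_width / 4``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if pixel_size > truth.head_width_um / 4.0:
        raise ResolutionError(
            f"pixel_size {pixel_size} um too coarse for head width "
            f"{truth.head_width_um} um (needs <= width/4)"
        )
    masks = render_masks(truth, pixel_size, margin_um, tail=tail)
    img = np.zeros(masks["head"].shape, dtype=np.float64)
    img[masks["head"]] = nuclear_density
    img[masks["cap"]] = nuclear_density * cap_density_ratio
    img[masks["tail"]] = nuclear_density * tail_density_ratio
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=blur_sigma)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return PhaseImage(
        pixels=img.astype(np.float32),
        pixel_size=pixel_size,
        metadata={
            "cell_id": truth.cell_id,
            "subject_id": truth.subject_id,
            "seed": seed,
            "blur_sigma": blur_sigma,
            "noise_sigma": noise_sigma,
            "tail": tail,
        },
    )


# ---------------------------------------------------------------------------
# measurement noise models


@dataclass(frozen=True)
class EndpointNoise:
    """Noise on one endpoint for one modality.

    ``bias`` is additive; ``sd`` is the between-cell measurement SD (drawn
    once per cell); ``repeat_sd`` is the SD of the *difference* between two
    replicates of the same cell (the quantity a repeatability analysis
    reports), so each replicate draw has SD ``repeat_sd / sqrt(2)``.
    """

    bias: float = 0.0
    sd: float = 0.0
    repeat_sd: float = 0.0

    def __post_init__(self):
        if self.sd < 0 or self.repeat_sd < 0:
            raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class ModalityNoiseModel:
    modality: str
    head_length_um: EndpointNoise = EndpointNoise()
    head_width_um: EndpointNoise = EndpointNoise()
    acrosome_pct: EndpointNoise = EndpointNoise()

    def endpoint(self, name: str) -> EndpointNoise:
        return getattr(self, name)


# Study-level default parameters.  Repeat SDs are the reported
# replicate-difference SDs per modality and endpoint; qpm-vs-reference
# biases are the reported agreement biases (reference taken as unbiased);
# between-cell SDs are solved (split equally between modalities) so the
# SD of the qpm-minus-reference replicate-mean difference matches the
# reported agreement SDs (0.32 um, 0.29 um, 9.6 points).
_AGREEMENT_SD = {"head_length_um": 0.32, "head_width_um": 0.29, "acrosome_pct": 9.6}
_QPM_BIAS = {"head_length_um": 0.18, "head_width_um": -0.26, "acrosome_pct": 5.7}
_QPM_REPEAT_SD = {"head_length_um": 0.13, "head_width_um": 0.10, "acrosome_pct": 7.49}
_REF_REPEAT_SD = {"head_length_um": 0.32, "head_width_um": 0.29, "acrosome_pct": 9.29}


def _solved_cell_sd(endpoint: str) -> float:
    # var(qpm_mean - ref_mean) = 2*sd_cell^2 + (rep_q^2 + rep_r^2)/4 for 2 replicates
    target = _AGREEMENT_SD[endpoint] ** 2
    rep = (_QPM_REPEAT_SD[endpoint] ** 2 + _REF_REPEAT_SD[endpoint] ** 2) / 4.0
    return math.sqrt(max(target - rep, 0.0) / 2.0)


def default_noise_models() -> Dict[str, ModalityNoiseModel]:
    """Per-modality noise models parameterised from the study's reported
    agreement and repeatability statistics."""
    models = {}
    for modality in MODALITIES:
        rep = _QPM_REPEAT_SD if modality == "qpm" else _REF_REPEAT_SD
        bias = _QPM_BIAS if modality == "qpm" else {e: 0.0 for e in NOISY_ENDPOINTS}
        models[modality] = ModalityNoiseModel(
            modality=modality,
            **{
                e: EndpointNoise(bias=bias[e], sd=_solved_cell_sd(e), repeat_sd=rep[e])
                for e in NOISY_ENDPOINTS
            },
        )
    return models


def zero_noise_models() -> Dict[str, ModalityNoiseModel]:
    return {m: ModalityNoiseModel(modality=m) for m in MODALITIES}


# ---------------------------------------------------------------------------
# measurement table simulation


def simulate_measurement_table(
    truths: Sequence[SpermGroundTruth],
    models: Dict[str, ModalityNoiseModel],
    replicates: int = 2,
    seed: int = 0,
    floor_um: float = 0.1,
) -> List[MorphometryRecord]:
    """Simulate the paired measurement table for a list of true cells.

    observed = truth + modality bias + cell-level noise + replicate noise;
    the length-to-width ratio is recomputed from the observed length and
    width.  Negative length/width draws are truncated at ``floor_um`` and
    the record flagged; acrosome percentages are clipped to [0, 100] with
    the same flag.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for modality in MODALITIES:
        if modality not in models:
            raise ConfigurationError(f"missing noise model for modality '{modality}'")
    rng = np.random.default_rng(seed)
    out: List[MorphometryRecord] = []
    for truth in truths:
        for modality in MODALITIES:
            model = models[modality]
            cell_noise = {
                e: rng.normal(0.0, model.endpoint(e).sd) if model.endpoint(e).sd > 0 else 0.0
                for e in NOISY_ENDPOINTS
            }
            for rep in range(1, replicates + 1):
                vals = {}
                truncated = False
                for e in NOISY_ENDPOINTS:
                    en = model.endpoint(e)
                    rep_noise = (
                        rng.normal(0.0, en.repeat_sd / math.sqrt(2.0)) if en.repeat_sd > 0 else 0.0
                    )
                    vals[e] = truth.endpoint(e) + en.bias + cell_noise[e] + rep_noise
                if vals["head_length_um"] < floor_um:
                    vals["head_length_um"] = floor_um
                    truncated = True
                if vals["head_width_um"] < floor_um:
                    vals["head_width_um"] = floor_um
                    truncated = True
                if vals["head_length_um"] < vals["head_width_um"]:
                    # keep the length >= width convention under noise
                    vals["head_length_um"], vals["head_width_um"] = (
                        vals["head_width_um"],
                        vals["head_length_um"],
                    )
                clipped = float(np.clip(vals["acrosome_pct"], 0.0, 100.0))
                truncated = truncated or clipped != vals["acrosome_pct"]
                out.append(
                    MorphometryRecord(
                        subject_id=truth.subject_id,
                        cell_id=truth.cell_id,
                        modality=modality,
                        replicate=rep,
                        head_length_um=vals["head_length_um"],
                        head_width_um=vals["head_width_um"],
                        lw_ratio=vals["head_length_um"] / vals["head_width_um"],
                        acrosome_pct=clipped,
                        a_priori_class=truth.a_priori_class,
                        truncated_flag=truncated,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# whole-study simulation


def default_exclusion_probabilities() -> Dict[str, Dict[str, float]]:
    """Per-modality, per-reason exclusion probabilities.

    qpm rates follow the reported exclusion table (38/1451 movement,
    593/1451 focus).  Reference rates keep the reported reason proportions
    and are scaled so the expected doubly-measurable share of cells is
    about 22.5%, the study's analysable fraction.
    """
    return {
        "qpm": {"insufficient_movement": 38 / 1451, "inadequate_focus": 593 / 1451},
        "reference": {"inadequate_focus": 0.539, "unclear_borders": 0.040, "not_flat": 0.022},
    }


@dataclass
class StudyConfig:
    """Parameters of one simulated study; defaults emulate the real design:
    73 subjects x (11 a-priori-normal + 11 a-priori-abnormal) cells, two
    modalities, two replicates."""

    subjects: int = 73
    normal_per_subject: int = 11
    abnormal_per_subject: int = 11
    replicates: int = 2
    seed: int = 0
    ranges: WHORanges = field(default_factory=WHORanges)
    noise_models: Optional[Dict[str, ModalityNoiseModel]] = None
    exclusion_probabilities: Optional[Dict[str, Dict[str, float]]] = None
    pixel_size: float = 0.05          # um / px
    blur_sigma: float = 1.0           # px, optical softness of the phantom
    noise_sigma: float = 0.03         # a.u. additive noise
    render_images: bool = False
    max_images: Optional[int] = None  # cap on rendered cells (None = all)
    floor_um: float = 0.1

    def __post_init__(self):
        if self.subjects < 1 or self.normal_per_subject + self.abnormal_per_subject < 1:
            raise ValueError("need at least one subject and one cell per subject")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def cells_per_subject(self) -> int:
        return self.normal_per_subject + self.abnormal_per_subject

    @property
    def n_cells(self) -> int:
        return self.subjects * self.cells_per_subject


@dataclass
class StudyBundle:
    """Everything one simulated study produced: truths, the measurement
    table, and (optionally) rendered qpm phase images keyed by cell id."""

    config: StudyConfig
    truths: List[SpermGroundTruth]
    records: List[MorphometryRecord]
    images: Dict[str, PhaseImage] = field(default_factory=dict)

    def records_frame(self):
        from .records import records_to_frame

        return records_to_frame(self.records)

    def truths_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "cell_id": t.cell_id,
                    "subject_id": t.subject_id,
                    "head_length_um": t.head_length_um,
                    "head_width_um": t.head_width_um,
                    "lw_ratio": t.lw_ratio,
                    "acrosome_pct": t.acrosome_pct,
                    "orientation": t.orientation,
                    "a_priori_class": t.a_priori_class,
                }
                for t in self.truths
            ]
        )


def simulate_study(config: Optional[StudyConfig] = None) -> StudyBundle:
    """Simulate a full study per :class:`StudyConfig`.

    Exclusion flags are assigned per cell and modality by independent
    Bernoulli draws per reason, the first firing reason (in gate-precedence
    order) winning; an excluded cell/modality pair contributes records that
    carry only the exclusion reason (endpoints NaN).
    """
    config = config or StudyConfig()
    models = config.noise_models or default_noise_models()
    probs = (
        config.exclusion_probabilities
        if config.exclusion_probabilities is not None
        else default_exclusion_probabilities()
    )
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(4)
    truth_rng = np.random.default_rng(seeds[0])
    excl_rng = np.random.default_rng(seeds[2])
    image_root = seeds[3]

    truths: List[SpermGroundTruth] = []
    for s in range(config.subjects):
        share = config.normal_per_subject / config.cells_per_subject
        truths.extend(
            sample_ground_truth(
                config.cells_per_subject,
                normal_share=share,
                ranges=config.ranges,
                subject_id=f"S{s:03d}",
                rng=truth_rng,
            )
        )

    records = simulate_measurement_table(
        truths,
        models,
        replicates=config.replicates,
        seed=int(np.random.default_rng(seeds[1]).integers(2**31)),
        floor_um=config.floor_um,
    )

    # per cell x modality exclusion flags, first firing reason wins
    from .records import EXCLUSION_REASONS

    excluded: Dict[Tuple[str, str], str] = {}
    for truth in truths:
        for modality in MODALITIES:
            for reason in EXCLUSION_REASONS:
                p = probs.get(modality, {}).get(reason, 0.0)
                if p > 0 and excl_rng.random() < p:
                    excluded[(truth.cell_id, modality)] = reason
                    break
    nan = float("nan")
    records = [
        replace(
            r,
            exclusion_reason=excluded[(r.cell_id, r.modality)],
            head_length_um=nan,
            head_width_um=nan,
            lw_ratio=nan,
            acrosome_pct=nan,
            truncated_flag=False,
        )
        if (r.cell_id, r.modality) in excluded
        else r
        for r in records
    ]

    images: Dict[str, PhaseImage] = {}
    if config.render_images:
        limit = config.max_images if config.max_images is not None else len(truths)
        image_seeds = image_root.generate_state(len(truths)) % (2**31)
        for truth, iseed in list(zip(truths, image_seeds))[:limit]:
            images[truth.cell_id] = render_phase_image(
                truth,
                pixel_size=config.pixel_size,
                blur_sigma=config.blur_sigma,
                noise_sigma=config.noise_sigma,
                seed=int(iseed),
            )
    return StudyBundle(config=config, truths=truths, records=records, images=images)
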