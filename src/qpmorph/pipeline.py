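"""End-to-end pipeline: simulate (or read) -> qc -> classify -> agreement +
repeatability -> concordance, with stable file outputs and a stage funnel log.

Every artifact a run writes embeds the run's seed and a hash of its full
configuration, and the configuration itself is copied verbatim into the
output directory, so any result file can be traced to the exact run that
produced it.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as qio
from .agreement import (
    AgreementResult,
    RepeatabilityResult,
    SdRatioResult,
    bland_altman,
    bland_altman_plot_data,
    characteristic_values,
    compare_repeatability,
    per_cell_differences,
    repeatability_summary,
    with_allowed_limit,
)
from .concordance import ConcordanceResult, ConversionResult, a_priori_conversion, concordance_summary
from .errors import InsufficientDataError, PipelineStageError, UndefinedRatioError
from .qc import ExclusionReport, GateConfig, apply_exclusions
from .synth import StudyConfig, simulate_study
from .who import ENDPOINTS, WHORanges, classify_frame

log = logging.getLogger("qpmorph")


@dataclass
class PipelineConfig:
    seed: int = 0
    study: StudyConfig = field(default_factory=StudyConfig)
    input_csv: Optional[str] = None       # read instead of simulate when set
    gates: GateConfig = field(default_factory=GateConfig)
    ranges: WHORanges = field(default_factory=WHORanges)
    inclusive_bounds: bool = True
    al_variant: str = "rss_downweighted"
    bootstrap_reps: int = 2000
    outdir: Optional[str] = None

    def __post_init__(self):
        # one seed drives everything; the study inherits it
        self.study = dataclasses.replace(self.study, seed=self.seed)

    def to_jsonable(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, WHORanges):
                return obj.to_dict()
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, WHORanges):
                d[f.name] = v.to_dict()
            elif dataclasses.is_dataclass(v) and not isinstance(v, type):
                dd = {}
                for sf in dataclasses.fields(v):
                    sv = getattr(v, sf.name)
                    dd[sf.name] = enc(sv)
                d[f.name] = dd
            else:
                d[f.name] = enc(v)
        return d

    @property
    def config_hash(self) -> str:
        # identifies the analysis, not its destination: outdir excluded
        payload = {k: v for k, v in self.to_jsonable().items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    config: PipelineConfig
    records: pd.DataFrame
    kept: pd.DataFrame
    exclusion_report: ExclusionReport
    classifications: pd.DataFrame
    agreement: Dict[str, AgreementResult]
    repeatability: Dict[str, Dict[str, RepeatabilityResult]]
    repeatability_ratio: Dict[str, SdRatioResult]
    concordance: ConcordanceResult
    concordance_apriori_normal: Optional[ConcordanceResult]
    conversions: Dict[str, ConversionResult]
    characteristic: Dict[str, float]
    funnel: List[dict]


def _classify_cells(kept: pd.DataFrame, ranges: WHORanges, inclusive: bool) -> pd.DataFrame:
    """Per cell x modality: replicate-mean endpoints (ratio recomputed from
    the mean length and width) and their WHO class."""
    means = (
        kept.groupby(["cell_id", "modality"], sort=True)
        .agg(
            subject_id=("subject_id", "first"),
            a_priori_class=("a_priori_class", "first"),
            head_length_um=("head_length_um", "mean"),
            head_width_um=("head_width_um", "mean"),
            acrosome_pct=("acrosome_pct", "mean"),
        )
        .reset_index()
    )
    means["lw_ratio"] = means["head_length_um"] / means["head_width_um"]
    return classify_frame(means, ranges, inclusive)


def run_pipeline(config: Optional[PipelineConfig] = None) -> PipelineReport:
    """Run the full analysis; see the module docstring for the stage order.

    Any stage hitting an insufficient-data condition halts the run with a
    :class:`PipelineStageError` naming the stage.
    """
    config = config or PipelineConfig()
    funnel: List[dict] = []

    def checkpoint(stage: str, n: int):
        funnel.append({"stage": stage, "n": n})
        log.info("stage %-12s n=%d", stage, n)

    # --- simulate or read -------------------------------------------------
    if config.input_csv:
        records = qio.read_measurements(config.input_csv)
        bundle = None
    else:
        bundle = simulate_study(config.study)
        records = bundle.records_frame()
    n_cells = records["cell_id"].nunique()
    checkpoint("input", n_cells)

    # --- qc ---------------------------------------------------------------
    try:
        kept, excl_report = apply_exclusions(records, config.gates)
    except ValueError as exc:
        raise PipelineStageError("qc", str(exc)) from exc
    measurable = kept["cell_id"].nunique()
    checkpoint("measurable", measurable)

    # --- classification ---------------------------------------------------
    classifications = _classify_cells(kept, config.ranges, config.inclusive_bounds)
    by_mod = classifications.pivot_table(
        index="cell_id", columns="modality", values="who_class", aggfunc="first"
    )
    for col in ("qpm", "reference"):
        if col not in by_mod.columns:
            by_mod[col] = None
    both = by_mod.dropna(subset=["qpm", "reference"])
    checkpoint("analyzable", len(both))

    # --- agreement --------------------------------------------------------
    agreement: Dict[str, AgreementResult] = {}
    repeatability: Dict[str, Dict[str, RepeatabilityResult]] = {"qpm": {}, "reference": {}}
    ratios: Dict[str, SdRatioResult] = {}
    try:
        for endpoint in ENDPOINTS:
            diffs = per_cell_differences(kept, endpoint, mode="between_modalities")
            result = bland_altman(diffs)
            for modality in ("qpm", "reference"):
                repeatability[modality][endpoint] = repeatability_summary(
                    kept, endpoint, modality
                )
            agreement[endpoint] = with_allowed_limit(
                result, repeatability["reference"][endpoint].sd, config.al_variant
            )
            ratios[endpoint] = compare_repeatability(
                repeatability["qpm"][endpoint],
                repeatability["reference"][endpoint],
                bootstrap_reps=config.bootstrap_reps,
                seed=config.seed + 1,
            )
        characteristic = characteristic_values(kept)
    except (InsufficientDataError, UndefinedRatioError) as exc:
        raise PipelineStageError("agree", str(exc)) from exc

    # --- concordance ------------------------------------------------------
    apriori = (
        classifications.drop_duplicates("cell_id").set_index("cell_id")["a_priori_class"]
    )
    apriori = apriori.reindex(both.index)
    try:
        conc = concordance_summary(both["qpm"], both["reference"], subgroup="all")
        conc_normal = None
        conversions: Dict[str, ConversionResult] = {}
        if (apriori == "normal").any():
            mask = (apriori == "normal").to_numpy()
            conc_normal = concordance_summary(
                both["qpm"], both["reference"], subgroup_mask=mask, subgroup="a_priori_normal"
            )
            for modality in ("reference", "qpm"):
                conversions[modality] = a_priori_conversion(apriori, both[modality])
    except InsufficientDataError as exc:
        raise PipelineStageError("concord", str(exc)) from exc

    report = PipelineReport(
        config=config,
        records=records,
        kept=kept,
        exclusion_report=excl_report,
        classifications=classifications,
        agreement=agreement,
        repeatability=repeatability,
        repeatability_ratio=ratios,
        concordance=conc,
        concordance_apriori_normal=conc_normal,
        conversions=conversions,
        characteristic=characteristic,
        funnel=funnel,
    )
    if config.outdir:
        write_report(report, Path(config.outdir))
    return report


def write_report(report: PipelineReport, outdir: Path) -> None:
    """Serialize a run: CSV tables + JSON summaries, each stamped with the
    config hash and seed; the config itself is copied verbatim."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    stamp = {"config_hash": cfg.config_hash, "seed": cfg.seed}

    (outdir / "config.json").write_text(
        json.dumps(cfg.to_jsonable(), sort_keys=True, indent=1, default=str)
    )
    qio.write_measurements(report.records, outdir / "records.csv")
    report.classifications.to_csv(outdir / "classifications.csv", index=False)
    report.exclusion_report.to_frame().to_csv(outdir / "qc_report.csv", index=False)

    def dump(name: str, payload) -> None:
        (outdir / name).write_text(
            json.dumps({**stamp, **payload}, sort_keys=True, indent=1, default=str)
        )

    dump("qc_report.json", {"report": report.exclusion_report.to_dict()})
    dump("agreement.json", {"endpoints": {e: r.to_dict() for e, r in report.agreement.items()}})
    dump(
        "repeatability.json",
        {
            "endpoints": {
                m: {e: r.to_dict() for e, r in res.items()}
                for m, res in report.repeatability.items()
            },
            "sd_ratio": {
                e: dataclasses.asdict(r) for e, r in report.repeatability_ratio.items()
            },
        },
    )
    conc = {"all": report.concordance.to_dict()}
    if report.concordance_apriori_normal is not None:
        conc["a_priori_normal"] = report.concordance_apriori_normal.to_dict()
    dump(
        "concordance.json",
        {
            "concordance": conc,
            "conversions": {m: c.to_dict() for m, c in report.conversions.items()},
        },
    )
    dump("characteristic_values.json", {"values": report.characteristic})
    dump("funnel.json", {"funnel": report.funnel})
    plot_frames = []
    for endpoint in ENDPOINTS:
        pf = bland_altman_plot_data(report.kept, endpoint)
        pf.insert(0, "endpoint", endpoint)
        plot_frames.append(pf)
    pd.concat(plot_frames, ignore_index=True).to_csv(
        outdir / "bland_altman_data.csv", index=False
    )
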