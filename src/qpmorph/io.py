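"""File contracts: measurement-table CSV and TIFF phase images with JSON sidecars."""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError
from .records import CSV_COLUMNS, MODALITIES, as_frame
from .synth import PhaseImage

log = logging.getLogger("qpmorph")

REQUIRED_COLUMNS = CSV_COLUMNS

#: Plausibility band for head lengths/widths, um; values outside are logged.
PLAUSIBLE_UM = (0.0, 20.0)


def write_measurements(records, path: str | Path) -> Path:
    """Write a measurement table to CSV in the canonical schema."""
    df = as_frame(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in REQUIRED_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in REQUIRED_COLUMNS
    ]
    # %.17g round-trips IEEE doubles exactly
    df[cols].to_csv(path, index=False, float_format="%.17g")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement-table CSV.

    Raises :class:`SchemaError` naming the first missing required column;
    unparseable rows raise with the offending row index.  Lengths outside
    the plausible 0-20 um band are logged as warnings, not errors.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}' in {path}")
    for col in ("head_length_um", "head_width_um", "lw_ratio", "acrosome_pct"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = int(bad.index[0]) if len(bad) else -1
            raise SchemaError(f"unparseable value in column '{col}' at row {row}") from exc
    try:
        df["replicate"] = df["replicate"].astype(int)
    except (ValueError, TypeError) as exc:
        raise SchemaError("unparseable replicate index") from exc
    bad_modality = ~df["modality"].isin(MODALITIES)
    if bad_modality.any():
        raise SchemaError(
            f"unknown modality at row {int(df.index[bad_modality][0])}"
        )
    for col in ("head_length_um", "head_width_um"):
        vals = df[col].dropna()
        outside = vals[(vals < PLAUSIBLE_UM[0]) | (vals > PLAUSIBLE_UM[1])]
        if len(outside):
            log.warning(
                "%d values of %s outside plausible %s um band in %s",
                len(outside), col, PLAUSIBLE_UM, path,
            )
    if "truncated_flag" in df.columns:
        df["truncated_flag"] = df["truncated_flag"].astype(bool)
    df["exclusion_reason"] = df["exclusion_reason"].fillna("none")
    return df


def write_image(image: PhaseImage, path: str | Path) -> Path:
    """Write a single-channel 32-bit TIFF plus a JSON sidecar carrying the
    pixel size and provenance metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    sidecar = path.with_suffix(".json")
    meta = {"pixel_size_um": image.pixel_size, **(image.metadata or {})}
    sidecar.write_text(json.dumps(meta, sort_keys=True, indent=1, default=str))
    return path


def read_image(path: str | Path) -> PhaseImage:
    """Read a TIFF and its JSON sidecar back into a :class:`PhaseImage`."""
    path = Path(path)
    pixels = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise SchemaError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "pixel_size_um" not in meta:
        raise SchemaError(f"sidecar {sidecar} lacks pixel_size_um")
    pixel_size = float(meta.pop("pixel_size_um"))
    return PhaseImage(pixels=np.asarray(pixels), pixel_size=pixel_size, metadata=meta)
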