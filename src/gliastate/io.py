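"""Readers/writers for the pipeline's tables and 10x Visium position files.

CSV with a header row is the canonical interchange format (TSV via
``sep``).  Visium ``tissue_positions`` files are accepted in both the
legacy headerless 6-column dialect and the headered dialect; coordinates
convert to micrometres via the slide scalefactors (a Visium spot is 55 um
across, and 65 um is the printed fiducial spot spacing used for the
full-resolution pixel-to-um factor).  Every ``write_results`` call emits a
run manifest (tool version, seed, input checksums, filters) so outputs are
traceable and reproducible.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

CELL_REQUIRED = [
    "cell_id",
    "dataset_id",
    "sample_id",
    "batch_id",
    "cluster_id",
    "original_label",
    "disease_group",
    "sex",
]
SPOT_REQUIRED = ["spot_id", "sample_id", "x_um", "y_um", "layer"]

LEGACY_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]

#: printed center-to-center fiducial geometry of a Visium slide, in um
VISIUM_SPOT_DIAMETER_UM = 65.0

_LAYER_PATTERNS = {
    "1": "I", "2": "II", "3": "III", "4": "IV", "5": "V", "6": "VI",
    "i": "I", "ii": "II", "iii": "III", "iv": "IV", "v": "V", "vi": "VI",
}


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


class IntegrityError(ValueError):
    """Input violates an integrity constraint (e.g. duplicate ids)."""


def normalize_layer_label(label: str) -> str:
    """Map common layer spellings ('L2', 'layer 2', 'ii') to Roman numerals."""
    s = str(label).strip()
    m = re.fullmatch(r"(?:l(?:ayer)?\s*)?([1-6]|[ivx]+)", s, flags=re.IGNORECASE)
    if m:
        key = m.group(1).lower()
        if key in _LAYER_PATTERNS:
            return _LAYER_PATTERNS[key]
    if s.upper() in ("I", "II", "III", "IV", "V", "VI"):
        return s.upper()
    raise SchemaError(f"unrecognized cortical layer label {label!r}")


def _check_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def read_cell_table(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a cell annotation table."""
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, CELL_REQUIRED, "cell table")
    dup = df["cell_id"].duplicated()
    if dup.any():
        raise IntegrityError(
            f"duplicate cell_id(s): {df.loc[dup, 'cell_id'].unique()[:5].tolist()}"
        )
    logger.info("read_cell_table: %d cells from %s", len(df), path)
    return df


def read_spot_table(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a spatial spot table; layer labels normalized."""
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, SPOT_REQUIRED, "spot table")
    raw = df["layer"].astype(str)
    df["layer"] = raw.map(normalize_layer_label)
    changed = raw[raw != df["layer"]]
    if len(changed):
        mapping = dict(zip(changed, df.loc[changed.index, "layer"]))
        logger.info("read_spot_table: normalized layer labels %s", mapping)
    dup = df.groupby("sample_id", observed=True)["spot_id"].apply(lambda s: s.duplicated().any())
    if dup.any():
        raise IntegrityError("duplicate spot_id within a sample")
    score_cols = [c for c in df.columns if c.startswith("score_")]
    for c in score_cols:
        v = df[c]
        if ((v < 0) | (v > 1)).any():
            raise SchemaError(f"scores in {c!r} fall outside [0, 1]")
    for c in ("ab_overlap", "nft_overlap"):
        if c in df.columns:
            df[c] = df[c].astype(bool)
    logger.info("read_spot_table: %d spots from %s", len(df), path)
    return df


def read_staining_table(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, ["sample_id", "layer_group", "category", "count"], "staining table")
    if (df["count"] < 0).any():
        raise SchemaError("staining counts must be nonnegative")
    return df


def read_visium_positions(
    path, scalefactors_path: Optional[object] = None
) -> pd.DataFrame:
    """Read a 10x Visium tissue positions file (either dialect).

    Auto-detects the legacy headerless ``tissue_positions_list.csv`` (six
    unnamed columns) vs the headered ``tissue_positions.csv``.
    Out-of-tissue spots are dropped.  With scalefactors, full-resolution
    pixel coordinates convert to um as
    ``um = px * 65 / spot_diameter_fullres``; otherwise pixel units are
    kept and flagged in the ``units`` attribute.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    if has_header:
        df = pd.read_csv(path)
        _check_columns(df, LEGACY_POSITION_COLUMNS, "tissue positions (headered)")
        df = df[LEGACY_POSITION_COLUMNS]
    else:
        df = pd.read_csv(path, header=None)
        if df.shape[1] != 6:
            raise SchemaError(
                f"unrecognized positions dialect with {df.shape[1]} columns; "
                "supported: legacy headerless 6-column tissue_positions_list.csv "
                "or headered tissue_positions.csv"
            )
        df.columns = LEGACY_POSITION_COLUMNS
    n0 = len(df)
    df = df[df["in_tissue"] == 1].reset_index(drop=True)
    logger.info("read_visium_positions: %d/%d spots in tissue", len(df), n0)

    out = pd.DataFrame(
        {
            "spot_id": df["barcode"],
            "array_row": df["array_row"],
            "array_col": df["array_col"],
        }
    )
    if scalefactors_path is not None:
        with open(scalefactors_path, "r", encoding="utf-8") as fh:
            sf = json.load(fh)
        factor = VISIUM_SPOT_DIAMETER_UM / float(sf["spot_diameter_fullres"])
        logger.info("read_visium_positions: px->um factor %.6g", factor)
        out["x_um"] = df["pxl_col_in_fullres"] * factor
        out["y_um"] = df["pxl_row_in_fullres"] * factor
        out.attrs["units"] = "um"
    else:
        out["x_px"] = df["pxl_col_in_fullres"]
        out["y_px"] = df["pxl_row_in_fullres"]
        out.attrs["units"] = "fullres_px"
    return out


def read_plaque_centers(path, sep: str = ",") -> np.ndarray:
    """Two-column (x_um, y_um) CSV of plaque centers."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise SchemaError("plaque centers file needs two columns (x_um, y_um)")
    return df.iloc[:, :2].to_numpy(float)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record accompanying every set of pipeline outputs."""

    seed: Optional[int] = None
    inputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    filters: Dict[str, object] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def add_input(self, path) -> None:
        self.inputs[str(path)] = sha256_of(path)

    def write(self, out_dir) -> Path:
        self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        path = Path(out_dir) / "run_manifest.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "inputs": self.inputs,
                    "filters": self.filters,
                    "timestamp": self.timestamp,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        return path


def write_results(
    results: Mapping[str, object], out_dir, manifest: Optional[RunManifest] = None
) -> Dict[str, Path]:
    """Write tables as CSV and scalars/dicts as a JSON summary + manifest.

    DataFrames land in ``<name>.csv`` with deterministic float formatting;
    everything else is collected into ``summary.json``.  Re-running with
    the same inputs and seed produces byte-identical CSVs (the manifest
    timestamp is excluded from that guarantee).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    summary = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            if obj.empty:
                logger.warning("write_results: %s is empty (header-only CSV)", name)
            obj.to_csv(path, index=False, float_format="%.10g")
            written[name] = path
        else:
            summary[name] = obj
    if summary:
        path = out_dir / "summary.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        written["summary"] = path
    manifest = manifest or RunManifest()
    written["manifest"] = manifest.write(out_dir)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
    raise TypeError(f"not JSON serializable: {type(obj)}")
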