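"""File dialects: droplet CSV, timeseries CSV, dilution CSV, panel YAML/JSON.

Droplet CSV (one row per well, UTF-8, comma-separated):
    well_id,sample_id,assay_id,n_total,n_double,n_fam_only,n_hex_only,n_negative

Timeseries CSV (tidy):
    condition,timepoint_h,replicate,state,percent

Dilution CSV:
    level_expected,replicate,observed

Validation failures carry 1-based data-row numbers in their messages.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .assays import AssayPanelConfig
from .detection_limits import DilutionSeries
from .dpcr_core import DropletWellCounts
from .errors import InputError

__all__ = [
    "DROPLET_COLUMNS",
    "read_droplet_csv",
    "write_droplet_csv",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_dilution_csv",
    "load_panel",
]

DROPLET_COLUMNS = [
    "well_id", "sample_id", "assay_id",
    "n_total", "n_double", "n_fam_only", "n_hex_only", "n_negative",
]

TIMESERIES_COLUMNS = ["condition", "timepoint_h", "replicate", "state", "percent"]


def read_droplet_csv(path) -> list[DropletWellCounts]:
    df = pd.read_csv(path)
    missing = [c for c in DROPLET_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing droplet CSV columns {missing}")
    wells = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            wells.append(
                DropletWellCounts(
                    n_total=float(row.n_total),
                    n_double=float(row.n_double),
                    n_fam_only=float(row.n_fam_only),
                    n_hex_only=float(row.n_hex_only),
                    n_negative=float(row.n_negative),
                    well_id=str(row.well_id),
                    sample_id=str(row.sample_id),
                    assay_id=str(row.assay_id),
                )
            )
        except (InputError, ValueError) as exc:
            raise InputError(f"{path}: row {i}: {exc}") from exc
    return wells


def write_droplet_csv(wells: Sequence[DropletWellCounts], path) -> None:
    rows = [
        {
            "well_id": w.well_id,
            "sample_id": w.sample_id,
            "assay_id": w.assay_id,
            "n_total": w.n_total,
            "n_double": w.n_double,
            "n_fam_only": w.n_fam_only,
            "n_hex_only": w.n_hex_only,
            "n_negative": w.n_negative,
        }
        for w in wells
    ]
    pd.DataFrame(rows, columns=DROPLET_COLUMNS).to_csv(path, index=False)


def read_timeseries_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing timeseries columns {missing}")
    if df.empty:
        raise InputError(f"{path}: timeseries is empty")
    return df


def write_timeseries_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=TIMESERIES_COLUMNS)


def read_dilution_csv(path) -> DilutionSeries:
    df = pd.read_csv(path)
    needed = {"level_expected", "replicate", "observed"}
    if not needed.issubset(df.columns):
        raise InputError(f"{path}: dilution CSV needs columns {sorted(needed)}")
    levels = sorted(df["level_expected"].unique(), reverse=True)
    observed = [
        tuple(df.loc[df["level_expected"] == lv, "observed"].astype(float))
        for lv in levels
    ]
    return DilutionSeries(
        expected_fraction=tuple(float(lv) for lv in levels),
        observed=tuple(observed),
    )


def load_panel(path) -> AssayPanelConfig:
    """Load a panel configuration from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InputError(f"{path}: panel config must be a mapping")
    return AssayPanelConfig.from_dict(data)
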