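"""Feature-table I/O (CSV and spreadsheet) with schema validation."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "read_feature_table",
    "write_feature_table",
]

#: one row per cell; extra columns are preserved untouched
REQUIRED_COLUMNS = [
    "sample_id",
    "cell_id",
    "centroid_x",
    "centroid_y",
    "orientation",
    "area",
    "perimeter",
    "eccentricity",
    "n_neighbors",
]

OPTIONAL_COLUMNS = [
    "golgi_angle",
    "pressure",
    "stress_direction",
    "stress_anisotropy",
    "lambda1",
    "lambda2",
    "boundary",
    "region_label",
    "cluster",
]

_NUMERIC = [
    "centroid_x",
    "centroid_y",
    "orientation",
    "area",
    "perimeter",
    "eccentricity",
    "n_neighbors",
    "golgi_angle",
    "pressure",
    "stress_direction",
    "stress_anisotropy",
    "lambda1",
    "lambda2",
]


def read_feature_table(path) -> pd.DataFrame:
    """Read a per-cell feature table from CSV or spreadsheet (xlsx).

    Validates the documented schema: all required columns present, numeric
    columns parseable.  Row order is preserved; extra columns pass through.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing required column(s): {missing}")
    for col in _NUMERIC:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())
        if bad.size:
            raise SchemaError(
                f"non-numeric value in column {col!r} at row {int(bad[0])}"
            )
        df[col] = coerced
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write a feature table; format chosen by suffix (.csv or .xlsx)."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
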