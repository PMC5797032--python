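"""Reading and writing screen tables, feature files and result tables.

The canonical interchange format is a single long-format delimited table
(CSV, or TSV when the filename ends in ``.tsv``) with header

    cell_line, drug, concentration_uM, replicate, viability_pct

In memory, concentrations are carried as ``x = log10(concentration in µM)``
and responses as ``response`` (% viability).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["SCREEN_FILE_COLUMNS", "read_screen", "write_screen", "read_features"]

SCREEN_FILE_COLUMNS = ("cell_line", "drug", "concentration_uM", "replicate", "viability_pct")


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def read_screen(path: str | Path) -> pd.DataFrame:
    """Read a long-format screen table, validating and converting to log10 µM.

    Raises a descriptive ``ValueError`` (with 1-based file line numbers) for
    missing columns, non-numeric values, or non-positive concentrations.
    """
    df = pd.read_csv(path, sep=_sep(path))
    missing = [c for c in SCREEN_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("concentration_uM", "replicate", "viability_pct"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col!r} at file line(s) "
                             f"{[int(i) + 2 for i in bad[:5]]}")
        df[col] = vals
    nonpos = df.index[df["concentration_uM"] <= 0]
    if len(nonpos):
        raise ValueError(f"{path}: non-positive concentration (log10 undefined) at file "
                         f"line(s) {[int(i) + 2 for i in nonpos[:5]]}")
    out = pd.DataFrame({
        "cell_line": df["cell_line"].astype(str),
        "drug": df["drug"].astype(str),
        "x": np.log10(df["concentration_uM"].to_numpy(float)),
        "replicate": df["replicate"].astype(int),
        "response": df["viability_pct"].astype(float),
    })
    if (out["replicate"] < 1).any():
        raise ValueError(f"{path}: replicate indices must start at 1")
    return out


def write_screen(screen: pd.DataFrame, path: str | Path) -> None:
    """Write an in-memory screen table back to the canonical file format."""
    out = pd.DataFrame({
        "cell_line": screen["cell_line"],
        "drug": screen["drug"],
        "concentration_uM": 10.0 ** screen["x"].to_numpy(float),
        "replicate": screen["replicate"],
        "viability_pct": screen["response"],
    })
    out.to_csv(path, sep=_sep(path), index=False, float_format="%.10g")


def read_features(path: str | Path, key_column: str = "cell_line",
                  value_column: str | None = None) -> dict[str, float]:
    """Read a per-cell-line feature vector keyed by ``key_column``.

    With ``value_column`` omitted, the first non-key column is used.
    Duplicate keys raise.
    """
    df = pd.read_csv(path, sep=_sep(path))
    if key_column not in df.columns:
        raise ValueError(f"{path}: missing key column {key_column!r}")
    if value_column is None:
        others = [c for c in df.columns if c != key_column]
        if not others:
            raise ValueError(f"{path}: no feature column found")
        value_column = others[0]
    elif value_column not in df.columns:
        raise ValueError(f"{path}: missing feature column {value_column!r}")
    keys = df[key_column].astype(str)
    if keys.duplicated().any():
        dupes = sorted(keys[keys.duplicated()].unique().tolist())
        raise ValueError(f"{path}: duplicate cell line key(s) {dupes[:5]}")
    return dict(zip(keys, pd.to_numeric(df[value_column]).astype(float)))
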