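"""Delimited-table readers/writers shared by the command-line interface."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_counts", "read_metadata", "is_proportion_table", "write_json"]


def read_counts(path, transpose_hint: bool = False) -> pd.DataFrame:
    """Read a taxa × samples table from delimited text (TSV or CSV).

    The header row holds sample IDs and the first column taxon labels;
    ``transpose_hint`` flips a samples × taxa table.  Duplicate labels and
    empty tables are rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.empty:
        raise ValueError(f"empty table: {path}")
    if transpose_hint:
        df = df.T
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon labels: {dupes}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in {path}: {exc}") from exc
    if (df.to_numpy() < 0).any():
        raise ValueError("negative abundances")
    return df


def is_proportion_table(df: pd.DataFrame, tol: float = 1e-6) -> bool:
    """True when every sample (column) already sums to ~1."""
    sums = df.sum(axis=0).to_numpy()
    return bool(np.allclose(sums, 1.0, atol=tol))


def read_metadata(path) -> pd.DataFrame:
    """Read a samples × variables metadata table (first column = sample ID)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.empty:
        raise ValueError(f"empty metadata table: {path}")
    if df.index.duplicated().any():
        raise ValueError("duplicate sample IDs in metadata")
    return df


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
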