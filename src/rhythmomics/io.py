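"""Readers and writers for the plain-text interchange formats.

Feature tables are TSV/CSV with the feature id in the first column and one
column per sample; metadata tables carry ``sample_id, zt_h, group, cage_id,
animal_id``; class maps are two-column ``feature_id, class`` files. Values
round-trip bit-exactly: floats are written with ``repr`` (shortest
round-trip) precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import InputError

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_class_map",
    "write_results_table",
    "read_results_table",
    "write_json",
]

METADATA_COLUMNS = ("sample_id", "zt_h", "group", "cage_id", "animal_id")


def _sep(path: Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_feature_table(path, allow_negative: bool = False) -> pd.DataFrame:
    """Read a feature x sample table; ``allow_negative`` for CLR tables."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep(path), index_col=0, float_precision="round_trip")
    if table.empty:
        raise InputError(f"feature table {path} is empty")
    table.index = table.index.astype(str)
    table.index.name = "feature_id"
    try:
        table = table.astype(float)
    except ValueError as exc:
        raise InputError(f"non-numeric abundance values in {path}: {exc}") from exc
    if not allow_negative and (table.to_numpy() < 0).any():
        raise InputError(f"negative abundances in {path}")
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    table.to_csv(path, sep=_sep(path), index_label="feature_id")


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep(path))
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise InputError(f"metadata {path} lacks required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise InputError(f"duplicate sample ids in {path}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["zt_h"] = meta["zt_h"].astype(float)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    path = Path(path)
    meta.to_csv(path, sep=_sep(path), index=False)


def read_class_map(path) -> pd.Series:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep(path))
    if frame.shape[1] < 2:
        raise InputError(f"class map {path} needs columns feature_id, class")
    frame = frame.iloc[:, :2]
    frame.columns = ["feature_id", "class_"]
    return frame.set_index("feature_id")["class_"].astype(str)


def write_results_table(results: pd.DataFrame, path) -> None:
    path = Path(path)
    results.to_csv(path, sep=_sep(path), index=False)


def read_results_table(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep(path), float_precision="round_trip")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
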