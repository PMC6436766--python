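"""Readers and writers for the seven delimited analysis tables and results.

All tables are UTF-8 comma-separated text with a header row.  Readers are
forgiving about case (enum tokens and booleans are normalized); writers always
emit canonical tokens so outputs are stable across runs.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    Dataset,
    ENUM_VALUES,
    SchemaError,
    TABLE_SCHEMAS,
    UNBOUNDED_TOKEN,
)

_TRUE_TOKENS = {"true", "1", "yes", "t", "y"}
_FALSE_TOKENS = {"false", "0", "no", "f", "n"}

#: Stable column order of the per-island score table written by
#: :func:`write_results` (and produced by the ranking step).
SCORE_COLUMNS = ["island_id", "name", "country", "ccr", "pcr", "eb", "rank"]


def _parse_bool(value, table: str, column: str):
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise SchemaError(f"table {table!r}, column {column!r}: not a boolean: {value!r}")


def _parse_real_or_inf(value, table: str, column: str) -> float:
    token = str(value).strip().lower()
    if token in (UNBOUNDED_TOKEN, "+inf", "infinity", "unbounded"):
        return float("inf")
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise SchemaError(
            f"table {table!r}, column {column!r}: not a number or 'inf': {value!r}"
        ) from exc


def normalize_table(name: str, df: pd.DataFrame) -> pd.DataFrame:
    """Check the schema of raw table *name* and normalize its values.

    Raises :class:`SchemaError` for missing columns and malformed numbers or
    booleans, and :class:`ValueError` for tokens outside an enumerated
    vocabulary (e.g. an IUCN category other than CR/EN — only Critically
    Endangered and Endangered species are in scope).
    """
    schema = TABLE_SCHEMAS[name]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"table {name!r} is missing required column(s): {missing}")
    out = df.loc[:, list(schema)].copy()
    for col, kind in schema.items():
        if kind in ("id", "text"):
            out[col] = out[col].astype(str).str.strip()
        elif kind == "real":
            out[col] = pd.to_numeric(out[col], errors="coerce").astype(float)
            if out[col].isna().any():
                raise SchemaError(f"table {name!r}, column {col!r}: non-numeric value")
        elif kind == "real_or_inf":
            out[col] = [_parse_real_or_inf(v, name, col) for v in out[col]]
            out[col] = out[col].astype(float)
        elif kind == "int":
            numeric = pd.to_numeric(out[col], errors="coerce")
            if numeric.isna().any() or (numeric % 1 != 0).any():
                raise SchemaError(f"table {name!r}, column {col!r}: non-integer value")
            out[col] = numeric.astype(np.int64)
        elif kind == "bool":
            out[col] = [_parse_bool(v, name, col) for v in out[col]]
            out[col] = out[col].astype(bool)
        elif kind.startswith("enum:"):
            enum_name = kind.split(":", 1)[1]
            allowed = ENUM_VALUES[enum_name]
            canonical = {v.lower(): v for v in allowed}
            tokens = out[col].astype(str).str.strip().str.lower()
            bad = sorted(set(tokens) - set(canonical))
            if bad:
                raise ValueError(
                    f"table {name!r}, column {col!r}: unknown token(s) {bad}; "
                    f"allowed: {sorted(allowed)}"
                )
            out[col] = tokens.map(canonical)
    return out.reset_index(drop=True)


def _table_paths(source) -> dict[str, Path]:
    if isinstance(source, Mapping):
        return {name: Path(p) for name, p in source.items()}
    directory = Path(source)
    return {name: directory / f"{name}.csv" for name in TABLE_SCHEMAS}


def read_dataset(source, validate: bool = True) -> Dataset:
    """Read a dataset from a directory of ``<table>.csv`` files (or a mapping
    of table name to path) and return a validated :class:`Dataset`.

    Domestic invasive populations are kept in the table (they are masked out of
    scoring later, preserving the audit trail).  With ``validate=True`` the
    dataset is checked for referential integrity and per-table invariants and
    the first violation is raised.
    """
    paths = _table_paths(source)
    tables = {}
    for name in TABLE_SCHEMAS:
        path = paths[name]
        if not path.exists():
            raise FileNotFoundError(f"table {name!r}: no such file {path}")
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        tables[name] = normalize_table(name, raw)
    dataset = Dataset(**tables)
    if validate:
        from .validate import validate_dataset

        validate_dataset(dataset).raise_if_violations()
    return dataset


def _format_value(kind: str, value):
    if kind == "bool":
        return "true" if value else "false"
    if kind == "real_or_inf" and np.isinf(value):
        return UNBOUNDED_TOKEN
    return value


def write_dataset(dataset: Dataset, directory) -> dict[str, Path]:
    """Write all seven tables as ``<table>.csv`` under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, schema in TABLE_SCHEMAS.items():
        df = dataset.table(name).copy()
        for col, kind in schema.items():
            if kind in ("bool", "real_or_inf"):
                df[col] = [_format_value(kind, v) for v in df[col]]
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
    return written


def write_results(scores: pd.DataFrame, summaries: pd.DataFrame, destination) -> dict[str, Path]:
    """Write the per-island score table and the benefit summaries.

    ``scores`` must carry the :data:`SCORE_COLUMNS`; any sensitive-location
    masking is the caller's responsibility (see
    :func:`islerank.reporting.mask_sensitive`).  Column order is stable so
    repeated runs are byte-identical.
    """
    destination = Path(destination)
    try:
        destination.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create results destination {destination}: {exc}") from exc
    if not os.access(destination, os.W_OK):
        raise OSError(f"results destination {destination} is not writable")
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise SchemaError(f"scores table is missing column(s): {missing}")
    paths = {
        "scores": destination / "island_scores.csv",
        "summaries": destination / "benefit_summaries.csv",
    }
    scores.loc[:, SCORE_COLUMNS].to_csv(paths["scores"], index=False)
    summaries.to_csv(paths["summaries"], index=False)
    return paths


def read_results(destination) -> pd.DataFrame:
    """Read back the per-island score table written by :func:`write_results`."""
    df = pd.read_csv(Path(destination) / "island_scores.csv", dtype={"island_id": str})
    df["rank"] = pd.to_numeric(df["rank"], errors="coerce").astype("Int64")
    return df
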