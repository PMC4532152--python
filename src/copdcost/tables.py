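"""Delimited-text table IO with per-row schema validation.

All pipeline files are UTF-8, tab-separated, "." decimal, header mandatory.
Readers fail loudly with the offending row number and field name rather than
coercing silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd


class SchemaError(ValueError):
    """A table file does not conform to its declared schema."""


@dataclass(frozen=True)
class Column:
    name: str
    dtype: type
    check: Callable[[object], bool] | None = None
    check_desc: str = ""


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[Column, ...]

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]


def _non_negative(x) -> bool:
    return x >= 0


def _in_unit_interval(x) -> bool:
    return 0.0 <= x <= 1.0


REGISTER_EVENTS = TableSchema(
    "register_events",
    (
        Column("person_id", str),
        Column("year", int),
        Column("category", str),
        Column("primary_icd10", str),
        Column("quantity", float, _non_negative, "must be >= 0"),
        Column("reimbursement_entitled", bool),
        Column("uses_anticholinergic", bool),
        Column("age_group", str),
        Column("sex", str),
    ),
)

SMOKING_PREVALENCE = TableSchema(
    "smoking_prevalence",
    (
        Column("year", int),
        Column("age_group", str),
        Column("sex", str),
        Column("category", str),
        Column("fraction", float, _in_unit_interval, "must be in [0, 1]"),
    ),
)

POPULATION = TableSchema(
    "population",
    (
        Column("year", int),
        Column("age_group", str),
        Column("sex", str),
        Column("count", float, _non_negative, "must be >= 0"),
    ),
)

PRICE_INDEX = TableSchema(
    "price_index",
    (
        Column("year", int),
        Column("index", float, lambda x: x > 0, "must be > 0"),
    ),
)

STANDARDISED_COST = TableSchema(
    "standardised_cost",
    (
        Column("age_group", str),
        Column("sex", str),
        Column("channel", str),
        Column("eur_per_equivalent", float, _non_negative, "must be >= 0"),
    ),
)

UTILISATION = TableSchema(
    "utilisation",
    (
        Column("year", int),
        Column("population", float, lambda x: x > 0, "must be > 0"),
        Column("phc_hospital_days", float, _non_negative, "must be >= 0"),
        Column("shc_hospital_days", float, _non_negative, "must be >= 0"),
        Column("shc_outpatient_visits", float, _non_negative, "must be >= 0"),
        Column("sickness_allowance_days", float, _non_negative, "must be >= 0"),
        Column("disability_pension_subjects", float, _non_negative, "must be >= 0"),
        Column("medication_cost", float, _non_negative, "must be >= 0"),
    ),
)

COST_REFERENCE = TableSchema(
    "cost_reference",
    (
        Column("year", int),
        Column("component", str),
        Column("eur", int, _non_negative, "must be >= 0"),
        Column("eur_per_100k", int, _non_negative, "must be >= 0"),
    ),
)

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def _coerce(value: str, col: Column, path: Path, row: int):
    if col.dtype is bool:
        key = str(value).strip().lower()
        if key not in _BOOL_MAP:
            raise SchemaError(f"{path}: row {row}, field {col.name!r}: {value!r} is not a boolean")
        return _BOOL_MAP[key]
    try:
        if col.dtype is int:
            # reject "3.7" but accept "3" / "3.0"
            f = float(value)
            if f != int(f):
                raise ValueError
            return int(f)
        if col.dtype is float:
            return float(value)
        return str(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"{path}: row {row}, field {col.name!r}: {value!r} is not a valid {col.dtype.__name__}"
        ) from None


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a tab-separated table against ``schema``.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{schema.name} file not found: {path}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(raw.columns) != schema.column_names:
        raise SchemaError(
            f"{path}: wrong header for {schema.name}: expected {schema.column_names}, got {list(raw.columns)}"
        )
    data: dict[str, list] = {c.name: [] for c in schema.columns}
    for i, rec in enumerate(raw.itertuples(index=False), start=1):
        for col, value in zip(schema.columns, rec):
            coerced = _coerce(value, col, path, i)
            if col.check is not None and not col.check(coerced):
                raise SchemaError(f"{path}: row {i}, field {col.name!r}: value {coerced!r} {col.check_desc}")
            data[col.name].append(coerced)
    df = pd.DataFrame(data, columns=schema.column_names)
    for col in schema.columns:
        if col.dtype is int:
            df[col.name] = df[col.name].astype("int64")
        elif col.dtype is float:
            df[col.name] = df[col.name].astype("float64")
        elif col.dtype is bool:
            df[col.name] = df[col.name].astype("bool")
        else:
            df[col.name] = df[col.name].astype("object") if len(df) else df[col.name]
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema | None = None) -> Path:
    """Write a table as tab-separated UTF-8 text (index dropped; header mandatory)."""
    path = Path(path)
    out = df.reset_index() if df.index.name is not None else df
    if schema is not None:
        missing = [c for c in schema.column_names if c not in out.columns]
        if missing:
            raise SchemaError(f"cannot write {schema.name}: missing columns {missing}")
        out = out[schema.column_names]
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path
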