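"""Tabular data ingestion and variable semantics.

Experimental data enters as a delimited text file (comma, tab or semicolon),
is held in a :class:`DataTable`, and each column gets a
:class:`VariableMeta` describing its statistical role (response, predictor,
unused) and kind (continuous, count, binary, categorical, proportion).  The
kind is guessed automatically from the observed values and can be corrected
by the user; models downstream refuse kinds their noise family cannot
generate.  Before fitting, the table is restricted to complete cases over
the variables the model uses, and the dropped rows are reported rather than
silently discarded.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataTable",
    "VariableMeta",
    "CompletenessReport",
    "MISSING_MARKERS",
    "read_table",
    "wide_to_long",
    "long_to_wide",
    "guess_variable_type",
    "set_variable_meta",
    "complete_cases",
]

#: Cell contents treated as missing (case-insensitive), plus the empty cell.
MISSING_MARKERS = ("", "na", "nan")

ROLES = ("response", "predictor", "unused")
KINDS = ("continuous", "count", "binary", "categorical", "proportion")


@dataclass
class DataTable:
    """An immutable-ish wrapper around a pandas DataFrame with provenance.

    Invariants: all columns share the same length and column names are
    unique and non-empty (enforced at construction).
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        cols = list(self.df.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate column names in table")
        if any((not isinstance(c, str)) or c == "" for c in cols):
            raise ValueError("column names must be non-empty strings")
        self.df = self.df.reset_index(drop=True)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def column(self, name: str) -> pd.Series:
        return self.df[name]

    def to_records(self) -> list[dict]:
        out = self.df.copy()
        return out.where(pd.notna(out), None).to_dict(orient="records")

    @classmethod
    def from_records(cls, records: Sequence[dict], provenance: str = "") -> "DataTable":
        return cls(pd.DataFrame.from_records(records), provenance=provenance)


@dataclass
class VariableMeta:
    """Semantic description of one column: role, kind and theoretical bounds."""

    name: str
    role: str = "unused"
    kind: str = "continuous"
    lower_bound: float | None = None
    upper_bound: float | None = None
    lower_open: bool = False
    upper_open: bool = False
    user_confirmed: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind == "count" and self.lower_bound is None:
            self.lower_bound = 0.0

    def to_dict(self) -> dict:
        return {
            "name": self.name, "role": self.role, "kind": self.kind,
            "lower_bound": self.lower_bound, "upper_bound": self.upper_bound,
            "lower_open": self.lower_open, "upper_open": self.upper_open,
            "user_confirmed": self.user_confirmed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariableMeta":
        return cls(**d)


@dataclass
class CompletenessReport:
    """What complete-case filtering removed and why."""

    n_input_rows: int
    n_retained_rows: int
    dropped_row_indices: list[int]
    affected_variables: list[str]

    def __post_init__(self) -> None:
        if self.n_retained_rows + len(self.dropped_row_indices) != self.n_input_rows:
            raise ValueError("inconsistent completeness report")

    def to_dict(self) -> dict:
        return {
            "n_input_rows": self.n_input_rows,
            "n_retained_rows": self.n_retained_rows,
            "dropped_row_indices": list(self.dropped_row_indices),
            "affected_variables": list(self.affected_variables),
        }


def _sniff_delimiter(sample: str) -> str:
    counts = {d: sample.count(d) for d in (",", "\t", ";")}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def read_table(path: str | Path, delimiter: str | None = None,
               header: bool = True) -> DataTable:
    """Parse a delimited text file into a :class:`DataTable`.

    The delimiter is auto-detected among comma, tab and semicolon unless
    given.  Empty cells and the markers ``NA``/``NaN`` (any case) are read
    as missing values.  Ragged rows and duplicate header names are errors.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    delim = delimiter or _sniff_delimiter(text.splitlines()[0])

    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    rows = [r for r in rows if r]  # drop fully blank lines
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (field counts {sorted(widths)})")
    if header:
        names, body = rows[0], rows[1:]
        if len(set(names)) != len(names):
            raise ValueError(f"{path}: duplicated column names in header")
    else:
        names = [f"V{i + 1}" for i in range(widths.pop())]
        body = rows

    data: dict[str, list] = {n: [] for n in names}
    for r in body:
        for n, cell in zip(names, r):
            data[n].append(None if cell.strip().lower() in MISSING_MARKERS else cell.strip())

    df = pd.DataFrame(data, dtype=object)
    # convert columns to numeric where every non-missing cell parses
    for n in names:
        converted = pd.to_numeric(df[n], errors="coerce")
        ok = converted.notna() | df[n].isna()
        if len(df) and ok.all():
            df[n] = converted
        else:
            df[n] = df[n].where(df[n].notna(), np.nan)
    return DataTable(df, provenance=str(path))


def wide_to_long(table: DataTable, id_columns: Sequence[str],
                 value_columns: Sequence[str], key_name: str = "variable",
                 value_name: str = "value") -> DataTable:
    """Reshape measurement columns into (key, value) long format.

    Output has one row per (input row x value column); ``key_name`` holds
    the originating column name.
    """
    id_columns, value_columns = list(id_columns), list(value_columns)
    if not value_columns:
        raise ValueError("value_columns must be non-empty")
    if set(id_columns) & set(value_columns):
        raise ValueError("id_columns and value_columns overlap")
    missing = (set(id_columns) | set(value_columns)) - set(table.columns)
    if missing:
        raise ValueError(f"columns not in table: {sorted(missing)}")
    if key_name in id_columns + value_columns or value_name in id_columns + value_columns:
        raise ValueError("key_name/value_name collide with existing columns")
    long = table.df.melt(id_vars=id_columns, value_vars=value_columns,
                         var_name=key_name, value_name=value_name)
    return DataTable(long, provenance=table.provenance)


def long_to_wide(table: DataTable, id_columns: Sequence[str], key_name: str,
                 value_name: str) -> DataTable:
    """Inverse of :func:`wide_to_long` (used mainly for round-trip checks)."""
    wide = table.df.pivot_table(index=list(id_columns), columns=key_name,
                                values=value_name, aggfunc="first",
                                dropna=False).reset_index()
    wide.columns.name = None
    return DataTable(wide, provenance=table.provenance)


def _nonmissing(values: Iterable) -> list:
    out = []
    for v in values:
        if v is None:
            continue
        if isinstance(v, float) and np.isnan(v):
            continue
        if isinstance(v, str) and v.strip().lower() in MISSING_MARKERS:
            continue
        out.append(v)
    return out


def guess_variable_type(values: Iterable, name: str = "x") -> VariableMeta:
    """Guess a column's kind and theoretical bounds from its observed values.

    The rules apply most-specific-first: binary (two levels, numeric levels
    within {0,1} or exactly two string levels), then count (nonnegative
    integers, more than two distinct), then proportion (reals strictly
    inside the unit interval), then categorical (non-numeric), then
    continuous as the fallback (with a lower bound of 0 guessed for
    strictly positive data).  The guess is deterministic and marked
    unconfirmed so the user can correct it.
    """
    vals = _nonmissing(values)
    if not vals:
        raise ValueError(f"column {name!r} has no non-missing values")

    numeric = all(isinstance(v, (int, float, np.integer, np.floating))
                  and not isinstance(v, bool) for v in vals)
    distinct = set(vals)

    if numeric:
        arr = np.asarray(vals, dtype=float)
        if len(distinct) <= 2 and distinct <= {0, 1, 0.0, 1.0}:
            return VariableMeta(name, kind="binary", lower_bound=0.0, upper_bound=1.0)
        integral = np.all(arr == np.round(arr))
        if integral and np.all(arr >= 0) and len(distinct) > 2:
            return VariableMeta(name, kind="count", lower_bound=0.0)
        if np.all((arr > 0) & (arr < 1)):
            return VariableMeta(name, kind="proportion", lower_bound=0.0,
                                upper_bound=1.0, lower_open=True, upper_open=True)
        if np.all(arr > 0):
            return VariableMeta(name, kind="continuous", lower_bound=0.0, lower_open=True)
        return VariableMeta(name, kind="continuous")

    if len(distinct) == 2:
        return VariableMeta(name, kind="binary")
    return VariableMeta(name, kind="categorical")


def _check_override(meta: VariableMeta, values: Iterable | None) -> None:
    if values is None:
        return
    vals = _nonmissing(values)
    numeric = all(isinstance(v, (int, float, np.integer, np.floating))
                  and not isinstance(v, bool) for v in vals)
    if meta.kind in ("count", "continuous", "proportion") and not numeric:
        raise ValueError(f"kind={meta.kind} incompatible with non-numeric values")
    if numeric:
        arr = np.asarray(vals, dtype=float)
        if meta.kind == "count" and not (np.all(arr == np.round(arr)) and np.all(arr >= 0)):
            raise ValueError("kind=count requires nonnegative integer values")
        if meta.kind == "proportion" and not np.all((arr >= 0) & (arr <= 1)):
            raise ValueError("kind=proportion requires values within [0, 1]")
        if meta.kind == "binary" and not set(arr) <= {0.0, 1.0}:
            raise ValueError("kind=binary requires values in {0, 1}")
        for bound, op, word in ((meta.lower_bound, np.less, "below"),
                                (meta.upper_bound, np.greater, "above")):
            if bound is not None and np.any(op(arr, bound)):
                raise ValueError(f"observed values fall {word} the declared bound {bound}")


def set_variable_meta(meta: VariableMeta, override: dict,
                      values: Iterable | None = None) -> VariableMeta:
    """Apply a user correction to a guessed meta; the result is confirmed.

    ``override`` is a partial dict of VariableMeta fields.  When the
    observed values are supplied, overrides that contradict them (e.g.
    declaring counts for data containing 2.5) raise.
    """
    unknown = set(override) - {f for f in VariableMeta.__dataclass_fields__}
    if unknown:
        raise ValueError(f"unknown VariableMeta fields: {sorted(unknown)}")
    merged = replace(meta, **override)
    merged.user_confirmed = True
    if merged.kind == "count" and "lower_bound" not in override:
        merged.lower_bound = 0.0
    _check_override(merged, values)
    return merged


def complete_cases(table: DataTable, used_variables: Sequence[str]
                   ) -> tuple[DataTable, CompletenessReport]:
    """Drop rows with a missing value in any used variable; report the rest.

    Row indices in the report are 0-based positions in the input table.
    Raises if nothing is retained (with the report attached to the error).
    """
    used = list(used_variables)
    missing_cols = set(used) - set(table.columns)
    if missing_cols:
        raise KeyError(f"used variables not in table: {sorted(missing_cols)}")
    sub = table.df[used]
    bad = sub.isna().any(axis=1).to_numpy()
    dropped = list(np.flatnonzero(bad))
    affected = [c for c in used if sub[c].isna().any()]
    report = CompletenessReport(
        n_input_rows=table.n_rows,
        n_retained_rows=int(table.n_rows - len(dropped)),
        dropped_row_indices=[int(i) for i in dropped],
        affected_variables=affected,
    )
    if report.n_retained_rows == 0:
        err = ValueError("no complete cases remain after filtering")
        err.report = report  # type: ignore[attr-defined]
        raise err
    kept = DataTable(table.df.loc[~bad].reset_index(drop=True), provenance=table.provenance)
    return kept, report
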