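"""Core data types and table I/O.

Two tables drive everything downstream:

* the **cell table** — one row per cell (or data point), columns of
  categorical or numeric annotations such as cell type assignments,
  anatomic structures, donor metadata or QC metrics;
* the optional **annotation-info table** — one row per (annotation column,
  value) pair carrying a display order, a free-text description (aliases,
  marker genes), and the direction of abundance change with disease.

Cell tables are read from csv, gzipped csv, feather (Arrow IPC) and h5ad
(per-cell ``obs`` metadata only; the expression matrix is never touched).
Every column is tagged exactly one of ``categorical`` or ``numeric`` and the
tag is preserved across write/load round trips.
"""

from __future__ import annotations

import gzip
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORICAL",
    "NUMERIC",
    "DIRECTIONS",
    "CellTable",
    "AnnotationInfo",
    "ValidationReport",
    "load_cell_table",
    "load_annotation_info",
    "load_config",
    "validate",
    "write_cell_table",
]

CATEGORICAL = "categorical"
NUMERIC = "numeric"

#: Recognized direction-of-abundance-change values; anything else found in an
#: annotation-info file is mapped to "unknown" with a warning.
DIRECTIONS = ("up", "down", "unchanged", "unknown")

#: Tokens treated as missing when reading csv text. Fixed dialect so that
#: write -> load round trips are stable.
DEFAULT_MISSING_TOKENS = ("", "NA")

_FORMATS = ("csv", "csv_gz", "feather", "h5ad")


class FormatError(ValueError):
    """Raised when a file format cannot be determined or is unsupported."""


class ValidationError(ValueError):
    """Raised for inputs that violate a hard invariant (e.g. duplicate ids)."""


# ---------------------------------------------------------------------------
# CellTable
# ---------------------------------------------------------------------------

class CellTable:
    """A cell-by-annotation table with per-column kind tags.

    Parameters
    ----------
    ids
        Unique, non-empty string identifier per record.
    data
        One column per annotation. Categorical columns are held as object
        dtype with ``nan`` for missing; numeric columns as float64 with
        ``nan`` for missing.
    kinds
        Mapping from column name to ``"categorical"`` or ``"numeric"``.
        Must cover exactly the columns of ``data``.
    check_ids
        When false, duplicate ids are tolerated at construction so that
        :func:`validate` can report them; loading from file always checks.
    """

    def __init__(
        self,
        ids,
        data: pd.DataFrame,
        kinds: dict[str, str],
        *,
        check_ids: bool = True,
    ):
        ids = np.asarray(ids, dtype=object)
        if len(ids) != len(data):
            raise ValidationError(
                f"{len(ids)} cell ids for {len(data)} records"
            )
        if any(pd.isna(i) or str(i) == "" for i in ids):
            raise ValidationError("cell ids must be non-empty")
        ids = np.array([str(i) for i in ids], dtype=object)
        if check_ids and len(set(ids)) != len(ids):
            dupes = pd.Series(ids).value_counts()
            dupes = list(dupes.index[dupes > 1])[:5]
            raise ValidationError(f"duplicate cell ids: {dupes}")
        if set(kinds) != set(data.columns):
            raise ValidationError(
                "kinds must tag exactly the data columns; "
                f"extra={set(kinds) - set(data.columns)}, "
                f"missing={set(data.columns) - set(kinds)}"
            )
        bad = {c: k for c, k in kinds.items() if k not in (CATEGORICAL, NUMERIC)}
        if bad:
            raise ValidationError(f"invalid column kinds: {bad}")

        data = data.copy()
        data.index = pd.RangeIndex(len(data))
        for col, kind in kinds.items():
            if kind == NUMERIC:
                # astype goes through Python float parsing, which is
                # round-trip exact (pd.to_numeric's C parser is not)
                data[col] = data[col].astype(np.float64)
            else:
                vals = data[col].astype(object)
                mask = vals.isna()
                vals = vals.astype(str).astype(object)
                vals[mask] = np.nan
                data[col] = vals
        self.ids = ids
        self.data = data
        self.kinds = dict(kinds)

    # -- basic protocol ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return self.n_cells

    def __repr__(self) -> str:
        return f"CellTable({self.n_cells} cells, {len(self.columns)} columns)"

    def kind(self, column: str) -> str:
        if column not in self.kinds:
            raise KeyError(f"no such column: {column!r}")
        return self.kinds[column]

    def column(self, name: str) -> pd.Series:
        """Return one annotation column as a Series (positional index)."""
        if name not in self.data.columns:
            raise KeyError(f"no such column: {name!r}")
        return self.data[name]

    def require_kind(self, column: str, kind: str) -> pd.Series:
        if self.kind(column) != kind:
            raise ValidationError(
                f"column {column!r} is {self.kind(column)}, expected {kind}"
            )
        return self.data[column]

    # -- derived tables ----------------------------------------------------
    def take(self, positions) -> "CellTable":
        """Row subset by integer positions, preserving order of positions."""
        positions = np.asarray(positions, dtype=np.intp)
        return CellTable(
            self.ids[positions],
            self.data.iloc[positions],
            self.kinds,
        )

    def with_column(self, name: str, values, kind: str) -> "CellTable":
        """Return a copy with one column added (or replaced)."""
        data = self.data.copy()
        data[name] = np.asarray(values, dtype=object if kind == CATEGORICAL else np.float64)
        kinds = dict(self.kinds)
        kinds[name] = kind
        return CellTable(self.ids, data, kinds)

    def equals(self, other: "CellTable") -> bool:
        """Field-by-field equality: ids, kinds, values and missingness."""
        if not isinstance(other, CellTable):
            return False
        if list(self.ids) != list(other.ids):
            return False
        if self.kinds != other.kinds:
            return False
        if list(self.columns) != list(other.columns):
            return False
        for col, kind in self.kinds.items():
            a, b = self.data[col], other.data[col]
            if kind == NUMERIC:
                if not np.array_equal(
                    a.to_numpy(np.float64), b.to_numpy(np.float64), equal_nan=True
                ):
                    return False
            else:
                ma, mb = a.isna().to_numpy(), b.isna().to_numpy()
                if not np.array_equal(ma, mb):
                    return False
                if not (a[~ma].to_numpy() == b[~mb].to_numpy()).all():
                    return False
        return True

    def to_frame(self) -> pd.DataFrame:
        """The table as a plain DataFrame with a leading ``cell_id`` column."""
        out = self.data.copy()
        out.insert(0, "cell_id", self.ids)
        return out


# ---------------------------------------------------------------------------
# AnnotationInfo
# ---------------------------------------------------------------------------

@dataclass
class InfoEntry:
    column: str
    value: str
    order: int
    description: str = ""
    direction: str = "unknown"
    notes: str = ""


class AnnotationInfo:
    """Per-(column, value) metadata: display order, description, direction.

    The row order of the source file dictates display order within each
    annotation column; the ``direction`` vocabulary is
    up / down / unchanged / unknown, defaulting to unknown for any pair not
    listed.
    """

    def __init__(self, entries: list[InfoEntry] | None = None):
        self._entries: dict[tuple[str, str], InfoEntry] = {}
        for e in entries or []:
            key = (e.column, e.value)
            if key in self._entries:
                raise ValidationError(f"duplicate annotation-info entry {key}")
            self._entries[key] = e
        # total order within each column
        per_col: dict[str, set[int]] = {}
        for e in self._entries.values():
            ranks = per_col.setdefault(e.column, set())
            if e.order in ranks:
                raise ValidationError(
                    f"tied display order {e.order} in column {e.column!r}"
                )
            ranks.add(e.order)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    @property
    def entries(self) -> list[InfoEntry]:
        return list(self._entries.values())

    @property
    def columns(self) -> set[str]:
        return {e.column for e in self._entries.values()}

    def get(self, column: str, value: str) -> InfoEntry | None:
        return self._entries.get((column, str(value)))

    def direction(self, column: str, value: str) -> str:
        e = self.get(column, value)
        return e.direction if e is not None else "unknown"

    def order(self, column: str, value: str) -> int | None:
        e = self.get(column, value)
        return e.order if e is not None else None

    def values_for(self, column: str) -> list[str]:
        """Values listed for a column, in display order."""
        es = [e for e in self._entries.values() if e.column == column]
        return [e.value for e in sorted(es, key=lambda e: e.order)]


# ---------------------------------------------------------------------------
# ValidationReport
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Problems found in a cell table / annotation-info pair.

    ``is_valid`` is true iff no error-severity entries exist; warnings do
    not invalidate.
    """

    errors: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.errors)

    def add(self, severity: str, location: str, message: str) -> None:
        self.errors.append((severity, location, message))

    def __repr__(self) -> str:
        n_err = sum(1 for s, _, _ in self.errors if s == "error")
        n_warn = len(self.errors) - n_err
        return f"ValidationReport(valid={self.is_valid}, errors={n_err}, warnings={n_warn})"


# ---------------------------------------------------------------------------
# format handling
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".csv.gz"):
        return "csv_gz"
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".feather":
        return "feather"
    if suffix == ".h5ad":
        return "h5ad"
    raise FormatError(
        f"cannot infer format of {path} (expected .csv, .csv.gz, .feather, .h5ad); "
        "pass format_hint"
    )


def load_config(path) -> dict:
    """Read a TOML config with per-column kind overrides and missing tokens.

    Recognized keys::

        missing_values = ["", "NA"]      # tokens treated as missing in csv
        [kinds]                          # per-column kind overrides
        cluster_id = "categorical"
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    out = {
        "kinds": dict(cfg.get("kinds", {})),
        "missing_values": list(cfg.get("missing_values", DEFAULT_MISSING_TOKENS)),
    }
    for col, kind in out["kinds"].items():
        if kind not in (CATEGORICAL, NUMERIC):
            raise FormatError(f"config kind override {col}={kind!r} invalid")
    return out


def _infer_kind_from_text(series: pd.Series) -> str:
    """Numeric iff every non-missing entry parses as a finite real."""
    vals = series.dropna()
    if len(vals) == 0:
        return CATEGORICAL
    parsed = pd.to_numeric(vals, errors="coerce")
    if parsed.isna().any():
        return CATEGORICAL
    if not np.isfinite(parsed.to_numpy(np.float64)).all():
        return CATEGORICAL
    return NUMERIC


def _frame_from_text(
    df: pd.DataFrame,
    kind_overrides: dict[str, str],
) -> tuple[pd.DataFrame, dict[str, str]]:
    kinds = {}
    for col in df.columns:
        kinds[col] = kind_overrides.get(col, _infer_kind_from_text(df[col]))
    return df, kinds


def _pick_ids(df: pd.DataFrame, index=None):
    """First column named cell_id if present, else the given/row index."""
    if "cell_id" in df.columns:
        ids = df["cell_id"].astype(str).to_numpy(dtype=object)
        df = df.drop(columns=["cell_id"])
        return ids, df
    if index is not None:
        return np.array([str(i) for i in index], dtype=object), df
    return np.array([str(i) for i in range(len(df))], dtype=object), df


def load_cell_table(
    path,
    format_hint: str | None = None,
    *,
    kind_overrides: dict[str, str] | None = None,
    missing_tokens=DEFAULT_MISSING_TOKENS,
) -> CellTable:
    """Load a cell table from csv, csv.gz, feather or h5ad.

    For h5ad only the per-cell metadata (``obs``) is read, with the obs index
    as ``cell_id``. Column kinds are inferred (csv: a column is numeric iff
    every non-missing entry parses as a finite real; feather/h5ad: from the
    stored dtype) unless overridden via ``kind_overrides``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    fmt = format_hint or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    kind_overrides = kind_overrides or {}

    if fmt in ("csv", "csv_gz"):
        df = pd.read_csv(
            path,
            dtype=str,
            keep_default_na=False,
            na_values=list(missing_tokens),
            compression="gzip" if fmt == "csv_gz" else None,
        )
        # note: numeric parsing happens below via to_numeric, which is
        # round-trip exact for the repr-style floats write_cell_table emits
        ids, df = _pick_ids(df)
        df, kinds = _frame_from_text(df, kind_overrides)
        return CellTable(ids, df, kinds)

    if fmt == "feather":
        df = pd.read_feather(path)
        return _from_typed_frame(df, kind_overrides, index=None)

    # h5ad: annotation-centric — obs only, expression matrix ignored
    import anndata as ad

    adata = ad.read_h5ad(path)
    obs = adata.obs.copy()
    return _from_typed_frame(obs, kind_overrides, index=obs.index)


def _from_typed_frame(
    df: pd.DataFrame, kind_overrides: dict[str, str], index
) -> CellTable:
    ids, df = _pick_ids(df, index=index)
    kinds = {}
    for col in df.columns:
        if col in kind_overrides:
            kinds[col] = kind_overrides[col]
        elif pd.api.types.is_numeric_dtype(df[col]) and not pd.api.types.is_bool_dtype(
            df[col]
        ):
            kinds[col] = NUMERIC
        else:
            kinds[col] = CATEGORICAL
    # normalize pandas Categorical / string dtypes to object
    df = df.copy()
    for col, kind in kinds.items():
        if kind == CATEGORICAL:
            vals = df[col].astype(object)
            mask = pd.isna(vals)
            vals = vals.astype(str).astype(object)
            vals[mask.to_numpy()] = np.nan
            df[col] = vals
    return CellTable(ids, df, kinds)


def write_cell_table(table: CellTable, path, format: str | None = None) -> None:
    """Write a cell table to csv, csv.gz or feather.

    ``load_cell_table`` on the result reproduces the table (values, kinds,
    row order), provided categorical values do not all parse as numbers in
    the csv formats (use a kind override on reload for that corner).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in ("csv", "csv_gz", "feather"):
        raise FormatError(f"unsupported write format {fmt!r}")
    df = table.to_frame()
    if fmt in ("csv", "csv_gz"):
        text = df.to_csv(index=False, na_rep="")
        if fmt == "csv_gz":
            # fixed mtime keeps byte-identical rewrites
            with gzip.GzipFile(path, "wb", mtime=0) as fh:
                fh.write(text.encode("utf-8"))
        else:
            path.write_text(text, encoding="utf-8")
    else:
        df = df.copy()
        for col, kind in table.kinds.items():
            if kind == CATEGORICAL:
                df[col] = df[col].astype("string")
        df.to_feather(path)


# ---------------------------------------------------------------------------
# annotation-info I/O
# ---------------------------------------------------------------------------

_INFO_COLUMN_ALIASES = ("column", "annotation", "column_name", "base")
_INFO_VALUE_ALIASES = ("value", "annotation_value", "name")


def load_annotation_info(path) -> AnnotationInfo:
    """Load an annotation-info csv.

    Needs columns naming the annotation column and the value (any of
    ``column``/``annotation``/``column_name`` and ``value``/``name``);
    ``description``, ``direction`` and ``notes`` are optional. Display order
    is taken from file row order within each annotation column. A missing
    direction column means every entry is ``unknown``; unrecognized
    direction strings are mapped to ``unknown`` with a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    col_field = next((c for c in _INFO_COLUMN_ALIASES if c in df.columns), None)
    val_field = next((c for c in _INFO_VALUE_ALIASES if c in df.columns), None)
    if col_field is None or val_field is None:
        raise FormatError(
            f"annotation-info file {path} needs an annotation-column field "
            f"(one of {_INFO_COLUMN_ALIASES}) and a value field "
            f"(one of {_INFO_VALUE_ALIASES}); found {list(df.columns)}"
        )
    entries = []
    rank: dict[str, int] = {}
    for _, row in df.iterrows():
        col, val = row[col_field], row[val_field]
        direction = row.get("direction", "unknown") or "unknown"
        direction = direction.strip().lower()
        if direction not in DIRECTIONS:
            warnings.warn(
                f"unrecognized direction {direction!r} for ({col}, {val}); "
                "using 'unknown'",
                stacklevel=2,
            )
            direction = "unknown"
        order = rank.get(col, 0)
        rank[col] = order + 1
        entries.append(
            InfoEntry(
                column=col,
                value=val,
                order=order,
                description=row.get("description", "") or "",
                direction=direction,
                notes=row.get("notes", "") or "",
            )
        )
    return AnnotationInfo(entries)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

RESERVED_NO_MAPPED = "noMappedCells"


def validate(table: CellTable, info: AnnotationInfo | None = None) -> ValidationReport:
    """Check a table (and optional info) for structural problems.

    Reports, never raises: duplicate cell ids and mixed-kind columns are
    error severity (duplicates cannot normally arise through CellTable's
    constructor but are checked for tables assembled by hand); info entries
    referencing columns or values absent from the table are warnings, as is
    use of the reserved ``noMappedCells`` label as a genuine category.
    """
    report = ValidationReport()
    ids = pd.Series(table.ids)
    dup = ids[ids.duplicated()]
    for cid in dup.unique():
        report.add("error", "cell_id", f"duplicate cell id {cid!r}")
    for col, kind in table.kinds.items():
        series = table.data[col]
        if kind == NUMERIC:
            nonnum = series.dropna().apply(
                lambda v: not isinstance(v, (int, float, np.floating, np.integer))
            )
            if nonnum.any():
                report.add("error", col, "numeric column holds non-numeric entries")
        else:
            vals = set(series.dropna().unique())
            if RESERVED_NO_MAPPED in vals:
                report.add(
                    "warning",
                    col,
                    f"reserved label {RESERVED_NO_MAPPED!r} used as a category",
                )
    if info is not None:
        table_cols = set(table.columns)
        for e in info.entries:
            if e.column not in table_cols:
                report.add(
                    "warning",
                    f"{e.column}/{e.value}",
                    f"info entry references absent column {e.column!r}",
                )
            elif table.kinds[e.column] == CATEGORICAL:
                present = set(table.data[e.column].dropna().unique())
                if e.value not in present:
                    report.add(
                        "warning",
                        f"{e.column}/{e.value}",
                        f"info value {e.value!r} absent from table column",
                    )
    return report
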