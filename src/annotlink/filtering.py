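"""Restrict a cell table to records matching annotation filters.

A filter set holds at most one filter per column: categorical filters keep
records whose value lies in an included set (optionally inverted), numeric
filters keep records inside an inclusive range. Filters compose
conjunctively — a record must pass every filter — and records missing a
filtered value fail that filter in both invert states, since membership
cannot be asserted for a missing value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CATEGORICAL, NUMERIC, CellTable, ValidationError

__all__ = [
    "CategoricalFilter",
    "NumericFilter",
    "FilterSet",
    "SelectionSummary",
    "apply_filter_set",
    "selection_summary",
]


@dataclass(frozen=True)
class CategoricalFilter:
    """Keep records whose value is in ``included`` (XOR ``invert``)."""

    column: str
    included: frozenset
    invert: bool = False

    def __post_init__(self):
        object.__setattr__(self, "included", frozenset(str(v) for v in self.included))
        if not self.included:
            raise ValidationError(f"empty included set for column {self.column!r}")

    def mask(self, table: CellTable) -> np.ndarray:
        series = table.require_kind(self.column, CATEGORICAL)
        present = series.notna().to_numpy()
        member = series.isin(self.included).to_numpy()
        if self.invert:
            member = ~member
        return present & member  # missing fails in both invert states


@dataclass(frozen=True)
class NumericFilter:
    """Keep records with ``lower <= value <= upper`` (inclusive both ends)."""

    column: str
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValidationError(
                f"lower bound {self.lower} > upper bound {self.upper} "
                f"for column {self.column!r}"
            )

    def mask(self, table: CellTable) -> np.ndarray:
        series = table.require_kind(self.column, NUMERIC)
        vals = series.to_numpy(np.float64)
        with np.errstate(invalid="ignore"):
            ok = (vals >= self.lower) & (vals <= self.upper)
        return ok & ~np.isnan(vals)


@dataclass
class FilterSet:
    """An ordered conjunction of filters, at most one per column."""

    filters: list = field(default_factory=list)

    def __post_init__(self):
        cols = [f.column for f in self.filters]
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValidationError(f"multiple filters on column(s) {dupes}")

    def __len__(self) -> int:
        return len(self.filters)

    def mask(self, table: CellTable) -> np.ndarray:
        keep = np.ones(table.n_cells, dtype=bool)
        for f in self.filters:
            keep &= f.mask(table)
        return keep

    # -- serialization for reproducible pipelines --------------------------
    def to_dict(self) -> dict:
        out = {}
        for f in self.filters:
            if isinstance(f, CategoricalFilter):
                out[f.column] = {
                    "keep": sorted(f.included),
                    "invert": f.invert,
                }
            else:
                out[f.column] = {"lower": float(f.lower), "upper": float(f.upper)}
        return out

    @classmethod
    def from_dict(cls, spec: dict) -> "FilterSet":
        filters = []
        for column, body in spec.items():
            if "keep" in body:
                filters.append(
                    CategoricalFilter(
                        column,
                        frozenset(body["keep"]),
                        invert=bool(body.get("invert", False)),
                    )
                )
            else:
                filters.append(
                    NumericFilter(
                        column,
                        lower=float(body.get("lower", -np.inf)),
                        upper=float(body.get("upper", np.inf)),
                    )
                )
        return cls(filters)


def apply_filter_set(table: CellTable, filters: FilterSet) -> CellTable:
    """Return the records satisfying every filter, in their original order."""
    keep = filters.mask(table)
    return table.take(np.flatnonzero(keep))


@dataclass
class SelectionSummary:
    """Details of the current selection: retained/total counts and, per
    categorical column, the value counts after filtering."""

    n_retained: int
    n_total: int
    value_counts: dict[str, dict[str, int]]

    def __repr__(self) -> str:
        return f"SelectionSummary({self.n_retained}/{self.n_total} records)"


def selection_summary(table: CellTable, filters: FilterSet) -> SelectionSummary:
    """Summarize what a filter set retains without materializing the subset."""
    keep = filters.mask(table)
    counts: dict[str, dict[str, int]] = {}
    for col, kind in table.kinds.items():
        if kind != CATEGORICAL:
            continue
        series = table.data[col][keep]
        vc = series.value_counts(dropna=True)
        # report zero counts for values present before filtering
        all_vals = table.data[col].dropna().unique()
        counts[col] = {str(v): int(vc.get(v, 0)) for v in all_vals}
    return SelectionSummary(
        n_retained=int(keep.sum()),
        n_total=table.n_cells,
        value_counts=counts,
    )
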