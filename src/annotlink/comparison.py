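"""Correspondence statistics between categorical annotations.

The statistics here back the main comparison views: cross-tabulations of two
annotation columns (viewable as raw counts, row/column fractions, or Jaccard
similarity), river/alluvial models over two or more columns whose links carry
shared-record counts, per-value breakdowns of how a single category maps into
other columns, and tallies of the disease-direction tags attached to those
matched values.

Records missing either column of a pairwise statistic are excluded from that
statistic (pairwise-complete, not listwise across all river columns), so each
adjacent-column link uses its own complete pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CATEGORICAL,
    AnnotationInfo,
    CellTable,
    ValidationError,
)

__all__ = [
    "ConfusionMatrix",
    "RiverModel",
    "RiverLink",
    "Breakdown",
    "BreakdownEntry",
    "DirectionTally",
    "crosstab",
    "jaccard_view",
    "fraction_view",
    "river_model",
    "value_breakdown",
    "direction_concordance",
    "order_labels",
]


def order_labels(
    series: pd.Series, column: str, info: AnnotationInfo | None
) -> list[str]:
    """Display order for the values of one categorical column.

    Values listed in the annotation-info table come first, in its order;
    remaining values follow by descending record count, ties broken
    lexicographically.
    """
    counts = series.value_counts(dropna=True)
    present = list(counts.index)
    ordered: list[str] = []
    if info is not None:
        for v in info.values_for(column):
            if v in counts.index:
                ordered.append(v)
    rest = [v for v in present if v not in ordered]
    rest.sort(key=lambda v: (-counts[v], v))
    return ordered + rest


# ---------------------------------------------------------------------------
# confusion matrices
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Cross-tabulation of two categorical columns.

    ``counts[i, j]`` is the number of records carrying ``row_labels[i]`` in
    column A and ``col_labels[j]`` in column B, both non-missing; the grand
    total therefore equals the number of records complete in both columns.
    """

    col_a: str
    col_b: str
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValidationError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self, values: np.ndarray | None = None) -> pd.DataFrame:
        """Labeled DataFrame of the counts (or of a derived metric view)."""
        vals = self.counts if values is None else values
        return pd.DataFrame(vals, index=self.row_labels, columns=self.col_labels)

    def transpose(self) -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.col_b, self.col_a, list(self.col_labels), list(self.row_labels),
            self.counts.T,
        )


def crosstab(
    table: CellTable,
    col_a: str,
    col_b: str,
    info: AnnotationInfo | None = None,
) -> ConfusionMatrix:
    """Cross-tabulate two categorical columns over pairwise-complete records."""
    a = table.require_kind(col_a, CATEGORICAL)
    b = table.require_kind(col_b, CATEGORICAL)
    if col_a == col_b:
        b = a
    complete = a.notna() & b.notna()
    ct = pd.crosstab(a[complete], b[complete], dropna=True)
    row_labels = order_labels(a[complete], col_a, info)
    col_labels = order_labels(b[complete], col_b, info)
    ct = ct.reindex(index=row_labels, columns=col_labels, fill_value=0)
    return ConfusionMatrix(
        col_a, col_b, row_labels, col_labels, ct.to_numpy(dtype=np.int64)
    )


def jaccard_view(cm: ConfusionMatrix) -> np.ndarray:
    """Jaccard similarity per cell: ``n_ij / (row_i + col_j - n_ij)``.

    The denominator is the size of the union of the two record sets; it is
    zero only when both sets are empty, in which case the similarity is
    defined as 0 (no relationship).
    """
    n = cm.counts.astype(np.float64)
    denom = cm.row_totals()[:, None] + cm.col_totals()[None, :] - n
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(denom > 0, n / denom, 0.0)
    return j


def fraction_view(cm: ConfusionMatrix, axis: str = "row") -> np.ndarray:
    """Counts normalized so each row (or column) sums to 1.

    Rows/columns with zero total stay all-zero.
    """
    n = cm.counts.astype(np.float64)
    if axis == "row":
        tot = cm.row_totals().astype(np.float64)[:, None]
    elif axis == "column":
        tot = cm.col_totals().astype(np.float64)[None, :]
    else:
        raise ValueError(f"axis must be 'row' or 'column', got {axis!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, n / tot, 0.0)


METRIC_VIEWS = ("counts", "row_fraction", "column_fraction", "jaccard")


def metric_view(cm: ConfusionMatrix, metric: str) -> np.ndarray:
    """Dispatch to the named metric view of a confusion matrix."""
    if metric == "counts":
        return cm.counts.astype(np.float64)
    if metric == "row_fraction":
        return fraction_view(cm, "row")
    if metric == "column_fraction":
        return fraction_view(cm, "column")
    if metric == "jaccard":
        return jaccard_view(cm)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRIC_VIEWS}")


# ---------------------------------------------------------------------------
# river models
# ---------------------------------------------------------------------------

@dataclass
class RiverLink:
    """One ribbon between adjacent river columns."""

    source_column: str
    target_column: str
    source: str
    target: str
    count: int


@dataclass
class RiverModel:
    """Ordered category columns plus weighted links between adjacent columns.

    Node counts are per-column non-missing record counts; each link carries
    the number of records shared by its two categories among records complete
    in both adjacent columns (the pairwise crosstab), so link totals conserve
    node counts restricted to those complete pairs.
    """

    columns: list[str]
    nodes: dict[str, list[tuple[str, int]]]
    links: list[RiverLink] = field(default_factory=list)

    def links_between(self, col_a: str, col_b: str) -> list[RiverLink]:
        return [
            l for l in self.links
            if l.source_column == col_a and l.target_column == col_b
        ]

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "nodes": {
                c: [{"value": v, "count": int(n)} for v, n in vs]
                for c, vs in self.nodes.items()
            },
            "links": [
                {
                    "source_column": l.source_column,
                    "target_column": l.target_column,
                    "source": l.source,
                    "target": l.target,
                    "count": int(l.count),
                }
                for l in self.links
            ],
        }


def river_model(
    table: CellTable,
    cols: list[str],
    info: AnnotationInfo | None = None,
) -> RiverModel:
    """Build the node/link model behind a river (alluvial) plot."""
    if len(cols) < 2:
        raise ValidationError("river model needs at least 2 columns")
    for c in cols:
        table.require_kind(c, CATEGORICAL)
    nodes = {}
    for c in cols:
        series = table.data[c]
        order = order_labels(series, c, info)
        vc = series.value_counts(dropna=True)
        nodes[c] = [(v, int(vc[v])) for v in order]
    links: list[RiverLink] = []
    for col_a, col_b in zip(cols[:-1], cols[1:]):
        cm = crosstab(table, col_a, col_b, info)
        for i, src in enumerate(cm.row_labels):
            for j, tgt in enumerate(cm.col_labels):
                n = int(cm.counts[i, j])
                if n > 0:
                    links.append(RiverLink(col_a, col_b, src, tgt, n))
    return RiverModel(columns=list(cols), nodes=nodes, links=links)


# ---------------------------------------------------------------------------
# single-value breakdowns and direction concordance
# ---------------------------------------------------------------------------

@dataclass
class BreakdownEntry:
    value: str
    count: int
    direction: str = "unknown"


@dataclass
class Breakdown:
    """How the records of one focal (column, value) distribute over other
    columns, each matched value tagged with its disease direction."""

    focal_column: str
    focal_value: str
    per_column: dict[str, list[BreakdownEntry]] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return all(not v for v in self.per_column.values())


def value_breakdown(
    table: CellTable,
    focal_col: str,
    focal_value: str,
    other_cols: list[str],
    info: AnnotationInfo | None = None,
) -> Breakdown:
    """Distribution of one focal category's records over other columns.

    Counts are restricted to records carrying the focal value; per other
    column, only records also non-missing there contribute, so the counts sum
    to the focal record count among records complete in that column. If the
    focal value never occurs, an empty breakdown is returned with a warning.
    """
    series = table.require_kind(focal_col, CATEGORICAL)
    for c in other_cols:
        table.require_kind(c, CATEGORICAL)
    focal_mask = (series == str(focal_value)).to_numpy()
    bd = Breakdown(focal_col, str(focal_value), {c: [] for c in other_cols})
    if not focal_mask.any():
        import warnings

        warnings.warn(
            f"focal value {focal_value!r} does not occur in column {focal_col!r}",
            stacklevel=2,
        )
        return bd
    for c in other_cols:
        sub = table.data[c][focal_mask]
        order = order_labels(sub, c, info)
        vc = sub.value_counts(dropna=True)
        bd.per_column[c] = [
            BreakdownEntry(
                value=v,
                count=int(vc[v]),
                direction=info.direction(c, v) if info is not None else "unknown",
            )
            for v in order
        ]
    return bd


@dataclass
class DirectionTally:
    """Per compared column: counts of direction tags among matched values and
    the dominant direction (ties resolve to unknown)."""

    per_column: dict[str, dict[str, int]]
    dominant: dict[str, str]

    def n_dominant(self, direction: str) -> int:
        """How many compared columns are dominated by the given direction."""
        return sum(1 for d in self.dominant.values() if d == direction)


def direction_concordance(
    bd: Breakdown,
    info: AnnotationInfo | None = None,
    weighting: str = "by_value",
) -> DirectionTally:
    """Tally direction tags of the values matched to a focal category.

    ``by_value`` counts each distinct matched value once; ``by_cell`` weights
    each value by its record count. The dominant direction per column is the
    argmax of the tally, with ties (including the empty tally) reported as
    unknown.
    """
    if weighting not in ("by_value", "by_cell"):
        raise ValueError(f"weighting must be by_value or by_cell, got {weighting!r}")
    per_column: dict[str, dict[str, int]] = {}
    dominant: dict[str, str] = {}
    for col, entries in bd.per_column.items():
        tally: Counter = Counter()
        for e in entries:
            direction = (
                info.direction(col, e.value) if info is not None else e.direction
            )
            tally[direction] += e.count if weighting == "by_cell" else 1
        per_column[col] = dict(tally)
        if not tally:
            dominant[col] = "unknown"
            continue
        best = max(tally.values())
        winners = [d for d, n in tally.items() if n == best]
        dominant[col] = winners[0] if len(winners) == 1 else "unknown"
    return DirectionTally(per_column=per_column, dominant=dominant)
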