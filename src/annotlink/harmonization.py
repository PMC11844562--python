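"""Probabilistic cross-study label harmonization.

Cross-study comparison needs every study's labels expressed on a common set
of cells. Given a set of cells carrying both a reference label (e.g. an
atlas supertype assigned by label transfer) and a study's own label, the
conditional proportions p(study label | reference label) are estimated from
the cells complete in both columns. Reference cells — possibly from a much
larger table — are then assigned a study label by an independent draw from
the distribution of their reference label. Reference labels never observed
together with a study label receive the reserved label ``noMappedCells``
with probability 1, which happens most often when a study covered only part
of the taxonomy (e.g. glia-only studies leave every neuronal type unmapped).
Broader label levels are inferred from their higher-resolution counterparts
through an explicit fine-to-broad hierarchy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CATEGORICAL,
    RESERVED_NO_MAPPED,
    CellTable,
    ValidationError,
)

__all__ = [
    "NO_MAPPED_CELLS",
    "ProportionTable",
    "LabelHierarchy",
    "proportion_table",
    "probabilistic_assign",
    "infer_broad_labels",
    "harmonize_study",
]

#: Reserved study label for reference labels with no counterpart in a study.
NO_MAPPED_CELLS = RESERVED_NO_MAPPED

_PROB_TOL = 1e-12


@dataclass
class ProportionTable:
    """Per reference label, a probability distribution over study labels.

    Each distribution sums to 1; the reserved ``noMappedCells`` label carries
    probability 1 exactly for reference labels absent from the source
    pairing.
    """

    ref_col: str
    study_col: str
    probs: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for s, dist in self.probs.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"probabilities for reference label {s!r} sum to {total}"
                )
            if any(p < 0 or p > 1 + _PROB_TOL for p in dist.values()):
                raise ValidationError(f"probability outside [0,1] for {s!r}")

    @property
    def ref_labels(self) -> list[str]:
        return list(self.probs)

    def distribution(self, ref_label: str) -> dict[str, float]:
        return self.probs[ref_label]

    def coarsen(self, hierarchy: "LabelHierarchy") -> "ProportionTable":
        """Sum study-label probabilities within each broad label."""
        out: dict[str, dict[str, float]] = {}
        for s, dist in self.probs.items():
            agg: dict[str, float] = {}
            for c, p in dist.items():
                broad = c if c == NO_MAPPED_CELLS else hierarchy.broad(c)
                agg[broad] = agg.get(broad, 0.0) + p
            out[s] = agg
        return ProportionTable(self.ref_col, self.study_col, out)

    # -- long-format serialization -----------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s, c, p)
            for s, dist in self.probs.items()
            for c, p in sorted(dist.items())
        ]
        return pd.DataFrame(rows, columns=["ref_label", "study_label", "probability"])

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, ref_col: str = "ref", study_col: str = "study"
    ) -> "ProportionTable":
        probs: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            probs.setdefault(str(row["ref_label"]), {})[str(row["study_label"])] = float(
                row["probability"]
            )
        return cls(ref_col, study_col, probs)


@dataclass
class LabelHierarchy:
    """Total mapping from fine labels to broad labels."""

    fine_to_broad: dict[str, str]

    def broad(self, fine: str) -> str:
        return self.fine_to_broad[fine]

    def __contains__(self, fine: str) -> bool:
        return fine in self.fine_to_broad


def proportion_table(
    table: CellTable, ref_col: str, study_col: str
) -> ProportionTable:
    """Estimate p(study label | reference label) from shared cells.

    Only records with both labels non-missing are retained; for each
    reference label s observed among them, p_{c|s} = n_{s,c} / n_s.
    Reference labels present in the column but never co-observed with a
    study label get ``{"noMappedCells": 1}``.
    """
    ref = table.require_kind(ref_col, CATEGORICAL)
    study = table.require_kind(study_col, CATEGORICAL)
    both = ref.notna() & study.notna()
    if not both.any():
        raise ValidationError(
            f"no records with both {ref_col!r} and {study_col!r} assigned"
        )
    probs: dict[str, dict[str, float]] = {}
    grouped = pd.crosstab(ref[both], study[both])
    for s in grouped.index:
        row = grouped.loc[s]
        n_s = int(row.sum())
        probs[str(s)] = {
            str(c): int(n) / n_s for c, n in row.items() if n > 0
        }
    # reference labels in the table but never paired
    for s in ref.dropna().unique():
        if str(s) not in probs:
            probs[str(s)] = {NO_MAPPED_CELLS: 1.0}
    return ProportionTable(ref_col, study_col, probs)


def probabilistic_assign(
    table: CellTable,
    pt: ProportionTable,
    ref_col: str,
    new_col: str,
    seed: int,
) -> CellTable:
    """Assign each record a study label drawn from its reference label's
    distribution.

    One uniform variate is consumed per table row, in row order, from a
    generator seeded per call — identical (table, pt, seed) give a
    bit-identical assignment column. Records with a missing reference label
    stay missing; reference labels absent from the proportion table are
    assigned ``noMappedCells`` with a warning.
    """
    ref = table.require_kind(ref_col, CATEGORICAL)
    rng = np.random.default_rng(seed)
    u = rng.random(table.n_cells)

    # per-label label arrays and cumulative probabilities
    lookup: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s, dist in pt.probs.items():
        labels = np.array(list(dist.keys()), dtype=object)
        cum = np.cumsum(np.array(list(dist.values()), dtype=np.float64))
        cum[-1] = 1.0  # guard against rounding shortfall
        lookup[s] = (labels, cum)

    out = np.full(table.n_cells, np.nan, dtype=object)
    unknown: set[str] = set()
    miss = ref.isna().to_numpy()
    # group rows by reference label; u was drawn in row order above, so the
    # variate consumed by row i is u[i] regardless of grouping
    codes, uniques = pd.factorize(ref, use_na_sentinel=True)
    for k, s in enumerate(uniques):
        idx = np.flatnonzero(codes == k)
        hit = lookup.get(s)
        if hit is None:
            unknown.add(s)
            out[idx] = NO_MAPPED_CELLS
            continue
        labels, cum = hit
        out[idx] = labels[np.searchsorted(cum, u[idx], side="right")]
    out[miss] = np.nan
    if unknown:
        warnings.warn(
            f"reference labels absent from proportion table assigned "
            f"{NO_MAPPED_CELLS!r}: {sorted(unknown)}",
            stacklevel=2,
        )
    return table.with_column(new_col, out, CATEGORICAL)


def infer_broad_labels(
    table: CellTable,
    fine_col: str,
    hierarchy: LabelHierarchy,
    new_col: str,
) -> CellTable:
    """Infer a broader label level from a higher-resolution column.

    Missing stays missing and the reserved ``noMappedCells`` label passes
    through verbatim; any other fine label absent from the hierarchy is an
    error naming the offending labels.
    """
    fine = table.require_kind(fine_col, CATEGORICAL)
    present = set(fine.dropna().unique())
    unmapped = sorted(
        v for v in present if v != NO_MAPPED_CELLS and v not in hierarchy
    )
    if unmapped:
        raise ValidationError(f"fine labels missing from hierarchy: {unmapped}")
    mapping = dict(hierarchy.fine_to_broad)
    mapping[NO_MAPPED_CELLS] = NO_MAPPED_CELLS
    out = fine.map(mapping).to_numpy(dtype=object)  # NaN maps to NaN
    return table.with_column(new_col, out, CATEGORICAL)


def harmonize_study(
    ref_table: CellTable,
    shared_pairing: CellTable,
    ref_col: str,
    study_col: str,
    seed: int,
    new_col: str | None = None,
) -> CellTable:
    """Express a study's labels on the reference cells in one step.

    Convenience composition: estimate the proportion table on the shared
    pairing, then probabilistically assign onto the reference table. The
    output column is named after the study column unless overridden.
    """
    pt = proportion_table(shared_pairing, ref_col, study_col)
    return probabilistic_assign(
        ref_table, pt, ref_col, new_col or study_col, seed
    )
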