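"""Even-by-cluster subsampling to cap table size.

Interactive exploration of very large cell tables is slow, so tables are
capped (by default at 500,000 records) by subsampling *evenly across
clusters* rather than uniformly: uniform subsampling would nearly erase rare
cell types, which is exactly the bias even subsampling mitigates.

Quotas come from iterative waterfilling: at each pass the even share is the
remaining cap divided by the remaining clusters; clusters at or below that
share are kept whole, their records subtracted from the cap, and the share
recomputed for the rest. Large clusters end up at a common share, small
clusters keep everything, and no nonempty cluster is ever emptied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CATEGORICAL, CellTable, ValidationError

__all__ = ["DEFAULT_CAP", "SubsamplePlan", "even_subsample", "waterfill_quotas"]

DEFAULT_CAP = 500_000

#: Pseudo-cluster assigned to records with a missing cluster value, so that
#: unlabeled cells are subsampled like any other group instead of dropped.
MISSING_CLUSTER = "(missing)"


@dataclass
class SubsamplePlan:
    """Per-cluster original/quota/retained counts for one subsampling run."""

    cap: int
    seed: int
    clusters: dict[str, dict[str, int]] = field(default_factory=dict)
    subsampled: bool = True

    @property
    def n_retained(self) -> int:
        return sum(c["retained"] for c in self.clusters.values())

    @property
    def n_original(self) -> int:
        return sum(c["original"] for c in self.clusters.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (name, c["original"], c["quota"], c["retained"])
            for name, c in sorted(self.clusters.items())
        ]
        return pd.DataFrame(rows, columns=["cluster", "original", "quota", "retained"])


def waterfill_quotas(sizes: dict[str, int], cap: int) -> dict[str, int]:
    """Even-share quotas per cluster under a total cap.

    Clusters at or below the running even share (remaining cap // remaining
    clusters) keep all their records; the remainder is split evenly among
    larger clusters. The total lands in ``[cap - n_clusters, cap]`` (integer
    division may leave up to one record per cluster unassigned) and never
    exceeds the cap.
    """
    if cap < len(sizes):
        raise ValidationError(
            f"cap {cap} below cluster count {len(sizes)}; every cluster "
            "must be allowed at least one record"
        )
    quotas: dict[str, int] = {}
    remaining = dict(sizes)
    remaining_cap = cap
    # settle small clusters first; a cluster at or below the share keeps all
    while remaining:
        share = remaining_cap // len(remaining)
        small = {k: n for k, n in remaining.items() if n <= share}
        if not small:
            for k in remaining:
                quotas[k] = share
            break
        for k, n in small.items():
            quotas[k] = n
            remaining_cap -= n
            del remaining[k]
    return quotas


def even_subsample(
    table: CellTable,
    cluster_col: str,
    cap: int = DEFAULT_CAP,
    seed: int = 0,
) -> tuple[CellTable, SubsamplePlan]:
    """Cap a table's size by even subsampling across one cluster column.

    Tables already at or under the cap are returned unchanged. Otherwise
    per-cluster quotas are waterfilled (see :func:`waterfill_quotas`) and
    records are chosen uniformly within each cluster at the given seed;
    output rows keep their original relative order. Missing cluster values
    form the pseudo-cluster ``(missing)``.
    """
    series = table.require_kind(cluster_col, CATEGORICAL)
    labels = series.fillna(MISSING_CLUSTER)
    sizes = {str(k): int(v) for k, v in labels.value_counts().items()}
    if cap < len(sizes):
        raise ValidationError(
            f"cap {cap} below cluster count {len(sizes)}"
        )
    if table.n_cells <= cap:
        plan = SubsamplePlan(cap=cap, seed=seed, subsampled=False)
        for k, n in sizes.items():
            plan.clusters[k] = {"original": n, "quota": n, "retained": n}
        return table, plan

    quotas = waterfill_quotas(sizes, cap)
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    plan = SubsamplePlan(cap=cap, seed=seed)
    # iterate clusters in sorted label order so the draw sequence is
    # independent of row order quirks
    for k in sorted(sizes):
        members = np.flatnonzero((labels == k).to_numpy())
        q = quotas[k]
        chosen = (
            members
            if q >= len(members)
            else rng.choice(members, size=q, replace=False)
        )
        keep_idx.append(np.sort(chosen))
        plan.clusters[k] = {
            "original": sizes[k],
            "quota": q,
            "retained": len(chosen),
        }
    keep = np.sort(np.concatenate(keep_idx))
    return table.take(keep), plan
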