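"""Independent brute-force oracles: per-record Python enumeration, no pandas
aggregation, kept deliberately separate from the implementation under test."""

from __future__ import annotations

import math


def _cells(table, col):
    """(cell_id, value) pairs with non-missing value, as plain Python."""
    out = []
    vals = table.column(col)
    for cid, v in zip(table.ids, vals):
        if isinstance(v, float) and math.isnan(v):
            continue
        if v is None:
            continue
        out.append((cid, v))
    return out


def brute_crosstab(table, col_a, col_b):
    """dict (value_a, value_b) -> count over records complete in both."""
    a = dict(_cells(table, col_a))
    b = dict(_cells(table, col_b))
    counts = {}
    for cid in table.ids:
        if cid in a and cid in b:
            key = (a[cid], b[cid])
            counts[key] = counts.get(key, 0) + 1
    return counts


def brute_jaccard(table, col_a, col_b, value_a, value_b):
    """|A ∩ B| / |A ∪ B| over complete pairs, by explicit set arithmetic."""
    a = dict(_cells(table, col_a))
    b = dict(_cells(table, col_b))
    shared = [cid for cid in table.ids if cid in a and cid in b]
    set_a = {cid for cid in shared if a[cid] == value_a}
    set_b = {cid for cid in shared if b[cid] == value_b}
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


def brute_row_fraction(table, col_a, col_b, value_a, value_b):
    counts = brute_crosstab(table, col_a, col_b)
    row_total = sum(n for (va, _), n in counts.items() if va == value_a)
    if row_total == 0:
        return 0.0
    return counts.get((value_a, value_b), 0) / row_total


def brute_node_count(table, col, value):
    return sum(1 for _, v in _cells(table, col) if v == value)
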