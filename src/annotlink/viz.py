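"""Static renderers for the four plot families.

Each renderer draws with matplotlib (Agg-safe) and can also emit its
plot-ready numbers — dot sizes, node and ribbon geometry, point positions —
as a CSV/JSON sidecar, so the visual encodings are testable without pixel
comparison. Rendering never mutates the model or table it is given.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Polygon

from .comparison import (
    METRIC_VIEWS,
    ConfusionMatrix,
    RiverModel,
    metric_view,
    order_labels,
)
from .io import CATEGORICAL, NUMERIC, AnnotationInfo, CellTable, ValidationError

__all__ = [
    "PlotStyle",
    "DIRECTION_COLORS",
    "render_river",
    "render_confusion",
    "render_beeswarm",
    "render_scatter",
]

#: Fixed colors for disease-direction tags (up / down / unchanged / unknown).
DIRECTION_COLORS = {
    "up": "#d7301f",
    "down": "#0570b0",
    "unchanged": "#4daf4a",
    "unknown": "#bdbdbd",
}

_OUTPUT_FORMATS = ("png", "svg", "pdf")


@dataclass
class PlotStyle:
    """Shared styling knobs for the renderers.

    ``metric`` selects the confusion-matrix view; dot areas scale linearly
    between ``min_dot`` and ``max_dot`` points² with the metric value.
    """

    metric: str = "counts"
    min_dot: float = 5.0
    max_dot: float = 400.0
    direction_colors: dict[str, str] = field(
        default_factory=lambda: dict(DIRECTION_COLORS)
    )
    cmap: str = "viridis"
    figsize: tuple[float, float] = (8.0, 6.0)
    dpi: int = 100
    seed: int = 0  # jitter seed for bee swarms

    def __post_init__(self):
        if self.metric not in METRIC_VIEWS:
            raise ValidationError(
                f"metric {self.metric!r} not one of {METRIC_VIEWS}"
            )
        if len(set(self.direction_colors.values())) != len(self.direction_colors):
            raise ValidationError("direction colors must be distinct")

    def dot_sizes(self, values: np.ndarray) -> np.ndarray:
        """Linear size scale: 0 -> min_dot, max(values) -> max_dot."""
        vmax = float(values.max()) if values.size else 0.0
        if vmax <= 0:
            return np.full(values.shape, self.min_dot)
        return self.min_dot + (self.max_dot - self.min_dot) * values / vmax


def _check_path(path) -> Path:
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in _OUTPUT_FORMATS:
        raise ValidationError(
            f"output format {fmt!r} not one of {_OUTPUT_FORMATS}"
        )
    return path


def _save(fig, path: Path, style: PlotStyle) -> None:
    # fixed metadata so raster reruns are byte-identical
    kwargs = {"dpi": style.dpi}
    if path.suffix.lower() == ".png":
        kwargs["metadata"] = {"Software": "annotlink"}
    elif path.suffix.lower() == ".svg":
        kwargs["metadata"] = {"Date": None}
    fig.savefig(path, **kwargs)
    plt.close(fig)


# ---------------------------------------------------------------------------
# river plots
# ---------------------------------------------------------------------------

def river_layout(model: RiverModel, gap: float = 0.02) -> dict:
    """Vertical node intervals and ribbon endpoints for a river plot.

    Per column, nodes are stacked in model order with a small gap, heights
    proportional to node counts (normalized per column). Ribbon thickness is
    the link count on the same per-column scale.
    """
    layout: dict = {"columns": list(model.columns), "nodes": {}, "ribbons": []}
    spans: dict[tuple[str, str], tuple[float, float]] = {}
    for ci, col in enumerate(model.columns):
        nodes = model.nodes[col]
        total = sum(n for _, n in nodes) or 1
        y = 0.0
        for value, n in nodes:
            h = n / total
            spans[(col, value)] = (y, y + h)
            layout["nodes"].setdefault(col, []).append(
                {"value": value, "count": n, "x": ci, "y0": y, "y1": y + h}
            )
            y += h + gap
    # ribbons: stack outgoing links within each source node, incoming within
    # each target node, in model node order
    out_cursor = {k: v[0] for k, v in spans.items()}
    in_cursor = {k: v[0] for k, v in spans.items()}
    for ca, cb in zip(model.columns[:-1], model.columns[1:]):
        tot_a = sum(n for _, n in model.nodes[ca]) or 1
        tot_b = sum(n for _, n in model.nodes[cb]) or 1
        node_order_a = [v for v, _ in model.nodes[ca]]
        node_order_b = [v for v, _ in model.nodes[cb]]
        links = sorted(
            model.links_between(ca, cb),
            key=lambda l: (node_order_a.index(l.source), node_order_b.index(l.target)),
        )
        for l in links:
            ha, hb = l.count / tot_a, l.count / tot_b
            y_a = out_cursor[(ca, l.source)]
            y_b = in_cursor[(cb, l.target)]
            out_cursor[(ca, l.source)] = y_a + ha
            in_cursor[(cb, l.target)] = y_b + hb
            layout["ribbons"].append(
                {
                    "source_column": ca,
                    "target_column": cb,
                    "source": l.source,
                    "target": l.target,
                    "count": l.count,
                    "x0": model.columns.index(ca),
                    "x1": model.columns.index(cb),
                    "y0a": y_a,
                    "y0b": y_a + ha,
                    "y1a": y_b,
                    "y1b": y_b + hb,
                }
            )
    return layout


def render_river(
    model: RiverModel,
    style: PlotStyle,
    path,
    data_path=None,
) -> Path:
    """Render a river (alluvial) plot; ribbon widths ∝ link counts."""
    path = _check_path(path)
    layout = river_layout(model)
    fig, ax = plt.subplots(figsize=style.figsize)
    node_w = 0.12
    for col, nodes in layout["nodes"].items():
        for nd in nodes:
            ax.add_patch(
                Polygon(
                    [
                        (nd["x"] - node_w / 2, nd["y0"]),
                        (nd["x"] + node_w / 2, nd["y0"]),
                        (nd["x"] + node_w / 2, nd["y1"]),
                        (nd["x"] - node_w / 2, nd["y1"]),
                    ],
                    facecolor="#555555",
                )
            )
            ax.text(
                nd["x"], (nd["y0"] + nd["y1"]) / 2, nd["value"],
                ha="center", va="center", fontsize=8, color="white",
            )
    for rb in layout["ribbons"]:
        xs = np.linspace(rb["x0"] + node_w / 2, rb["x1"] - node_w / 2, 50)
        t = (xs - xs[0]) / (xs[-1] - xs[0])
        ease = t * t * (3 - 2 * t)  # smoothstep
        top = rb["y0a"] + (rb["y1a"] - rb["y0a"]) * ease
        bot = rb["y0b"] + (rb["y1b"] - rb["y0b"]) * ease
        ax.fill_between(xs, top, bot, alpha=0.5, color="#7fa8d0", linewidth=0)
    ax.set_xticks(range(len(model.columns)))
    ax.set_xticklabels(model.columns)
    ax.set_yticks([])
    ax.set_xlim(-0.5, len(model.columns) - 0.5)
    ax.autoscale(axis="y")
    _save(fig, path, style)
    if data_path is not None:
        Path(data_path).write_text(json.dumps(layout, indent=1))
    return path


# ---------------------------------------------------------------------------
# confusion-matrix dot plots
# ---------------------------------------------------------------------------

def render_confusion(
    cm: ConfusionMatrix,
    style: PlotStyle,
    path,
    data_path=None,
) -> Path:
    """Dot-plot a confusion matrix; dot size and color encode the chosen
    metric (counts, row/column fraction, or Jaccard similarity)."""
    path = _check_path(path)
    values = metric_view(cm, style.metric)
    sizes = style.dot_sizes(values)
    rows, cols = np.nonzero(cm.counts) if cm.counts.any() else (np.array([], int),) * 2
    fig, ax = plt.subplots(figsize=style.figsize)
    if rows.size:
        ax.scatter(
            cols,
            rows,
            s=sizes[rows, cols],
            c=values[rows, cols],
            cmap=style.cmap,
            edgecolors="black",
            linewidths=0.3,
        )
    ax.set_xticks(range(len(cm.col_labels)))
    ax.set_xticklabels(cm.col_labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cm.row_labels)))
    ax.set_yticklabels(cm.row_labels, fontsize=7)
    ax.set_xlabel(cm.col_b)
    ax.set_ylabel(cm.col_a)
    ax.invert_yaxis()
    ax.set_title(style.metric)
    fig.tight_layout()
    _save(fig, path, style)
    if data_path is not None:
        records = [
            {
                "row_label": cm.row_labels[i],
                "col_label": cm.col_labels[j],
                "count": int(cm.counts[i, j]),
                "value": float(values[i, j]),
                "dot_size": float(sizes[i, j]),
            }
            for i, j in zip(*np.nonzero(np.ones_like(cm.counts)))
        ]
        pd.DataFrame(records).to_csv(data_path, index=False)
    return path


# ---------------------------------------------------------------------------
# bee swarm
# ---------------------------------------------------------------------------

def render_beeswarm(
    table: CellTable,
    numeric_col: str,
    group_col: str,
    color_col: str,
    style: PlotStyle,
    path,
    data_path=None,
    info: AnnotationInfo | None = None,
) -> Path:
    """One jittered swarm of points per group value, colored by another
    categorical column; jitter is deterministic at the style's seed."""
    path = _check_path(path)
    y = table.require_kind(numeric_col, NUMERIC)
    groups = table.require_kind(group_col, CATEGORICAL)
    colors = table.require_kind(color_col, CATEGORICAL)
    group_order = order_labels(groups, group_col, info)
    color_order = order_labels(colors, color_col, info)
    palette = plt.get_cmap("tab10")
    color_of = {v: palette(i % 10) for i, v in enumerate(color_order)}
    rng = np.random.default_rng(style.seed)

    fig, ax = plt.subplots(figsize=style.figsize)
    points = []
    for gi, g in enumerate(group_order):
        mask = (groups == g) & y.notna()
        vals = y[mask].to_numpy(np.float64)
        jitter = rng.uniform(-0.3, 0.3, size=len(vals))
        cvals = colors[mask]
        ax.scatter(
            gi + jitter,
            vals,
            s=12,
            c=[color_of.get(c, "#bdbdbd") for c in cvals],
            alpha=0.8,
            linewidths=0,
        )
        for xj, yv, cv in zip(gi + jitter, vals, cvals):
            points.append(
                {"group": g, "x": float(xj), "y": float(yv), "color_value": None if pd.isna(cv) else cv}
            )
    ax.set_xticks(range(len(group_order)))
    ax.set_xticklabels(group_order, rotation=45, ha="right")
    ax.set_ylabel(numeric_col)
    handles = [
        plt.Line2D([], [], marker="o", linestyle="", color=color_of[v], label=v)
        for v in color_order
    ]
    ax.legend(handles=handles, fontsize=7, title=color_col)
    fig.tight_layout()
    _save(fig, path, style)
    if data_path is not None:
        pd.DataFrame(points).to_csv(data_path, index=False)
    return path


# ---------------------------------------------------------------------------
# scatter
# ---------------------------------------------------------------------------

def render_scatter(
    table: CellTable,
    x_col: str,
    y_col: str,
    color_col: str | None,
    style: PlotStyle,
    path,
    data_path=None,
    info: AnnotationInfo | None = None,
) -> Path:
    """Scatter two numeric annotations, one point per record complete in
    both; categorical coloring lists legend entries in info order."""
    path = _check_path(path)
    x = table.require_kind(x_col, NUMERIC)
    y = table.require_kind(y_col, NUMERIC)
    complete = x.notna() & y.notna()
    if not complete.any():
        warnings.warn(
            f"no records complete in {x_col!r} and {y_col!r}; empty plot",
            stacklevel=2,
        )
    fig, ax = plt.subplots(figsize=style.figsize)
    xs = x[complete].to_numpy(np.float64)
    ys = y[complete].to_numpy(np.float64)
    records = pd.DataFrame({"x": xs, "y": ys})
    if color_col is None:
        ax.scatter(xs, ys, s=8, linewidths=0)
    elif table.kind(color_col) == NUMERIC:
        cvals = table.data[color_col][complete].to_numpy(np.float64)
        sc = ax.scatter(xs, ys, s=8, c=cvals, cmap=style.cmap, linewidths=0)
        fig.colorbar(sc, ax=ax, label=color_col)
        records["color_value"] = cvals
    else:
        cvals = table.data[color_col][complete]
        color_order = order_labels(cvals, color_col, info)
        palette = plt.get_cmap("tab10")
        color_of = {v: palette(i % 10) for i, v in enumerate(color_order)}
        ax.scatter(
            xs, ys, s=8,
            c=[color_of.get(c, "#bdbdbd") for c in cvals],
            linewidths=0,
        )
        handles = [
            plt.Line2D([], [], marker="o", linestyle="", color=color_of[v], label=v)
            for v in color_order
        ]
        ax.legend(handles=handles, fontsize=7, title=color_col)
        records["color_value"] = [None if pd.isna(c) else c for c in cvals]
    ax.set_xlabel(x_col)
    ax.set_ylabel(y_col)
    fig.tight_layout()
    _save(fig, path, style)
    if data_path is not None:
        records.to_csv(data_path, index=False)
    return path
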