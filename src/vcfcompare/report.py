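"""Tables and figures: count tables, pivots, histogram, Venn, clustergram, PR.

Every ``render_*`` function writes a PNG and a sibling CSV holding the
numbers behind the figure, so a plot is never the only record of a
result.

Venn diagrams (2-6 sets) are drawn from fixed circle/ellipse layouts.
Region labels (count and percentage in parentheses) are placed at the
geometric centroid of each membership region, found by rasterizing the
layout on a fine grid.  For k = 4 and 5 the ellipse layouts realize all
2^k − 1 regions; a true 6-curve ellipse Venn does not exist, so the
6-set drawing is inherently a pseudo-Venn: patterns without a
geometric region are omitted from the figure but always present in the
CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse
from scipy.cluster import hierarchy

from .benchmark import BenchmarkResult
from .errors import ArityError, SpecError
from .grouping import VariantGroup
from .setops import ClusterResult, SimilarityMatrix, VennTally
from .vcf_io import CallSet, MetadataTable, write_table_csv

Countable = Union[CallSet, VariantGroup]


@dataclass
class PivotSpec:
    """Which metadata columns go on each axis of a pivoted count table."""

    row_columns: Sequence[str]
    col_columns: Sequence[str]

    def __post_init__(self) -> None:
        overlap = set(self.row_columns) & set(self.col_columns)
        if overlap:
            raise SpecError(
                f"pivot row/column sets overlap: {', '.join(sorted(overlap))}"
            )
        if not self.row_columns or not self.col_columns:
            raise SpecError("pivot needs at least one row column and one col column")


@dataclass
class StyleSpec:
    """Figure styling: metadata-driven colors/shapes, font size, palettes."""

    color_by: str | None = None
    shape_by: str | None = None
    font_size: float = 12.0
    colormap: str = "viridis"
    pseudo_venn: bool = False

    def __post_init__(self) -> None:
        if self.font_size <= 0:
            raise SpecError("font_size must be positive")


def _item_count(item: Countable) -> tuple[str, int]:
    if isinstance(item, VariantGroup):
        return item.name, len(item.pooled)
    return item.name, len(item)


def count_table(items: Sequence[Countable]) -> pd.DataFrame:
    """Variant counts per file/group, descending; ties keep input order."""
    rows = [_item_count(it) for it in items]
    frame = pd.DataFrame(rows, columns=["name", "count"])
    return frame.sort_values(
        "count", ascending=False, kind="stable", ignore_index=True
    )


def pivot_counts(groups: Sequence[VariantGroup], spec: PivotSpec) -> pd.DataFrame:
    """Pooled-variant counts arranged on a 2-D metadata grid.

    Groups must have been built with ``group_by`` covering every pivot
    column; combinations with no group stay as empty cells.
    """
    if not groups:
        raise SpecError("pivot_counts needs at least one group")
    available = set(groups[0].group_by)
    missing = [
        c
        for c in list(spec.row_columns) + list(spec.col_columns)
        if c not in available
    ]
    if missing:
        raise SpecError(
            f"pivot column(s) not in the grouping key: {', '.join(missing)}"
        )
    records = []
    for g in groups:
        rec = dict(g.values())
        rec["count"] = len(g.pooled)
        records.append(rec)
    frame = pd.DataFrame(records)
    return pd.pivot_table(
        frame,
        values="count",
        index=list(spec.row_columns),
        columns=list(spec.col_columns),
        aggfunc="sum",
    )


def _sibling_csv(path: Path) -> Path:
    return path.with_suffix(".csv")


def render_histogram(
    counts: pd.DataFrame, style: StyleSpec, path: str | Path
) -> Path:
    """Bar chart of variant counts per file/group (+ CSV of the counts)."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(counts) + 2), 4))
    ax.bar(counts["name"], counts["count"], color="#4878cf")
    ax.set_ylabel("variants", fontsize=style.font_size)
    ax.tick_params(axis="x", labelrotation=45, labelsize=style.font_size)
    ax.tick_params(axis="y", labelsize=style.font_size)
    for tick in ax.get_xticklabels():
        tick.set_ha("right")
    fig.tight_layout()
    fig.savefig(path, format="png", dpi=150)
    plt.close(fig)
    write_table_csv(counts, _sibling_csv(path))
    return path


# --- Venn layouts -----------------------------------------------------------
# Each layout is a list of (cx, cy, width, height, angle_deg) ellipses on a
# unit-scale canvas.  The 2/3-set layouts are circles; 4 and 5 sets use
# ellipse arrangements verified (by rasterization) to realize all 2^k - 1
# membership regions; the 6-set arrangement is the pseudo-Venn.


def _venn_layout(k: int) -> list[tuple[float, float, float, float, float]]:
    if k == 2:
        return [(-0.35, 0.0, 1.2, 1.2, 0.0), (0.35, 0.0, 1.2, 1.2, 0.0)]
    if k == 3:
        r = 0.38
        out = []
        for ang in (90.0, 210.0, 330.0):
            a = math.radians(ang)
            out.append((r * math.cos(a), r * math.sin(a), 1.2, 1.2, 0.0))
        return out
    if k == 4:
        return [
            (-0.22, -0.05, 1.7, 0.90, -40.0),
            (-0.08, 0.12, 1.7, 0.90, -40.0),
            (0.08, 0.12, 1.7, 0.90, 40.0),
            (0.22, -0.05, 1.7, 0.90, 40.0),
        ]
    if k == 5:
        # symmetric 5-ellipse arrangement; rasterization confirms all 31
        # membership regions have positive area
        out = []
        for i in range(5):
            ang = 90.0 + i * 72.0
            a = math.radians(ang)
            out.append(
                (0.15 * math.cos(a), 0.15 * math.sin(a), 1.4, 0.80, ang + 30.0)
            )
        return out
    if k == 6:
        # pseudo-Venn: a 6-curve ellipse Venn cannot realize all 63 regions
        out = []
        for i in range(6):
            ang = 90.0 + i * 60.0
            a = math.radians(ang)
            out.append((0.22 * math.cos(a), 0.22 * math.sin(a), 1.6, 0.80, ang))
        return out
    raise ArityError(f"Venn layouts exist for 2-6 sets, got {k}")


def _ellipse_mask(
    xx: np.ndarray, yy: np.ndarray, params: tuple[float, float, float, float, float]
) -> np.ndarray:
    cx, cy, w, h, angle = params
    t = math.radians(angle)
    dx, dy = xx - cx, yy - cy
    xr = dx * math.cos(t) + dy * math.sin(t)
    yr = -dx * math.sin(t) + dy * math.cos(t)
    return (xr / (w / 2)) ** 2 + (yr / (h / 2)) ** 2 <= 1.0


def _region_centroids(
    layout: list[tuple[float, float, float, float, float]], n_grid: int = 500
) -> dict[int, tuple[float, float]]:
    """Centroid of each realized membership region, by rasterization."""
    xs = np.linspace(-1.5, 1.5, n_grid)
    xx, yy = np.meshgrid(xs, xs)
    masks = [_ellipse_mask(xx, yy, p) for p in layout]
    pattern = np.zeros(xx.shape, dtype=int)
    for i, m in enumerate(masks):
        pattern |= m.astype(int) << i
    centroids: dict[int, tuple[float, float]] = {}
    for mask_value in np.unique(pattern):
        if mask_value == 0:
            continue
        sel = pattern == mask_value
        centroids[int(mask_value)] = (
            float(xx[sel].mean()),
            float(yy[sel].mean()),
        )
    return centroids


def render_venn(tally: VennTally, style: StyleSpec, path: str | Path) -> Path:
    """Venn / pseudo-Venn PNG with count and percentage per region (+ CSV).

    ``style.pseudo_venn`` is only accepted for 6 sets.  Patterns with no
    drawable region (possible only at k = 6) are omitted from the
    figure; the CSV always carries the complete tally.
    """
    k = len(tally.set_names)
    if style.pseudo_venn and k != 6:
        raise SpecError("pseudo_venn rendering is only defined for 6 sets")
    path = Path(path)
    layout = _venn_layout(k)
    centroids = _region_centroids(layout)

    fig, ax = plt.subplots(figsize=(7, 7))
    cmap = plt.get_cmap("tab10")
    for i, params in enumerate(layout):
        cx, cy, w, h, angle = params
        ax.add_patch(
            Ellipse(
                (cx, cy),
                w,
                h,
                angle=angle,
                facecolor=cmap(i % 10),
                alpha=0.25,
                edgecolor=cmap(i % 10),
                linewidth=1.5,
            )
        )
        # set name at the ellipse tip farthest from the canvas centre
        t = math.radians(angle)
        tip_candidates = [
            (cx + (w / 2) * math.cos(t) * s, cy + (w / 2) * math.sin(t) * s)
            for s in (1.12, -1.12)
        ]
        tip = max(tip_candidates, key=lambda p: p[0] ** 2 + p[1] ** 2)
        ax.text(
            tip[0],
            tip[1],
            tally.set_names[i],
            ha="center",
            va="center",
            fontsize=style.font_size,
            color=cmap(i % 10),
            fontweight="bold",
        )
    for mask, (x, y) in centroids.items():
        count = tally.counts.get(mask)
        if count is None:
            continue
        pct = 100.0 * tally.percentages[mask]
        ax.text(
            x,
            y,
            f"{count}\n({pct:.1f}%)",
            ha="center",
            va="center",
            fontsize=max(6.0, style.font_size - 3),
        )
    ax.set_xlim(-1.5, 1.5)
    ax.set_ylim(-1.5, 1.5)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, format="png", dpi=150)
    plt.close(fig)
    write_table_csv(tally.to_frame(), _sibling_csv(path))
    return path


def render_clustergram(
    m: SimilarityMatrix,
    order: ClusterResult,
    style: StyleSpec,
    path: str | Path,
    label_classes: Sequence[str] | None = None,
) -> Path:
    """Heatmap of Jaccard similarities with dendrograms on both axes.

    Rows and columns follow the clustering leaf order.  When
    ``label_classes`` is given (one class per matrix label), tick
    labels are color-coded by class.
    """
    path = Path(path)
    idx = order.leaf_order
    reordered = m.values[np.ix_(idx, idx)]
    labels = [m.labels[i] for i in idx]

    fig = plt.figure(figsize=(8, 8))
    gs = fig.add_gridspec(
        2, 2, width_ratios=[1.2, 4], height_ratios=[1.2, 4],
        hspace=0.02, wspace=0.02,
    )
    ax_top = fig.add_subplot(gs[0, 1])
    ax_left = fig.add_subplot(gs[1, 0])
    ax_heat = fig.add_subplot(gs[1, 1])
    # colorbar in the otherwise-empty top-left corner, clear of row labels
    corner = gs[0, 0].get_position(fig)
    ax_cbar = fig.add_axes(
        (corner.x0 + 0.02, corner.y0 + 0.02, 0.03, corner.height - 0.04)
    )

    with plt.rc_context({"lines.linewidth": 1.0}):
        hierarchy.dendrogram(
            order.linkage, ax=ax_top, orientation="top", no_labels=True,
            link_color_func=lambda _: "#555555",
        )
        hierarchy.dendrogram(
            order.linkage, ax=ax_left, orientation="left", no_labels=True,
            link_color_func=lambda _: "#555555",
        )
    ax_left.invert_yaxis()  # align with heatmap row order (top to bottom)
    for ax in (ax_top, ax_left):
        ax.axis("off")

    im = ax_heat.imshow(
        reordered, cmap=style.colormap, vmin=0.0, vmax=1.0, aspect="auto"
    )
    ax_heat.set_xticks(range(len(labels)), labels, rotation=90,
                       fontsize=style.font_size)
    ax_heat.set_yticks(range(len(labels)), labels, fontsize=style.font_size)
    ax_heat.yaxis.tick_right()
    if label_classes is not None:
        if len(label_classes) != len(m.labels):
            raise SpecError("label_classes must match the matrix labels")
        classes = sorted(set(label_classes))
        cmap = plt.get_cmap("tab10")
        class_color = {c: cmap(i % 10) for i, c in enumerate(classes)}
        ordered_classes = [label_classes[i] for i in idx]
        for tick, cls in zip(ax_heat.get_xticklabels(), ordered_classes):
            tick.set_color(class_color[cls])
        for tick, cls in zip(ax_heat.get_yticklabels(), ordered_classes):
            tick.set_color(class_color[cls])
    fig.colorbar(im, cax=ax_cbar, label="Jaccard similarity")
    fig.savefig(path, format="png", dpi=150, bbox_inches="tight")
    plt.close(fig)
    write_table_csv(m.to_frame().iloc[idx, idx], _sibling_csv(path))
    return path


_MARKERS = ["o", "s", "^", "D", "v", "P", "X", "*"]


def _category(meta: MetadataTable | None, name: str, column: str | None) -> str:
    if column is None:
        return ""
    if meta is None:
        raise SpecError(f"styling column {column!r} requires metadata")
    if column not in meta.property_columns:
        raise SpecError(f"unknown styling column: {column!r}")
    if name in meta.filenames:
        return meta.row(name)[column]
    return name  # grouped results: the label itself is the category


def render_pr_plot(
    results: Sequence[BenchmarkResult],
    meta: MetadataTable | None,
    style: StyleSpec,
    path: str | Path,
) -> Path:
    """Precision (x) vs recall (y) scatter, styled by metadata (+ CSV).

    Marker color follows ``style.color_by`` and marker shape follows
    ``style.shape_by``, each a metadata property column.
    """
    path = Path(path)
    color_cats = [_category(meta, r.name, style.color_by) for r in results]
    shape_cats = [_category(meta, r.name, style.shape_by) for r in results]
    color_levels = sorted(set(color_cats))
    shape_levels = sorted(set(shape_cats))
    cmap = plt.get_cmap("tab10")
    color_of = {c: cmap(i % 10) for i, c in enumerate(color_levels)}
    marker_of = {s: _MARKERS[i % len(_MARKERS)] for i, s in enumerate(shape_levels)}

    fig, ax = plt.subplots(figsize=(6, 6))
    seen = set()
    for r, ccat, scat in zip(results, color_cats, shape_cats):
        label = None
        if (ccat, scat) not in seen:
            seen.add((ccat, scat))
            label = " / ".join(x for x in (ccat, scat) if x) or r.name
        ax.scatter(
            r.precision,
            r.recall,
            color=color_of[ccat],
            marker=marker_of[scat],
            s=60,
            label=label,
        )
    ax.set_xlabel("Precision", fontsize=style.font_size)
    ax.set_ylabel("Recall", fontsize=style.font_size)
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.grid(True, linewidth=0.3, alpha=0.5)
    ax.legend(fontsize=max(6.0, style.font_size - 3), loc="best")
    fig.tight_layout()
    fig.savefig(path, format="png", dpi=150)
    plt.close(fig)
    frame = pd.DataFrame(
        [
            {
                "name": r.name,
                "precision": r.precision,
                "recall": r.recall,
                "n_correct": r.n_correct,
                "n_called": r.n_called,
                "n_golden": r.n_golden,
            }
            for r in results
        ]
    )
    write_table_csv(frame, _sibling_csv(path))
    return path
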