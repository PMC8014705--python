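"""Data-distribution summaries over annotation tables.

A pie summary tallies the distinct values of one table column; a sunburst
aggregates successive columns into a nested count tree, each column one
ring deeper. Both operate on plain :class:`pandas.DataFrame` objects (the
CSV view of a table — see :func:`qualiannot.table_io.to_dataframe`), so
they apply to any table with the right columns, not only tables produced
here.

Label ordering is first appearance in the data (deterministic), with an
optional sort by descending count. Empty cells are tallied under the
reserved ``(empty)`` label. Rendering uses matplotlib; a sunburst written
to a ``.html`` path is wrapped as a standalone SVG page.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.patches import Wedge

from .errors import ValidationError

EMPTY_LABEL = "(empty)"


def _clean(series: pd.Series) -> pd.Series:
    values = series.astype(object).where(series.notna(), EMPTY_LABEL)
    return values.map(lambda v: EMPTY_LABEL if str(v).strip() == "" else str(v))


@dataclass(frozen=True)
class PieSummary:
    """Ordered label→count tally of one column."""

    counts: tuple[tuple[str, int], ...]
    total: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def fractions(self) -> dict[str, float]:
        return {label: count / self.total for label, count in self.counts}


@dataclass
class SunburstNode:
    """One sector of a sunburst: a label, its row count and child sectors."""

    label: str
    count: int
    children: list["SunburstNode"] = field(default_factory=list)

    def child(self, label: str) -> "SunburstNode":
        for node in self.children:
            if node.label == label:
                return node
        raise KeyError(label)

    def depth(self) -> int:
        return 1 + max((c.depth() for c in self.children), default=0)


def pie_counts(df: pd.DataFrame, column: str, sort_by_count: bool = False) -> PieSummary:
    """Count the distinct values of one column, in first-appearance order."""
    if column not in df.columns:
        raise ValidationError(f"unknown column {column!r}")
    values = _clean(df[column])
    counts = values.value_counts(sort=False)  # preserves first-appearance order
    items = list(counts.items())
    if sort_by_count:
        items.sort(key=lambda kv: -kv[1])
    return PieSummary(tuple((str(k), int(v)) for k, v in items), total=int(counts.sum()))


def keyword_presence_counts(df: pd.DataFrame, keyword_columns) -> PieSummary:
    """Tally how many rows assert each boolean keyword column.

    One row may assert several keywords, so the counts are not a partition
    of the rows; ``total`` is the number of assertions, not of rows.
    """
    items = []
    for col in keyword_columns:
        if col not in df.columns:
            raise ValidationError(f"unknown column {col!r}")
        asserted = df[col].map(lambda v: str(v).strip().lower() in {"1", "true"})
        items.append((col, int(asserted.sum())))
    items = [(label, n) for label, n in items if n > 0]
    return PieSummary(tuple(items), total=sum(n for _, n in items))


def sunburst(df: pd.DataFrame, columns) -> SunburstNode:
    """Aggregate successive columns into a nested count tree.

    The virtual root counts all rows; level-*d* nodes are the distinct
    values of ``columns[d-1]`` within their parent's rows, in
    first-appearance order. Every node's count equals the sum of its
    children's counts.
    """
    columns = list(columns)
    if not columns:
        raise ValidationError("sunburst requires at least one column")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"unknown columns {missing}")

    def build(sub: pd.DataFrame, label: str, remaining: list[str]) -> SunburstNode:
        node = SunburstNode(label, len(sub))
        if remaining:
            values = _clean(sub[remaining[0]])
            for value in values.drop_duplicates():
                node.children.append(build(sub[values == value], value, remaining[1:]))
        return node

    return build(df, "", columns)


def render_pie(summary: PieSummary, path) -> None:
    """Write a pie chart (PNG or SVG by extension). Slice angles are count/total."""
    if summary.total == 0:
        raise ValidationError("cannot render an empty pie summary")
    labels = [label for label, _ in summary.counts]
    sizes = [count for _, count in summary.counts]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.pie(sizes, labels=labels, autopct=lambda pct: f"{pct:.1f}%", startangle=90,
           counterclock=False)
    ax.set_aspect("equal")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def _draw_ring(ax, node: SunburstNode, theta0: float, theta1: float, depth: int,
               cmap, color_index: list[int]) -> None:
    span = theta1 - theta0
    start = theta0
    for child in node.children:
        frac = child.count / node.count if node.count else 0.0
        end = start + span * frac
        ax.add_patch(
            Wedge((0, 0), depth + 1, 90 - end, 90 - start, width=0.95,
                  facecolor=cmap(color_index[0] % 20), edgecolor="white")
        )
        color_index[0] += 1
        if span * frac > 8:  # label only sectors wide enough to read
            mid = (start + end) / 2
            import math

            r = depth + 0.5
            ax.text(r * math.sin(math.radians(mid)), r * math.cos(math.radians(mid)),
                    f"{child.label}\n{child.count}", ha="center", va="center", fontsize=8)
        _draw_ring(ax, child, start, end, depth + 1, cmap, color_index)
        start = end


def render_sunburst(root: SunburstNode, path) -> None:
    """Write a nested-ring sunburst; ``.html`` paths get a standalone SVG page."""
    if root.count == 0 or not root.children:
        raise ValidationError("cannot render an empty sunburst")
    depth = root.depth() - 1
    fig, ax = plt.subplots(figsize=(7, 7))
    cmap = plt.get_cmap("tab20")
    _draw_ring(ax, root, 0.0, 360.0, 0, cmap, [0])
    ax.set_xlim(-depth - 1.2, depth + 1.2)
    ax.set_ylim(-depth - 1.2, depth + 1.2)
    ax.set_aspect("equal")
    ax.axis("off")

    path = Path(path)
    if path.suffix.lower() == ".html":
        import io

        buf = io.StringIO()
        fig.savefig(buf, format="svg", bbox_inches="tight")
        path.write_text(
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            "<title>Sunburst</title></head><body>\n"
            f"{buf.getvalue()}\n</body></html>",
            encoding="utf-8",
        )
    else:
        fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
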