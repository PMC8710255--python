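"""Render a dot-plot layout as a multi-panel PDF.

One panel per reference: the concatenated, reordered query contigs run
along the x axis and the reference along the y axis.  Forward matches are
drawn in purple and reverse matches in cyan, the MUMmer-plot convention.
Merged segments render as diagonal line glyphs (anti-diagonal for reverse);
a single-k-mer segment is a k-length tick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
from matplotlib.collections import LineCollection

from .cplot import DotPlotLayout

__all__ = ["PlotStyle", "segment_lines", "build_figure", "render_pdf", "panel_grid"]

Line = tuple[tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class PlotStyle:
    forward_color: str = "purple"
    reverse_color: str = "cyan"

    def __post_init__(self) -> None:
        if self.forward_color == self.reverse_color:
            raise ValueError("forward and reverse colors must differ")


def panel_grid(n_panels: int) -> tuple[int, int]:
    """Near-square (rows, cols) arrangement for ``n_panels`` panels."""
    if n_panels < 1:
        return (1, 1)
    cols = math.ceil(math.sqrt(n_panels))
    rows = math.ceil(n_panels / cols)
    return rows, cols


def segment_lines(layout: DotPlotLayout) -> dict[str, dict[str, list[Line]]]:
    """The drawn-primitive inventory: per reference, per orientation, the
    line endpoints in plot coordinates.

    x coordinates add the cumulative contig offset of the layout's contig
    order; forward segments run bottom-left to top-right, reverse segments
    top-left to bottom-right.
    """
    inventory: dict[str, dict[str, list[Line]]] = {}
    for ref_id in layout.ref_ids:
        fwd: list[Line] = []
        rev: list[Line] = []
        for s in layout.panels[ref_id]:
            off = layout.offsets[s.contig_id]
            x0, x1 = off + s.q_start, off + s.q_end
            if s.orientation == "forward":
                fwd.append(((x0, s.r_start), (x1, s.r_end)))
            else:
                rev.append(((x0, s.r_end), (x1, s.r_start)))
        inventory[ref_id] = {"forward": fwd, "reverse": rev}
    return inventory


def build_figure(layout: DotPlotLayout, style: PlotStyle | None = None):
    """Build the matplotlib figure: a grid of one dot-plot panel per reference."""
    style = style or PlotStyle()
    n = max(len(layout.ref_ids), 1)
    rows, cols = panel_grid(n)
    fig, axes = plt.subplots(
        rows, cols, figsize=(4.0 * cols, 4.0 * rows), squeeze=False
    )
    inventory = segment_lines(layout)
    span = max(layout.query_span, 1)
    boundaries = sorted(layout.offsets.values())
    for i, ref_id in enumerate(layout.ref_ids):
        ax = axes[i // cols][i % cols]
        for orient, color in (
            ("forward", style.forward_color),
            ("reverse", style.reverse_color),
        ):
            lines = inventory[ref_id][orient]
            if lines:
                ax.add_collection(
                    LineCollection(lines, colors=color, linewidths=1.0, label=orient)
                )
        ax.set_xlim(0, span)
        ax.set_ylim(0, max(layout.ref_lengths.get(ref_id, 1), 1))
        ax.set_xticks(boundaries)
        ax.set_xticklabels(
            [cid for cid, _ in sorted(layout.offsets.items(), key=lambda kv: kv[1])],
            rotation=90, fontsize=6,
        )
        ax.set_xlabel(f"query ({span} nt, {len(layout.contig_order)} contigs)")
        ax.set_ylabel(f"{ref_id} ({layout.ref_lengths.get(ref_id, 0)} nt)")
        ax.set_title(f"{ref_id} (k={layout.k})", fontsize=9)
    for j in range(len(layout.ref_ids), rows * cols):
        axes[j // cols][j % cols].set_axis_off()
    fig.tight_layout()
    return fig


def render_pdf(
    layout: DotPlotLayout, style: PlotStyle | None = None, path: str | Path = "cplot.pdf"
) -> None:
    """Write the multi-panel dot plot to a PDF file."""
    fig = build_figure(layout, style)
    try:
        fig.savefig(path, format="pdf")
    finally:
        plt.close(fig)
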