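"""Static rendering and export of a decorated dashboard.

The renderer turns the engine's :class:`~funcdash.subsystems.Dashboard`
into a static site: an index page of top-level panels, one page per
intermediate panel, and one grid page per base subsystem.  Bar graphs are
emitted as deterministic inline SVG whose bar values are copied verbatim
from the engine counts (the renderer never recomputes a tally).  Grid
cells are colored boxes whose opacity encodes the cell score: the linear
map ``0.25 + 0.75 * score``, so a fully supported capability is fully
opaque and a low-scoring one is faint but still visible.

In overlay mode a black line across each plot marks the number of items
common to all *visible* organisms, and a white tick on each bar marks
``total - unique``; the white tick is omitted for two-organism
comparisons.  Overlay statistics are recomputed at render time from the
visible organisms, so hiding an organism changes common/unique counts but
never any per-cell provenance.
"""

from __future__ import annotations

import html
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from funcdash.comparison import OverlayStats, overlay
from funcdash.subsystems import Dashboard, DecoratedNode

#: Fixed colorblind-safe 12-color cycle (Paul Tol's muted + light schemes).
DEFAULT_PALETTE = [
    "#332288", "#117733", "#44AA99", "#88CCEE", "#DDCC77", "#CC6677",
    "#AA4499", "#882255", "#999933", "#661100", "#6699CC", "#888888",
]

_HEX_COLOR = re.compile(r"^#[0-9a-fA-F]{6}$")


@dataclass
class RenderPrefs:
    """Display preferences: colors, names, order, visibility, sizing."""

    colors: dict[str, str] = field(default_factory=dict)
    display_names: dict[str, str] = field(default_factory=dict)
    order: list[str] | None = None
    hidden_organisms: set[str] = field(default_factory=set)
    hidden_panels: set[str] = field(default_factory=set)
    panel_width: int = 260
    panel_height: int = 160
    font_size: int = 11
    overlay_mode: bool = False

    def __post_init__(self):
        for org, color in self.colors.items():
            if not _HEX_COLOR.match(color):
                raise ValueError(f"organism {org}: invalid hex color {color!r}")


def opacity_for(score: float) -> float:
    """Map a cell score in [0, 1] to a box opacity in (0, 1].

    Monotone non-decreasing, ``opacity(1) = 1``, with a 0.25 floor so a
    present-but-unsupported capability still renders visibly:
    ``0.25 + 0.75 * score``.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    return 0.25 + 0.75 * score


def _effective_organisms(dashboard: Dashboard, prefs: RenderPrefs) -> list[str]:
    """Visible organisms in display order (alphabetical by display name
    unless an explicit order is given)."""
    shown = [o for o in dashboard.organisms if o not in prefs.hidden_organisms]
    if prefs.order is not None:
        ordered = [o for o in prefs.order if o in shown]
        if sorted(ordered) != sorted(shown):
            raise ValueError("prefs.order must be a permutation of shown organisms")
        return ordered
    names = {
        o: prefs.display_names.get(o, dashboard.display_names[o]) for o in shown
    }
    return sorted(shown, key=lambda o: (names[o], o))


def _org_colors(
    dashboard: Dashboard, organisms: Sequence[str], prefs: RenderPrefs
) -> dict[str, str]:
    colors = {}
    for i, org in enumerate(organisms):
        colors[org] = (
            prefs.colors.get(org)
            or dashboard.bundles[org].color
            or DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)]
        )
    return colors


# ---------------------------------------------------------------------------
# SVG bar plots
# ---------------------------------------------------------------------------


def bar_plot_svg(
    title: str,
    counts: Mapping[str, int],
    organisms: Sequence[str],
    colors: Mapping[str, str],
    width: int = 260,
    height: int = 160,
    font_size: int = 11,
    overlay_stats: OverlayStats | None = None,
) -> str:
    """Render one subsystem bar plot as deterministic SVG text.

    Every bar carries ``data-org``/``data-count`` attributes holding the
    engine count verbatim.  With ``overlay_stats``, a black line spans the
    plot at the common count and a white tick per bar marks
    ``total - unique`` (omitted when flagged for two-organism mode).
    """
    margin_top, margin_bottom, margin_side = 22, 18, 12
    plot_h = height - margin_top - margin_bottom
    plot_w = width - 2 * margin_side
    max_count = max([counts.get(o, 0) for o in organisms] + [1])
    n = max(len(organisms), 1)
    slot = plot_w / n
    bar_w = slot * 0.7

    def y_of(value: float) -> float:
        return margin_top + plot_h * (1 - value / max_count)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}" '
        f'class="funcdash-plot">',
        f'<text x="{width / 2:.1f}" y="14" text-anchor="middle" '
        f'font-size="{font_size}" font-family="sans-serif">'
        f"{html.escape(title)}</text>",
        f'<line x1="{margin_side}" y1="{y_of(0):.1f}" '
        f'x2="{width - margin_side}" y2="{y_of(0):.1f}" '
        'stroke="#444" stroke-width="1"/>',
    ]
    for i, org in enumerate(organisms):
        count = counts.get(org, 0)
        x = margin_side + i * slot + (slot - bar_w) / 2
        top = y_of(count)
        parts.append(
            f'<rect class="bar" data-org="{html.escape(org)}" '
            f'data-count="{count}" x="{x:.1f}" y="{top:.1f}" '
            f'width="{bar_w:.1f}" height="{y_of(0) - top:.1f}" '
            f'fill="{colors[org]}"/>'
        )
        if (
            overlay_stats is not None
            and not overlay_stats.white_bar_omitted
            and count > 0
        ):
            shared_top = overlay_stats.totals[org] - overlay_stats.unique[org]
            yy = y_of(shared_top)
            parts.append(
                f'<line class="white-line" data-org="{html.escape(org)}" '
                f'data-value="{shared_top}" x1="{x:.1f}" y1="{yy:.1f}" '
                f'x2="{x + bar_w:.1f}" y2="{yy:.1f}" '
                'stroke="#ffffff" stroke-width="2"/>'
            )
    if overlay_stats is not None and overlay_stats.common_count > 0:
        yy = y_of(overlay_stats.common_count)
        parts.append(
            f'<line class="common-line" data-value="{overlay_stats.common_count}" '
            f'x1="{margin_side}" y1="{yy:.1f}" x2="{width - margin_side}" '
            f'y2="{yy:.1f}" stroke="#000000" stroke-width="1.5"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# HTML pages
# ---------------------------------------------------------------------------

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 1.5em; }}
.plots {{ display: flex; flex-wrap: wrap; gap: 1em; }}
.plot-card {{ border: 1px solid #ccc; padding: 0.5em; }}
table.grid {{ border-collapse: collapse; }}
table.grid td, table.grid th {{ border: 1px solid #ddd; padding: 3px 8px; }}
td.cell {{ text-align: center; min-width: 3em; }}
.legend span {{ margin-right: 1em; }}
.footnotes {{ font-size: 85%; color: #555; }}
</style>
</head>
<body>
{body}
</body>
</html>
"""


def _legend(organisms, names, colors) -> str:
    spans = "".join(
        f'<span><svg width="12" height="12"><rect width="12" height="12" '
        f'fill="{colors[o]}"/></svg> {html.escape(names[o])}</span>'
        for o in organisms
    )
    return f'<div class="legend">{spans}</div>'


def _grid_page(
    node: DecoratedNode,
    organisms: Sequence[str],
    names: Mapping[str, str],
    colors: Mapping[str, str],
) -> str:
    grid = node.tally.grid
    head = "".join(f"<th>{html.escape(names[o])}</th>" for o in organisms)
    rows_html = []
    footnotes = []
    for row in grid.rows:
        label = grid.row_labels.get(row, row)
        cells = []
        any_cell = False
        for org in organisms:
            cell = grid.cell(row, org)
            if cell is None:
                cells.append('<td class="cell empty"></td>')
                continue
            any_cell = True
            op = opacity_for(cell.score)
            prov = ", ".join(cell.provenance)
            inner = str(cell.count) if grid.kind != "pathway" else "&#9632;"
            cells.append(
                f'<td class="cell" data-item="{html.escape(row)}" '
                f'data-org="{html.escape(org)}" data-count="{cell.count}" '
                f'data-score="{cell.score:g}" '
                f'style="background-color:{colors[org]};opacity:{op:.3f}" '
                f'title="{html.escape(prov)}">{inner}</td>'
            )
            footnotes.append(
                f"<li><b>{html.escape(label)}</b> / {html.escape(names[org])}: "
                f"{html.escape(prov)}</li>"
            )
        if any_cell:
            rows_html.append(
                f'<tr><th scope="row">{html.escape(label)}</th>{"".join(cells)}</tr>'
            )
    body = (
        f"<h1>{html.escape(node.label)}</h1>"
        + _legend(organisms, names, colors)
        + f'<table class="grid"><tr><th></th>{head}</tr>'
        + "".join(rows_html)
        + "</table>"
        + '<h2>Provenance</h2><ul class="footnotes">'
        + "".join(footnotes)
        + "</ul>"
        + '<p><a href="index.html">back to dashboard</a></p>'
    )
    return _PAGE.format(title=html.escape(node.label), body=body)


def _plot_card(
    node: DecoratedNode,
    organisms,
    colors,
    prefs: RenderPrefs,
    overlay_stats: OverlayStats | None,
    link: str | None,
) -> str:
    svg = bar_plot_svg(
        node.label,
        node.counts,
        organisms,
        colors,
        width=prefs.panel_width,
        height=prefs.panel_height,
        font_size=prefs.font_size,
        overlay_stats=overlay_stats,
    )
    inner = f'<a href="{link}">{svg}</a>' if link else svg
    return f'<div class="plot-card" data-panel="{html.escape(node.id)}">{inner}</div>'


def _node_overlay(
    node: DecoratedNode, organisms: Sequence[str]
) -> OverlayStats | None:
    if len(organisms) < 2:
        return None
    return overlay({o: node.item_sets.get(o, frozenset()) for o in organisms})


def render_dashboard(
    dashboard: Dashboard,
    prefs: RenderPrefs | None = None,
    out_dir: str | Path = "site",
) -> list[Path]:
    """Write the static dashboard site; returns the files written.

    Layout: ``index.html`` with one section per non-omitted top panel and
    one bar plot per child subsystem; ``panel_<id>.html`` for intermediate
    nodes; ``grid_<id>.html`` per base subsystem; a ``data/<id>.json``
    payload per base subsystem with the engine counts and provenance.
    """
    prefs = prefs or RenderPrefs()
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "data").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    organisms = _effective_organisms(dashboard, prefs)
    names = {
        o: prefs.display_names.get(o, dashboard.display_names[o]) for o in organisms
    }
    colors = _org_colors(dashboard, organisms, prefs)
    written: list[Path] = []

    def visible(node: DecoratedNode) -> bool:
        if node.id in prefs.hidden_panels:
            return False
        return any(node.item_sets.get(o) for o in organisms)

    def plot_for(node: DecoratedNode) -> str:
        stats = _node_overlay(node, organisms) if prefs.overlay_mode else None
        if node.tally is not None:
            link = f"grid_{node.id}.html"
        elif node.children:
            link = f"panel_{node.id}.html"
        else:
            link = None
        return _plot_card(node, organisms, colors, prefs, stats, link)

    def write_subtree(node: DecoratedNode):
        if not visible(node):
            return
        if node.tally is not None:
            page = out / f"grid_{node.id}.html"
            page.write_text(
                _grid_page(node, organisms, names, colors), encoding="utf-8"
            )
            written.append(page)
            payload = {
                "id": node.id,
                "label": node.label,
                "organisms": list(organisms),
                "counts": {o: node.counts[o] for o in organisms},
                "rows": [
                    {
                        "item": row,
                        "label": node.tally.grid.row_labels.get(row, row),
                        "cells": {
                            o: {
                                "count": c.count,
                                "score": c.score,
                                "provenance": list(c.provenance),
                            }
                            for o in organisms
                            if (c := node.tally.grid.cell(row, o)) is not None
                        },
                    }
                    for row in node.tally.grid.rows
                ],
            }
            data_file = out / "data" / f"{node.id}.json"
            data_file.write_text(
                json.dumps(payload, indent=1, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            written.append(data_file)
            return
        cards = "".join(plot_for(c) for c in node.children if visible(c))
        body = (
            f"<h1>{html.escape(node.label)}</h1>"
            + _legend(organisms, names, colors)
            + f'<div class="plots">{cards}</div>'
            + '<p><a href="index.html">back to dashboard</a></p>'
        )
        page = out / f"panel_{node.id}.html"
        page.write_text(
            _PAGE.format(title=html.escape(node.label), body=body),
            encoding="utf-8",
        )
        written.append(page)
        for child in node.children:
            write_subtree(child)

    sections = []
    for panel in dashboard.panels:
        if not visible(panel):
            continue
        children = [c for c in panel.children if visible(c)] or [panel]
        cards = "".join(plot_for(c) for c in children)
        sections.append(
            f'<section data-panel="{html.escape(panel.id)}">'
            f"<h2>{html.escape(panel.label)}</h2>"
            f'<div class="plots">{cards}</div></section>'
        )
        for child in panel.children:
            write_subtree(child)
        if panel.tally is not None:
            write_subtree(panel)
    index_body = (
        "<h1>Comparative functional dashboard</h1>"
        + _legend(organisms, names, colors)
        + "".join(sections)
    )
    index = out / "index.html"
    index.write_text(
        _PAGE.format(title="Comparative functional dashboard", body=index_body),
        encoding="utf-8",
    )
    written.append(index)
    return written


# ---------------------------------------------------------------------------
# Panel image export
# ---------------------------------------------------------------------------


def export_panel_image(
    node: DecoratedNode,
    organisms: Sequence[str],
    colors: Mapping[str, str],
    fmt: str,
    path,
    prefs: RenderPrefs | None = None,
    overlay_stats: OverlayStats | None = None,
) -> Path:
    """Export one panel's bar plot as an SVG or PNG file.

    SVG output is the renderer's own deterministic text (two exports of
    the same panel are byte-identical); PNG is rasterized via matplotlib.
    """
    prefs = prefs or RenderPrefs()
    path = Path(path)
    if fmt == "svg":
        svg = bar_plot_svg(
            node.label,
            node.counts,
            organisms,
            colors,
            width=prefs.panel_width,
            height=prefs.panel_height,
            font_size=prefs.font_size,
            overlay_stats=overlay_stats,
        )
        path.write_text(svg + "\n", encoding="utf-8")
        return path
    if fmt == "png":
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(prefs.panel_width / 96, prefs.panel_height / 96))
        values = [node.counts.get(o, 0) for o in organisms]
        ax.bar(
            range(len(organisms)),
            values,
            color=[colors[o] for o in organisms],
        )
        if overlay_stats is not None and overlay_stats.common_count > 0:
            ax.axhline(overlay_stats.common_count, color="black", linewidth=1.5)
        ax.set_title(node.label, fontsize=prefs.font_size)
        ax.set_xticks([])
        fig.savefig(path, format="png", dpi=96)
        plt.close(fig)
        return path
    raise ValueError(f"unsupported image format {fmt!r} (use 'png' or 'svg')")
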