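"""Colour assignment and vector output.

Homology groups receive colours by deterministic golden-angle hue stepping:
successive hues are separated by ~137.5 degrees, giving visually distinct
colours with guaranteed pairwise hue separation of at least 360/(n+1)
degrees for n groups, and identical output for identical seeds.  In the
default ``variable`` highlight mode every variable group gets its own
colour while conserved groups share a single grey; ``conserved`` mode
inverts the emphasis.

The figure is serialised to a single-page PDF through the deterministic
canvas in :mod:`locusplot.pdfcanvas`; an SVG mirror of the same layout is
available for convenience.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .layout import FigureLayout
from .pdfcanvas import PDFCanvas, text_width

GOLDEN_ANGLE = 137.50776405003785  # degrees

#: default colours for PHROG-style functional categories
DEFAULT_CATEGORY_COLORS = {
    "head and packaging": (0.35, 0.55, 0.85),
    "connector": (0.55, 0.75, 0.95),
    "tail": (0.25, 0.65, 0.55),
    "lysis": (0.85, 0.40, 0.35),
    "integration and excision": (0.90, 0.65, 0.25),
    "DNA, RNA and nucleotide metabolism": (0.60, 0.45, 0.80),
    "transcription regulation": (0.80, 0.55, 0.75),
    "moron, auxiliary metabolic gene and host takeover": (0.75, 0.75, 0.30),
    "other": (0.55, 0.55, 0.55),
}


@dataclass
class StyleConfig:
    """Colours, fonts and reproducibility knobs for rendering."""

    conserved_color: tuple[float, float, float] = (0.78, 0.78, 0.78)
    connector_color: tuple[float, float, float] = (0.88, 0.88, 0.88)
    outline_color: tuple[float, float, float] = (0.25, 0.25, 0.25)
    positive_track_color: tuple[float, float, float] = (0.80, 0.30, 0.25)
    negative_track_color: tuple[float, float, float] = (0.30, 0.45, 0.75)
    coverage_color: tuple[float, float, float] = (0.55, 0.10, 0.10)
    text_color: tuple[float, float, float] = (0.10, 0.10, 0.10)
    highlight_mode: str = "variable"  # variable | conserved
    color_intermediate: bool = True
    palette_seed: int = 0
    saturation: float = 0.55
    value: float = 0.88
    category_colors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COLORS)
    )
    color_overrides: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    creation_date: str = "D:20250101000000Z"


def golden_angle_palette(
    n: int, seed: int = 0, saturation: float = 0.55, value: float = 0.88
) -> list[tuple[float, float, float]]:
    """n distinct RGB colours by golden-angle hue stepping from a seed.

    Hues live on an even grid of n slots (so the pairwise circular hue
    separation is exactly 360/n >= 360/(n+1) degrees) and the slots are
    visited in the order induced by golden-angle stepping, which keeps
    consecutively assigned groups far apart on the colour wheel.
    """
    if n <= 0:
        return []
    start = (seed * GOLDEN_ANGLE) % 360.0
    used: set[int] = set()
    colors = []
    for k in range(n):
        target = ((start + k * GOLDEN_ANGLE) % 360.0) / 360.0 * n
        idx = int(target) % n
        while idx in used:
            idx = (idx + 1) % n
        used.add(idx)
        hue = (idx * 360.0 / n) % 360.0
        colors.append(colorsys.hsv_to_rgb(hue / 360.0, saturation, value))
    return colors


def assign_colors(
    group_classes: dict[str, str],
    style: Optional[StyleConfig] = None,
) -> dict[str, tuple[float, float, float]]:
    """Map every homology group to a colour.

    ``group_classes`` maps group_id -> class.  In ``variable`` mode,
    variable (and, by default, intermediate) groups each get a distinct
    palette colour and conserved groups share the grey; ``conserved`` mode
    swaps which side is emphasised.  Explicit colour overrides win.
    Deterministic for a fixed seed.
    """
    style = style or StyleConfig()
    if style.highlight_mode not in ("variable", "conserved"):
        raise ValueError(f"unknown highlight mode {style.highlight_mode!r}")
    if style.highlight_mode == "variable":
        highlighted_classes = {"variable"}
        if style.color_intermediate:
            highlighted_classes.add("intermediate")
    else:
        highlighted_classes = {"conserved"}
    highlighted = sorted(
        g for g, c in group_classes.items() if c in highlighted_classes
    )
    palette = golden_angle_palette(
        len(highlighted), style.palette_seed, style.saturation, style.value
    )
    out: dict[str, tuple[float, float, float]] = {}
    for gid, cls in group_classes.items():
        out[gid] = style.conserved_color
    for gid, color in zip(highlighted, palette):
        out[gid] = color
    for gid, color in style.color_overrides.items():
        out[gid] = color
    return out


# ---------------------------------------------------------------------------
# PDF rendering
# ---------------------------------------------------------------------------


def render_pdf(
    layout: FigureLayout,
    style: Optional[StyleConfig] = None,
    out_path: str | Path = "figure.pdf",
    group_colors: Optional[dict[str, tuple[float, float, float]]] = None,
) -> Path:
    """Render a layout to a single-page vector PDF.

    The page width comes from the canvas profile and the height grows to
    fit the rows; every element is a vector primitive and every label a
    text object.  Output bytes are a pure function of (layout, style).
    """
    style = style or StyleConfig()
    if group_colors is None:
        group_classes = {}
        for row in layout.rows:
            for a in row.arrows:
                if a.group_id:
                    group_classes[a.group_id] = a.group_class or "conserved"
        group_colors = assign_colors(group_classes, style)

    canvas_spec = layout.canvas
    pdf = PDFCanvas(
        canvas_spec.width_units, layout.height_units,
        creation_date=style.creation_date,
    )

    # homology ribbons go beneath everything else
    for conn in layout.connectors:
        pdf.polygon(conn.points, fill=style.connector_color)

    for row in layout.rows:
        # sequence baseline per displayed region
        for _region, x0, x1 in row.segments:
            pdf.line(x0, row.y_center, x1, row.y_center,
                     color=style.outline_color, width=0.6)
        if row.axis is not None:
            for x0, x1 in row.axis.segments:
                pdf.line(x0, row.axis.y, x1, row.axis.y,
                         color=(0.45, 0.45, 0.45), width=0.4)
            for x, lab in row.axis.ticks:
                pdf.line(x, row.axis.y, x, row.axis.y - 2.0,
                         color=(0.45, 0.45, 0.45), width=0.4)
                pdf.text(
                    x - text_width(lab, 4.5) / 2.0, row.axis.y - 7.0, lab,
                    font_size=4.5, color=(0.35, 0.35, 0.35),
                )
        for arrow in row.arrows:
            if arrow.group_id is not None:
                fill = group_colors.get(arrow.group_id, style.conserved_color)
            else:
                fill = (0.92, 0.92, 0.92)
            pdf.polygon(arrow.points, fill=fill, stroke=style.outline_color,
                        line_width=0.35)
        for seg in row.category_segments:
            color = style.category_colors.get(
                seg.category, style.category_colors.get("other", (0.55,) * 3)
            )
            pdf.line(seg.x0, seg.y, seg.x1, seg.y, color=color, width=1.6)
        # locus description, left column
        pdf.text(
            canvas_spec.margin_left,
            row.y_center - canvas_spec.locus_font_size * 0.35,
            _fit_text(row.description, canvas_spec.locus_label_column - 4,
                      canvas_spec.locus_font_size),
            font_size=canvas_spec.locus_font_size,
            font="Helvetica-Bold",
            color=style.text_color,
        )
        for box in row.labels:
            if box.tier > 1:
                pdf.line(
                    box.anchor_x,
                    row.y_center + canvas_spec.arrow_head_half,
                    min(max(box.anchor_x, box.x0), box.x1),
                    box.y0,
                    color=(0.6, 0.6, 0.6),
                    width=0.3,
                )
            pdf.text(
                box.x0, box.y0 + canvas_spec.label_font_size * 0.2, box.text,
                font_size=canvas_spec.label_font_size, color=style.text_color,
            )

    for panel in layout.track_panels:
        _render_panel(pdf, panel, layout, style)

    if layout.scale_bar is not None:
        sb = layout.scale_bar
        pdf.line(sb.x0, sb.y, sb.x1, sb.y, color=style.text_color, width=1.0)
        pdf.line(sb.x0, sb.y - 2, sb.x0, sb.y + 2, color=style.text_color, width=1.0)
        pdf.line(sb.x1, sb.y - 2, sb.x1, sb.y + 2, color=style.text_color, width=1.0)
        pdf.text(sb.x1 + 4, sb.y - 2, sb.label, font_size=6.0,
                 color=style.text_color)

    if layout.legend_categories:
        x = canvas_spec.margin_left
        y = canvas_spec.margin_bottom * 0.4
        for cat in layout.legend_categories:
            color = style.category_colors.get(
                cat, style.category_colors.get("other", (0.55,) * 3)
            )
            pdf.line(x, y + 2.0, x + 10.0, y + 2.0, color=color, width=1.6)
            pdf.text(x + 13.0, y, cat, font_size=5.0, color=style.text_color)
            x += 13.0 + text_width(cat, 5.0) + 10.0

    pdf.save(out_path)
    return Path(out_path)


def _render_panel(pdf: PDFCanvas, panel, layout: FigureLayout,
                  style: StyleConfig) -> None:
    canvas_spec = layout.canvas
    if panel.centred:
        for poly in panel.positive_polys:
            pdf.polygon(poly, fill=style.positive_track_color)
        for poly in panel.negative_polys:
            pdf.polygon(poly, fill=style.negative_track_color)
        pdf.line(
            canvas_spec.plot_left, panel.baseline_y,
            canvas_spec.width_units - canvas_spec.margin_right, panel.baseline_y,
            color=(0.5, 0.5, 0.5), width=0.3, dash=(2.0, 2.0),
        )
    else:
        for poly in panel.positive_polys:
            pdf.polygon(poly, fill=style.coverage_color)
        if panel.polyline:
            pdf.polyline(panel.polyline, color=style.coverage_color, width=0.4)
    pdf.text(
        canvas_spec.margin_left, panel.y0 + panel.height - 6.0, panel.name,
        font_size=6.0, font="Helvetica-Bold", color=style.text_color,
    )
    if panel.annotation:
        w = text_width(panel.annotation, 5.0)
        pdf.text(
            canvas_spec.width_units - canvas_spec.margin_right - w,
            panel.y0 + 1.0, panel.annotation, font_size=5.0,
            color=(0.35, 0.35, 0.35),
        )


def _fit_text(text: str, max_width: float, font_size: float) -> str:
    if text_width(text, font_size) <= max_width:
        return text
    while text and text_width(text + "...", font_size) > max_width:
        text = text[:-1]
    return text + "..." if text else ""


# ---------------------------------------------------------------------------
# SVG mirror
# ---------------------------------------------------------------------------


def render_svg(
    layout: FigureLayout,
    style: Optional[StyleConfig] = None,
    out_path: str | Path = "figure.svg",
    group_colors: Optional[dict[str, tuple[float, float, float]]] = None,
) -> Path:
    """SVG mirror of :func:`render_pdf` (same geometry, y-axis flipped)."""
    style = style or StyleConfig()
    if group_colors is None:
        group_classes = {}
        for row in layout.rows:
            for a in row.arrows:
                if a.group_id:
                    group_classes[a.group_id] = a.group_class or "conserved"
        group_colors = assign_colors(group_classes, style)
    H = layout.height_units
    W = layout.canvas.width_units

    def rgb(c):
        return "rgb(%d,%d,%d)" % tuple(round(255 * x) for x in c)

    def pts(points):
        return " ".join(f"{x:.3f},{H - y:.3f}" for x, y in points)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{W:.0f}" '
        f'height="{H:.0f}" viewBox="0 0 {W:.2f} {H:.2f}">'
    ]
    for conn in layout.connectors:
        parts.append(
            f'<polygon points="{pts(conn.points)}" fill="{rgb(style.connector_color)}"/>'
        )
    for row in layout.rows:
        for _r, x0, x1 in row.segments:
            parts.append(
                f'<line x1="{x0:.3f}" y1="{H - row.y_center:.3f}" '
                f'x2="{x1:.3f}" y2="{H - row.y_center:.3f}" '
                f'stroke="{rgb(style.outline_color)}" stroke-width="0.6"/>'
            )
        for arrow in row.arrows:
            fill = (
                group_colors.get(arrow.group_id, style.conserved_color)
                if arrow.group_id
                else (0.92, 0.92, 0.92)
            )
            parts.append(
                f'<polygon points="{pts(arrow.points)}" fill="{rgb(fill)}" '
                f'stroke="{rgb(style.outline_color)}" stroke-width="0.35"/>'
            )
        for box in row.labels:
            parts.append(
                f'<text x="{box.x0:.3f}" y="{H - box.y0:.3f}" '
                f'font-family="Helvetica" font-size="{layout.canvas.label_font_size}">'
                f"{_xml_escape(box.text)}</text>"
            )
    parts.append("</svg>")
    Path(out_path).write_text("\n".join(parts) + "\n")
    return Path(out_path)


def _xml_escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
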