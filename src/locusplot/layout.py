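"""Geometric layout of locus figures.

Turns ordered loci (with homology groups, classes and tracks already
attached) into a resolution-independent geometry: one row per locus with
gene arrows, automatically arranged labels, homology connectors between
adjacent rows, functional-category strips, per-row axes or a global scale
line, and stacked track panels for the single-locus browser mode.

All geometry is computed in canvas units (PDF points, origin bottom-left)
and is a pure function of its inputs, so identical inputs give identical
layout structures.  The non-negotiable invariants: visible label boxes in a
row never overlap (greedy slide / promote / drop placement), every homology
connector joins two features of the same group in vertically adjacent rows,
and the bp-to-unit scale is shared by all rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import Feature, Locus, Region
from .pdfcanvas import text_width
from .tracks import SignalTrack

# ---------------------------------------------------------------------------
# Canvas
# ---------------------------------------------------------------------------

#: page-profile widths in points (A4 is 595 x 842 pt)
PROFILE_WIDTHS = {"A4p1": 510.0, "A4p2": 247.0, "standard": 595.0}


@dataclass
class CanvasSpec:
    """Page geometry and typography shared by all layout operations."""

    width_units: float = 595.0
    margin_left: float = 20.0
    margin_right: float = 20.0
    margin_top: float = 20.0
    margin_bottom: float = 25.0
    locus_label_column: float = 80.0
    row_pitch: float = 34.0  # vertical space per locus row
    arrow_body_half: float = 3.2
    arrow_head_half: float = 5.0
    arrow_head_units: float = 6.0
    label_font_size: float = 6.0
    locus_font_size: float = 7.0
    label_pad: float = 1.5
    inter_region_gap: float = 6.0
    category_strip_offset: float = 6.5
    category_strip_height: float = 1.8
    scale_bar_fraction: float = 0.25
    track_panel_height: float = 36.0
    mode: str = "full"  # full | compact | browser
    profile: str = "standard"

    @classmethod
    def from_profile(cls, profile: str, mode: str = "full") -> "CanvasSpec":
        if profile not in PROFILE_WIDTHS:
            raise ValueError(
                f"unknown profile {profile!r}; valid: {sorted(PROFILE_WIDTHS)}"
            )
        return cls(width_units=PROFILE_WIDTHS[profile], mode=mode, profile=profile)

    @property
    def usable_width(self) -> float:
        return (
            self.width_units
            - self.margin_left
            - self.margin_right
            - self.locus_label_column
        )

    @property
    def plot_left(self) -> float:
        return self.margin_left + self.locus_label_column


# ---------------------------------------------------------------------------
# Geometry records
# ---------------------------------------------------------------------------


@dataclass
class ArrowGeom:
    feature_id: str
    group_id: Optional[str]
    group_class: Optional[str]
    category: Optional[str]
    strand: str
    x0: float
    x1: float
    points: list[tuple[float, float]]
    label: str
    row_index: int
    clipped: bool = False


@dataclass
class LabelBox:
    feature_id: str
    text: str
    x0: float
    y0: float
    x1: float
    y1: float
    tier: int
    anchor_x: float  # feature midpoint, for the tier-2 leader line

    def overlaps(self, other: "LabelBox") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )


@dataclass
class Connector:
    group_id: str
    upper_feature: str
    lower_feature: str
    points: list[tuple[float, float]]  # quadrilateral


@dataclass
class CategorySegment:
    category: str
    x0: float
    x1: float
    y: float


@dataclass
class AxisSpec:
    y: float
    segments: list[tuple[float, float]]
    ticks: list[tuple[float, str]]


@dataclass
class ScaleBar:
    x0: float
    x1: float
    y: float
    bp: int
    label: str


@dataclass
class TrackPanel:
    kind: str
    name: str
    y0: float  # bottom of panel
    height: float
    baseline_y: float
    polyline: list[tuple[float, float]]
    positive_polys: list[list[tuple[float, float]]]
    negative_polys: list[list[tuple[float, float]]]
    annotation: str
    centred: bool


@dataclass
class RowGeom:
    locus_id: str
    description: str
    y_center: float
    segments: list[tuple[Region, float, float]]  # region, x0, x1
    arrows: list[ArrowGeom] = field(default_factory=list)
    labels: list[LabelBox] = field(default_factory=list)
    category_segments: list[CategorySegment] = field(default_factory=list)
    axis: Optional[AxisSpec] = None


@dataclass
class FigureLayout:
    canvas: CanvasSpec
    height_units: float
    rows: list[RowGeom]
    connectors: list[Connector] = field(default_factory=list)
    scale_bar: Optional[ScaleBar] = None
    legend_categories: list[str] = field(default_factory=list)
    track_panels: list[TrackPanel] = field(default_factory=list)
    units_per_bp: float = 0.0
    dropped_labels: list[str] = field(default_factory=list)

    def all_visible_labels(self) -> list[LabelBox]:
        return [b for row in self.rows for b in row.labels]

    def to_debug_json(self) -> str:
        """Plain-text geometry dump for golden-file comparison."""

        def default(o):
            if hasattr(o, "__dict__"):
                return {k: v for k, v in o.__dict__.items()}
            return str(o)

        return json.dumps(self, default=default, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Coordinate mapping
# ---------------------------------------------------------------------------


class RowTransform:
    """Piecewise-affine bp -> canvas-x mapping for one locus row.

    Regions are laid left-to-right in their given order with a fixed gap;
    a region that wraps the origin of a circular sequence is continuous
    across the seam.  The units-per-bp factor is shared figure-wide.
    """

    def __init__(
        self, locus: Locus, units_per_bp: float, x_left: float, gap: float
    ) -> None:
        if locus.displayed_span() <= 0:
            raise ValueError(f"locus {locus.locus_id}: zero-length displayed span")
        self.locus = locus
        self.units_per_bp = units_per_bp
        self.segments: list[tuple[Region, float, float]] = []
        x = x_left
        for region in locus.regions:
            span = region.span(locus.length_bp)
            x1 = x + span * units_per_bp
            self.segments.append((region, x, x1))
            x = x1 + gap
        self.x_right = x - gap

    def _region_offset(self, region: Region, bp: int) -> Optional[int]:
        """Display offset of base ``bp`` inside ``region``, or None."""
        L = self.locus.length_bp
        if region.wraps_origin:
            if bp >= region.start:
                return bp - region.start
            if bp < region.end:
                return (L - region.start) + bp
            return None
        if region.start <= bp < region.end:
            return bp - region.start
        return None

    def map(self, bp: int) -> Optional[float]:
        """Canvas x of base ``bp`` (left edge), or None if not displayed."""
        for region, x0, _x1 in self.segments:
            off = self._region_offset(region, bp)
            if off is not None:
                return x0 + off * self.units_per_bp
        return None

    def feature_intervals(
        self, feature: Feature
    ) -> list[tuple[float, float, bool, bool]]:
        """Displayed (x0, x1, clipped_left, clipped_right) pieces of a feature.

        Pieces that are contiguous in display space (a feature wrapping the
        origin inside a wrapping region) are merged, so a wrap-flagged
        feature inside a wrap-flagged region yields one continuous piece.
        """
        L = self.locus.length_bp
        if feature.wraps_origin:
            base_intervals = [(feature.start, L), (0, feature.end)]
        else:
            base_intervals = [(feature.start, feature.end)]
        total = feature.span(L)
        out: list[tuple[float, float, bool, bool]] = []
        for region, x0, _x1 in self.segments:
            # region display space as (base_start, base_end, display_offset)
            if region.wraps_origin:
                reg_intervals = [
                    (region.start, L, -region.start),
                    (0, region.end, L - region.start),
                ]
            else:
                reg_intervals = [(region.start, region.end, -region.start)]
            offs = []
            for fs, fe in base_intervals:
                for rs, re, shift in reg_intervals:
                    lo, hi = max(fs, rs), min(fe, re)
                    if lo < hi:
                        offs.append((lo + shift, hi + shift))
            if not offs:
                continue
            offs.sort()
            merged = [list(offs[0])]
            for lo, hi in offs[1:]:
                if lo <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], hi)
                else:
                    merged.append([lo, hi])
            for lo, hi in merged:
                is_partial = (hi - lo) < total  # part of the feature is off-screen
                out.append(
                    (
                        x0 + lo * self.units_per_bp,
                        x0 + hi * self.units_per_bp,
                        is_partial,
                        is_partial,
                    )
                )
        return out


def shared_units_per_bp(loci: Sequence[Locus], canvas: CanvasSpec) -> float:
    """Units per bp such that the widest row spans the usable width."""
    best = None
    for locus in loci:
        n_gaps = len(locus.regions) - 1
        avail = canvas.usable_width - n_gaps * canvas.inter_region_gap
        span = locus.displayed_span()
        if span <= 0:
            raise ValueError(f"locus {locus.locus_id}: zero displayed span")
        upb = avail / span
        if best is None or upb < best:
            best = upb
    return best


# ---------------------------------------------------------------------------
# Arrow geometry
# ---------------------------------------------------------------------------


def arrow_polygon(
    x0: float,
    x1: float,
    strand: str,
    y: float,
    canvas: CanvasSpec,
    clipped_left: bool = False,
    clipped_right: bool = False,
) -> list[tuple[float, float]]:
    """Gene arrow polygon; flat cut edge where the feature was clipped.

    A plus-strand feature points right; a short feature degrades to a pure
    triangle (head length capped at the feature's drawn length).
    """
    bh = canvas.arrow_body_half
    hh = canvas.arrow_head_half
    head = min(canvas.arrow_head_units, x1 - x0)
    if strand == "+":
        if clipped_right:
            return [(x0, y - bh), (x1, y - bh), (x1, y + bh), (x0, y + bh)]
        xh = x1 - head
        return [
            (x0, y - bh), (xh, y - bh), (xh, y - hh), (x1, y),
            (xh, y + hh), (xh, y + bh), (x0, y + bh),
        ]
    if clipped_left:
        return [(x0, y - bh), (x1, y - bh), (x1, y + bh), (x0, y + bh)]
    xh = x0 + head
    return [
        (x1, y - bh), (xh, y - bh), (xh, y - hh), (x0, y),
        (xh, y + hh), (xh, y + bh), (x1, y + bh),
    ]


# ---------------------------------------------------------------------------
# Label rules and placement
# ---------------------------------------------------------------------------


def label_visibility(rows_arrows: Sequence[Sequence[ArrowGeom]],
                     features: dict[str, Feature]) -> dict[str, bool]:
    """Which labels are shown, following the figure conventions.

    Hypothetical / unknown-function proteins are hidden; conserved groups
    are labelled only at their first occurrence in reading order (top row
    first, then left to right) since homology lines mark the repeats;
    variable and intermediate features keep their labels; a per-feature
    ``show_label`` table override beats every rule.
    """
    seen_conserved: set[str] = set()
    visible: dict[str, bool] = {}
    for row in rows_arrows:
        for arrow in sorted(row, key=lambda a: (a.x0, a.feature_id)):
            feat = features[arrow.feature_id]
            if feat.show_label is not None:
                show = feat.show_label
                if feat.group_class == "conserved" and feat.group_id:
                    seen_conserved.add(feat.group_id)
            elif feat.hypothetical or not feat.label:
                show = False
            elif feat.group_class == "conserved" and feat.group_id:
                show = feat.group_id not in seen_conserved
                seen_conserved.add(feat.group_id)
            else:
                show = True
            visible[arrow.feature_id] = show
    return visible


def place_labels(
    row: RowGeom, visible: dict[str, bool], canvas: CanvasSpec
) -> tuple[list[LabelBox], list[str]]:
    """Greedy two-tier label placement with slide, promote, drop.

    Labels are processed left-to-right by feature start.  The preferred
    slot is centred above the feature on tier 1; on collision the box
    slides horizontally by up to half the feature's drawn width; failing
    that it is promoted one label-height higher (tier 2, with a leader
    line); if tier 2 also collides everywhere the label is dropped and
    reported.  The result is overlap-free by construction.
    """
    placed: list[LabelBox] = []
    dropped: list[str] = []
    lh = canvas.label_font_size * 1.25
    tier1_y = row.y_center + canvas.arrow_head_half + canvas.label_pad
    xmin = canvas.margin_left
    xmax = canvas.width_units - canvas.margin_right
    for arrow in sorted(row.arrows, key=lambda a: (a.x0, a.feature_id)):
        if not visible.get(arrow.feature_id) or not arrow.label:
            continue
        w = text_width(arrow.label, canvas.label_font_size)
        mid = (arrow.x0 + arrow.x1) / 2.0
        slide_max = max((arrow.x1 - arrow.x0) / 2.0, 1.0)
        step = max(slide_max / 8.0, 0.25)
        shifts = [0.0]
        k = 1
        while k * step <= slide_max + 1e-9:
            shifts += [k * step, -k * step]
            k += 1
        placed_box = None
        for tier in (1, 2):
            y0 = tier1_y + (tier - 1) * (lh + 1.0)
            for shift in shifts:
                x0 = mid + shift - w / 2.0
                x0 = min(max(x0, xmin), xmax - w)
                box = LabelBox(
                    feature_id=arrow.feature_id, text=arrow.label,
                    x0=x0, y0=y0, x1=x0 + w, y1=y0 + lh,
                    tier=tier, anchor_x=mid,
                )
                if not any(box.overlaps(p) for p in placed):
                    placed_box = box
                    break
            if placed_box is not None:
                break
        if placed_box is None:
            dropped.append(arrow.feature_id)
        else:
            placed.append(placed_box)
    return placed, dropped


# ---------------------------------------------------------------------------
# Connectors, category strip, scale bar
# ---------------------------------------------------------------------------


def homology_connectors(rows: Sequence[RowGeom], canvas: CanvasSpec) -> list[Connector]:
    """Grey homology ribbons between same-group features in adjacent rows.

    When a group has several copies in a row, the pair with the smallest
    x-midpoint distance is connected (ties by feature id).  Chains across
    more than two rows are conveyed transitively, never drawn directly.
    """
    connectors: list[Connector] = []
    for upper, lower in zip(rows, rows[1:]):
        up_groups: dict[str, list[ArrowGeom]] = {}
        for a in upper.arrows:
            if a.group_id:
                up_groups.setdefault(a.group_id, []).append(a)
        lo_groups: dict[str, list[ArrowGeom]] = {}
        for a in lower.arrows:
            if a.group_id:
                lo_groups.setdefault(a.group_id, []).append(a)
        for gid in sorted(set(up_groups) & set(lo_groups)):
            best = None
            for ua in up_groups[gid]:
                for la in lo_groups[gid]:
                    dist = abs((ua.x0 + ua.x1) / 2 - (la.x0 + la.x1) / 2)
                    key = (dist, ua.feature_id, la.feature_id)
                    if best is None or key < best[0]:
                        best = (key, ua, la)
            _, ua, la = best
            y_up = upper.y_center - canvas.arrow_body_half
            y_lo = lower.y_center + canvas.arrow_body_half
            connectors.append(
                Connector(
                    group_id=gid,
                    upper_feature=ua.feature_id,
                    lower_feature=la.feature_id,
                    points=[
                        (ua.x0, y_up), (ua.x1, y_up),
                        (la.x1, y_lo), (la.x0, y_lo),
                    ],
                )
            )
    return connectors


def category_strip(row: RowGeom, canvas: CanvasSpec) -> list[CategorySegment]:
    """Coloured sub-lines beneath categorised ORFs (hidden in compact mode)."""
    if canvas.mode == "compact":
        return []
    y = row.y_center - canvas.category_strip_offset
    return [
        CategorySegment(category=a.category, x0=a.x0, x1=a.x1, y=y)
        for a in row.arrows
        if a.category
    ]


def nice_scale_bar(units_per_bp: float, canvas: CanvasSpec) -> tuple[int, str]:
    """Largest 1-2-5 x 10^k bp length fitting the configured width fraction."""
    limit = canvas.scale_bar_fraction * canvas.width_units
    best = 1
    for k in range(0, 9):
        for m in (1, 2, 5):
            v = m * 10 ** k
            if v * units_per_bp <= limit:
                best = max(best, v)
    if best >= 1000:
        label = f"{best / 1000:g} kbp"
    else:
        label = f"{best} bp"
    return best, label


def make_scale_bar(units_per_bp: float, canvas: CanvasSpec, y: float) -> ScaleBar:
    bp, label = nice_scale_bar(units_per_bp, canvas)
    x0 = canvas.plot_left
    return ScaleBar(x0=x0, x1=x0 + bp * units_per_bp, y=y, bp=bp, label=label)


def _row_axis(row: RowGeom, locus: Locus, canvas: CanvasSpec) -> AxisSpec:
    y = row.y_center - canvas.category_strip_offset - 3.0
    segments = [(x0, x1) for _r, x0, x1 in row.segments]
    ticks = []
    for region, x0, x1 in row.segments:
        ticks.append((x0, f"{region.start + 1}"))
        ticks.append((x1, f"{region.end if not region.wraps_origin else region.end}"))
    return AxisSpec(y=y, segments=segments, ticks=ticks)


# ---------------------------------------------------------------------------
# Figure assembly
# ---------------------------------------------------------------------------


def build_comparative_layout(
    loci: Sequence[Locus],
    order: Sequence[str],
    canvas: CanvasSpec,
) -> FigureLayout:
    """Assemble the multi-row comparative figure layout.

    ``loci`` must already carry group ids / classes / categories; ``order``
    is the final top-to-bottom row order (dendrogram leaf order or a manual
    override).
    """
    by_id = {l.locus_id: l for l in loci}
    missing = [lid for lid in order if lid not in by_id]
    if missing:
        raise ValueError(f"order names unknown loci: {missing}")
    ordered = [by_id[lid] for lid in order]
    upb = shared_units_per_bp(ordered, canvas)
    n = len(ordered)
    compact = canvas.mode == "compact"
    used_categories: list[str] = []
    legend_h = 0.0
    scale_h = 14.0 if compact else 0.0
    height = canvas.margin_top + n * canvas.row_pitch + canvas.margin_bottom + scale_h

    rows: list[RowGeom] = []
    features_index: dict[str, Feature] = {}
    for i, locus in enumerate(ordered):
        y_center = height - canvas.margin_top - (i + 0.5) * canvas.row_pitch
        tr = RowTransform(locus, upb, canvas.plot_left, canvas.inter_region_gap)
        row = RowGeom(
            locus_id=locus.locus_id,
            description=locus.description or locus.locus_id,
            y_center=y_center,
            segments=tr.segments,
        )
        for feat in locus.features:
            features_index[feat.feature_id] = feat
            for x0, x1, cl, cr in tr.feature_intervals(feat):
                row.arrows.append(
                    ArrowGeom(
                        feature_id=feat.feature_id,
                        group_id=feat.group_id,
                        group_class=feat.group_class,
                        category=feat.category,
                        strand=feat.strand,
                        x0=x0,
                        x1=x1,
                        points=arrow_polygon(
                            x0, x1, feat.strand, y_center, canvas, cl, cr
                        ),
                        label=feat.label,
                        row_index=i,
                        clipped=cl or cr,
                    )
                )
        if not compact:
            row.category_segments = category_strip(row, canvas)
            for seg in row.category_segments:
                if seg.category not in used_categories:
                    used_categories.append(seg.category)
            row.axis = _row_axis(row, locus, canvas)
        rows.append(row)

    visible = label_visibility([r.arrows for r in rows], features_index)
    dropped_all: list[str] = []
    for row in rows:
        row.labels, dropped = place_labels(row, visible, canvas)
        dropped_all.extend(dropped)

    layout = FigureLayout(
        canvas=canvas,
        height_units=height,
        rows=rows,
        connectors=homology_connectors(rows, canvas),
        legend_categories=sorted(used_categories),
        units_per_bp=upb,
        dropped_labels=dropped_all,
    )
    if compact:
        layout.scale_bar = make_scale_bar(upb, canvas, canvas.margin_bottom + 4.0)
    return layout


def build_browser_layout(
    locus: Locus,
    tracks: Sequence[SignalTrack],
    canvas: CanvasSpec,
    gc_tracks: Sequence[SignalTrack] = (),
) -> FigureLayout:
    """Single-locus browser layout: gene map stacked over track panels.

    Panel order, top to bottom: functional-category strip + gene map, GC
    content, GC skew, then the signal tracks in input order.  Centred
    tracks are drawn as filled areas, with separate polygon sets for values
    above and below the raw mean.
    """
    if canvas.mode != "browser":
        canvas.mode = "browser"
    all_tracks = list(gc_tracks) + list(tracks)
    n_panels = len(all_tracks)
    height = (
        canvas.margin_top
        + canvas.row_pitch
        + n_panels * (canvas.track_panel_height + 6.0)
        + canvas.margin_bottom
    )
    upb = shared_units_per_bp([locus], canvas)
    y_center = height - canvas.margin_top - 0.5 * canvas.row_pitch
    tr = RowTransform(locus, upb, canvas.plot_left, canvas.inter_region_gap)
    row = RowGeom(
        locus_id=locus.locus_id,
        description=locus.description or locus.locus_id,
        y_center=y_center,
        segments=tr.segments,
    )
    features_index = {}
    for feat in locus.features:
        features_index[feat.feature_id] = feat
        for x0, x1, cl, cr in tr.feature_intervals(feat):
            row.arrows.append(
                ArrowGeom(
                    feature_id=feat.feature_id,
                    group_id=feat.group_id,
                    group_class=feat.group_class,
                    category=feat.category,
                    strand=feat.strand,
                    x0=x0, x1=x1,
                    points=arrow_polygon(x0, x1, feat.strand, y_center, canvas, cl, cr),
                    label=feat.label,
                    row_index=0,
                    clipped=cl or cr,
                )
            )
    row.category_segments = category_strip(row, canvas)
    visible = label_visibility([row.arrows], features_index)
    row.labels, dropped = place_labels(row, visible, canvas)

    panels: list[TrackPanel] = []
    y_top = height - canvas.margin_top - canvas.row_pitch
    for k, track in enumerate(all_tracks):
        y0 = y_top - (k + 1) * (canvas.track_panel_height + 6.0) + 6.0
        panels.append(_track_panel(track, tr, y0, canvas))
    used = []
    for seg in row.category_segments:
        if seg.category not in used:
            used.append(seg.category)
    return FigureLayout(
        canvas=canvas,
        height_units=height,
        rows=[row],
        legend_categories=sorted(used),
        track_panels=panels,
        units_per_bp=upb,
        dropped_labels=dropped,
    )


def _track_panel(
    track: SignalTrack, tr: RowTransform, y0: float, canvas: CanvasSpec
) -> TrackPanel:
    h = canvas.track_panel_height
    vals = track.values
    n = len(vals)
    if n == 0:
        return TrackPanel(
            kind=track.kind, name=track.name, y0=y0, height=h,
            baseline_y=y0, polyline=[], positive_polys=[], negative_polys=[],
            annotation="", centred=track.centred,
        )
    vmin = float(vals.min())
    vmax = float(vals.max())
    if track.centred:
        amp = max(abs(vmin), abs(vmax), 1e-12)
        lo, hi = -amp, amp
        baseline_frac = 0.5
    else:
        lo, hi = min(0.0, vmin), max(vmax, 1e-12)
        baseline_frac = (0.0 - lo) / (hi - lo)
    span_y = hi - lo if hi > lo else 1.0
    baseline_y = y0 + baseline_frac * h

    def ty(v: float) -> float:
        return y0 + (v - lo) / span_y * h

    x_left = tr.segments[0][1]
    pts = []
    for i, v in enumerate(vals):
        bp = track.span.start + i * track.step
        x = x_left + (bp - track.span.start) * tr.units_per_bp
        pts.append((x, ty(float(v))))
    pos_polys, neg_polys = [], []
    i = 0
    while i < n:
        sign = 1 if vals[i] > 0 else (-1 if vals[i] < 0 else 0)
        j = i
        while j + 1 < n and (
            (vals[j + 1] > 0) == (sign > 0) and (vals[j + 1] < 0) == (sign < 0)
        ):
            j += 1
        if sign != 0:
            poly = (
                [(pts[i][0], baseline_y)]
                + pts[i : j + 1]
                + [(pts[j][0], baseline_y)]
            )
            (pos_polys if sign > 0 else neg_polys).append(poly)
        i = j + 1
    rmin, rmax = track.value_range
    annotation = (
        f"range: {rmin:.3g}..{rmax:.3g}, mean: {track.mean_value:.3g}"
    )
    return TrackPanel(
        kind=track.kind, name=track.name, y0=y0, height=h,
        baseline_y=baseline_y, polyline=pts,
        positive_polys=pos_polys, negative_polys=neg_polys,
        annotation=annotation, centred=track.centred,
    )
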