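"""Coordinate mapping, arrows, label rules and placement, connectors,
scale bar, and the browser panel stack."""

import numpy as np
import pytest

from locusplot import layout as lay
from locusplot import tracks
from locusplot.model import Feature, Locus, Region
from tests.conftest import make_simple_locus


def bare_canvas(width=100.0, mode="full"):
    return lay.CanvasSpec(
        width_units=width, margin_left=0.0, margin_right=0.0,
        locus_label_column=0.0, mode=mode,
    )


class TestMapCoords:
    def test_affine_midpoint(self):
        locus = make_simple_locus(length=1000)
        canvas = bare_canvas()
        upb = lay.shared_units_per_bp([locus], canvas)
        tr = lay.RowTransform(locus, upb, canvas.plot_left, canvas.inter_region_gap)
        assert tr.map(500) == pytest.approx(50.0)
        assert tr.map(0) == pytest.approx(0.0)

    def test_two_regions_share_scale(self):
        locus = make_simple_locus(length=1000)
        locus.regions = [Region(0, 400), Region(500, 900)]
        canvas = bare_canvas()
        upb = lay.shared_units_per_bp([locus], canvas)
        tr = lay.RowTransform(locus, upb, canvas.plot_left, canvas.inter_region_gap)
        (r1, x10, x11), (r2, x20, x21) = tr.segments
        assert (x11 - x10) == pytest.approx(x21 - x20)  # same units/bp
        assert x20 - x11 == pytest.approx(canvas.inter_region_gap)

    def test_wrapping_region_is_continuous_at_seam(self):
        """Circular 100 bp locus, region 90->10: no gap at the origin."""
        locus = make_simple_locus(length=100, circular=True)
        locus.regions = [Region(90, 10, wraps_origin=True)]
        canvas = bare_canvas()
        upb = lay.shared_units_per_bp([locus], canvas)
        tr = lay.RowTransform(locus, upb, canvas.plot_left, canvas.inter_region_gap)
        assert locus.displayed_span() == 20
        x99 = tr.map(99)
        x0 = tr.map(0)
        assert x0 - x99 == pytest.approx(upb)  # one-base step across the seam
        assert tr.map(50) is None  # outside the window

    def test_zero_span_rejected(self):
        locus = make_simple_locus(length=100)
        locus.regions = [Region(5, 5)]
        with pytest.raises(ValueError):
            lay.RowTransform(locus, 1.0, 0.0, 5.0)

    def test_wrapping_feature_in_wrapping_region_is_one_piece(self):
        locus = make_simple_locus(length=100, circular=True)
        locus.regions = [Region(90, 10, wraps_origin=True)]
        feat = Feature(feature_id="w", type="CDS", start=95, end=5, strand="+",
                       protein_seq="M", wraps_origin=True)
        canvas = bare_canvas()
        upb = lay.shared_units_per_bp([locus], canvas)
        tr = lay.RowTransform(locus, upb, canvas.plot_left, canvas.inter_region_gap)
        pieces = tr.feature_intervals(feat)
        assert len(pieces) == 1
        x0, x1, _cl, _cr = pieces[0]
        assert x1 - x0 == pytest.approx(10 * upb)


class TestArrowGeometry:
    def test_plus_strand_seven_point_arrow(self):
        canvas = bare_canvas()
        pts = lay.arrow_polygon(0.0, 50.0, "+", 10.0, canvas)
        assert len(pts) == 7
        assert max(x for x, _y in pts) == 50.0  # tip on the right
        assert pts[3] == (50.0, 10.0)

    def test_minus_strand_is_mirror(self):
        canvas = bare_canvas()
        plus = lay.arrow_polygon(0.0, 50.0, "+", 10.0, canvas)
        minus = lay.arrow_polygon(0.0, 50.0, "-", 10.0, canvas)
        mirrored = sorted((50.0 - x, y) for x, y in plus)
        assert sorted(minus) == pytest.approx(mirrored)

    def test_clipped_feature_has_flat_edge(self):
        canvas = bare_canvas()
        pts = lay.arrow_polygon(0.0, 50.0, "+", 10.0, canvas, clipped_right=True)
        assert len(pts) == 4  # rectangle: headless cut at the boundary

    def test_short_gene_degrades_to_triangle(self):
        canvas = bare_canvas()
        pts = lay.arrow_polygon(0.0, 2.0, "+", 10.0, canvas)
        xs = sorted({x for x, _y in pts})
        assert xs[0] == 0.0 and xs[-1] == 2.0


def _three_locus_rows():
    """Three loci sharing a conserved group plus variable/hypothetical mix."""
    gene = lambda s, e, label, group, cls: (s, e, "+", label, group, cls)
    l1 = make_simple_locus("L1", 1000, [
        gene(50, 300, "terminase", "G1", "conserved"),
        gene(400, 700, "cargo one", "G2", "variable"),
        gene(750, 950, "hypothetical protein", "G3", "variable"),
    ])
    l1.features[2].hypothetical = True
    l2 = make_simple_locus("L2", 1000, [
        gene(60, 310, "terminase", "G1", "conserved"),
        gene(420, 720, "cargo two", "G4", "variable"),
    ])
    l3 = make_simple_locus("L3", 1000, [
        gene(40, 290, "terminase", "G1", "conserved"),
    ])
    return [l1, l2, l3]


class TestLabelRules:
    def test_conserved_label_first_occurrence_only(self):
        loci = _three_locus_rows()
        canvas = lay.CanvasSpec()
        fig = lay.build_comparative_layout(loci, ["L1", "L2", "L3"], canvas)
        terminase_rows = [
            b for row in fig.rows for b in row.labels if b.text == "terminase"
        ]
        assert len(terminase_rows) == 1
        assert terminase_rows[0].feature_id == "L1_g1"

    def test_hypothetical_labels_hidden(self):
        loci = _three_locus_rows()
        fig = lay.build_comparative_layout(loci, ["L1", "L2", "L3"],
                                           lay.CanvasSpec())
        texts = [b.text for b in fig.all_visible_labels()]
        assert "hypothetical protein" not in texts
        assert "cargo one" in texts and "cargo two" in texts

    def test_show_label_override_beats_every_rule(self):
        loci = _three_locus_rows()
        loci[0].features[2].show_label = True  # force the hypothetical label
        fig = lay.build_comparative_layout(loci, ["L1", "L2", "L3"],
                                           lay.CanvasSpec())
        texts = [b.text for b in fig.all_visible_labels()]
        assert "hypothetical protein" in texts


class TestPlaceLabels:
    def _overlaps(self, fig):
        boxes = fig.all_visible_labels()
        return [
            (a.feature_id, b.feature_id)
            for i, a in enumerate(boxes)
            for b in boxes[i + 1 :]
            if a.overlaps(b) and (a.tier, b.tier)
        ]

    def test_distant_genes_both_tier1(self):
        locus = make_simple_locus("L1", 2000, [
            (0, 300, "+", "portal", "G1", "variable"),
            (1500, 1900, "+", "holin", "G2", "variable"),
        ])
        fig = lay.build_comparative_layout([locus], ["L1"], lay.CanvasSpec())
        assert all(b.tier == 1 for b in fig.all_visible_labels())
        assert not self._overlaps(fig)

    def test_adjacent_wide_labels_do_not_overlap(self):
        locus = make_simple_locus("L1", 1000, [
            (0, 100, "+", "very long protein label number one", "G1", "variable"),
            (110, 210, "+", "very long protein label number two", "G2", "variable"),
            (220, 320, "+", "very long protein label number three", "G3", "variable"),
        ])
        fig = lay.build_comparative_layout([locus], ["L1"], lay.CanvasSpec())
        assert not self._overlaps(fig)
        assert len(fig.all_visible_labels()) + len(fig.dropped_labels) == 3

    def test_pathological_crowding_stays_overlap_free(self):
        """50 overlapping features in ~10 units: some labels drop, none
        overlap."""
        genes = [
            (i * 2, i * 2 + 40, "+", f"crowded protein {i}", f"G{i}", "variable")
            for i in range(50)
        ]
        locus = make_simple_locus("L1", 140, genes)
        canvas = lay.CanvasSpec(
            width_units=10.0, margin_left=0, margin_right=0,
            locus_label_column=0,
        )
        fig = lay.build_comparative_layout([locus], ["L1"], canvas)
        assert not self._overlaps(fig)
        assert fig.dropped_labels  # crowding forces drops


class TestConnectors:
    def test_adjacent_rows_only(self):
        loci = _three_locus_rows()
        fig = lay.build_comparative_layout(loci, ["L1", "L2", "L3"],
                                           lay.CanvasSpec())
        g1 = [c for c in fig.connectors if c.group_id == "G1"]
        assert len(g1) == 2  # rows 1-2 and 2-3, never 1-3

    def test_group_missing_from_middle_row_gives_no_connector(self):
        loci = _three_locus_rows()
        # G2 only in row 1; G4 only in row 2 -> no cross connectors for them
        fig = lay.build_comparative_layout(loci, ["L1", "L2", "L3"],
                                           lay.CanvasSpec())
        assert all(c.group_id == "G1" for c in fig.connectors)

    def test_paralogue_connects_nearest_copy(self):
        l1 = make_simple_locus("L1", 1000, [
            (600, 700, "+", "x", "GP", "conserved"),
        ])
        l2 = make_simple_locus("L2", 1000, [
            (0, 100, "+", "x", "GP", "conserved"),
            (580, 680, "+", "x", "GP", "conserved"),
        ])
        fig = lay.build_comparative_layout([l1, l2], ["L1", "L2"],
                                           lay.CanvasSpec())
        (conn,) = fig.connectors
        assert conn.lower_feature == "L2_g2"  # the copy nearer in x

    def test_connector_anchors_share_group(self):
        loci = _three_locus_rows()
        fig = lay.build_comparative_layout(loci, ["L1", "L2", "L3"],
                                           lay.CanvasSpec())
        feats = {f.feature_id: f for l in loci for f in l.features}
        for c in fig.connectors:
            assert feats[c.upper_feature].group_id == c.group_id
            assert feats[c.lower_feature].group_id == c.group_id


class TestScaleBar:
    def test_nice_ladder_40kbp(self):
        canvas = bare_canvas(width=100.0)
        upb = 100.0 / 40000.0
        bp, label = lay.nice_scale_bar(upb, canvas)
        assert bp == 10000 and label == "10 kbp"

    def test_nice_ladder_900bp(self):
        canvas = bare_canvas(width=100.0)
        upb = 100.0 / 900.0
        bp, label = lay.nice_scale_bar(upb, canvas)
        assert bp == 200 and label == "200 bp"

    def test_bar_never_exceeds_fraction(self, rng):
        canvas = bare_canvas(width=100.0)
        for span in rng.integers(100, 500_000, size=20):
            upb = canvas.usable_width / float(span)
            bp, _ = lay.nice_scale_bar(upb, canvas)
            assert bp * upb <= canvas.scale_bar_fraction * canvas.width_units + 1e-9

    def test_compact_mode_has_scale_bar_and_no_strip(self):
        loci = _three_locus_rows()
        for l in loci:
            for f in l.features:
                f.category = "lysis"
        canvas = lay.CanvasSpec(mode="compact")
        fig = lay.build_comparative_layout(loci, ["L1", "L2", "L3"], canvas)
        assert fig.scale_bar is not None
        assert all(not row.category_segments for row in fig.rows)
        assert all(row.axis is None for row in fig.rows)


class TestSharedScale:
    def test_units_per_bp_constant_across_rows(self):
        loci = [
            make_simple_locus("L1", 4000, [(0, 900, "+", "a", "G1", "variable")]),
            make_simple_locus("L2", 2000, [(0, 900, "+", "b", "G2", "variable")]),
        ]
        fig = lay.build_comparative_layout(loci, ["L1", "L2"], lay.CanvasSpec())
        widths = []
        for row in fig.rows:
            (arrow,) = row.arrows
            widths.append((arrow.x1 - arrow.x0) / 900.0)
        assert widths[0] == pytest.approx(widths[1], abs=1e-9)
        # the longer locus spans twice the drawn width
        r1, r2 = fig.rows
        assert (r1.segments[0][2] - r1.segments[0][1]) == pytest.approx(
            2 * (r2.segments[0][2] - r2.segments[0][1])
        )


class TestBrowserPanels:
    def _locus(self):
        return make_simple_locus(
            "L1", 400, [(10, 100, "+", "portal", "G1", "conserved")]
        )

    def test_panel_order_gc_then_signals(self):
        locus = self._locus()
        gc = [
            tracks.centre_track(tracks.gc_content(locus.sequence, 3, "L1")),
            tracks.centre_track(tracks.gc_skew(locus.sequence, 3, "L1")),
        ]
        sig = [
            tracks.SignalTrack("L1", Region(0, 400), np.ones(400), name=f"s{i}")
            for i in range(3)
        ]
        canvas = lay.CanvasSpec(mode="browser")
        fig = lay.build_browser_layout(locus, sig, canvas, gc_tracks=gc)
        kinds = [p.kind for p in fig.track_panels]
        assert kinds[:2] == ["gc_content", "gc_skew"]
        assert [p.name for p in fig.track_panels[2:]] == ["s0", "s1", "s2"]
        ys = [p.y0 for p in fig.track_panels]
        assert ys == sorted(ys, reverse=True)  # stacked downward

    def test_no_signal_tracks_gives_gc_only(self):
        locus = self._locus()
        gc = [tracks.centre_track(tracks.gc_content(locus.sequence, 3, "L1"))]
        fig = lay.build_browser_layout(
            locus, [], lay.CanvasSpec(mode="browser"), gc_tracks=gc
        )
        assert len(fig.track_panels) == 1

    def test_centred_positive_fill_matches_sign_of_raw_deviation(self):
        """Area above the baseline appears exactly where raw > mean."""
        locus = self._locus()
        raw = tracks.gc_skew(locus.sequence, 5, "L1")
        centred = tracks.centre_track(raw)
        fig = lay.build_browser_layout(
            locus, [], lay.CanvasSpec(mode="browser"), gc_tracks=[centred]
        )
        panel = fig.track_panels[0]
        base = panel.baseline_y
        for poly in panel.positive_polys:
            assert all(y >= base - 1e-9 for _x, y in poly)
        for poly in panel.negative_polys:
            assert all(y <= base + 1e-9 for _x, y in poly)
        n_pos_runs = _count_sign_runs(centred.values, +1)
        assert len(panel.positive_polys) == n_pos_runs


def _count_sign_runs(values, sign):
    runs, prev = 0, 0
    for v in values:
        s = 1 if v > 0 else (-1 if v < 0 else 0)
        if s == sign and prev != sign:
            runs += 1
        prev = s
    return runs


class TestDeterminism:
    def test_identical_inputs_identical_layout_dump(self):
        loci1 = _three_locus_rows()
        loci2 = _three_locus_rows()
        fig1 = lay.build_comparative_layout(loci1, ["L1", "L2", "L3"],
                                            lay.CanvasSpec())
        fig2 = lay.build_comparative_layout(loci2, ["L1", "L2", "L3"],
                                            lay.CanvasSpec())
        assert fig1.to_debug_json() == fig2.to_debug_json()
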