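"""End-to-end pipeline orchestration.

``run_comparative`` mirrors the full workflow: parse annotated loci, assign
protein homology groups (built-in clusterer, predefined table, or external
adapter), compute the proteome-similarity matrix, order and cluster the
sequences by UPGMA, classify groups per cluster, lay out and render the
figure, and emit the similarity matrix, dendrogram, class table and the
feature/locus annotation tables it used — so any run can be reproduced and
hand-edited by feeding its own tables back in.

``run_browser`` is the single-locus mode: gene map stacked over GC content,
GC skew, and any number of signal tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import annotation_io, homology, proteome, tracks
from .config import Parameters
from .layout import build_browser_layout, build_comparative_layout
from .model import Locus, Region, mark_hypothetical
from .render import assign_colors, render_pdf

logger = logging.getLogger("locusplot")


@dataclass
class ComparativeResult:
    loci: list[Locus]
    assignment: homology.GroupAssignment
    matrix: proteome.ProteomeMatrix
    classes: dict[str, dict[str, tuple[float, str]]]
    order: list[str]
    layout: object
    outputs: dict[str, Path] = field(default_factory=dict)


def collect_input_files(
    gb: Sequence[str | Path] = (), gff: Sequence[str | Path] = ()
) -> list[tuple[str, Path]]:
    """Expand files/directories into (format, path) pairs, sorted."""
    out: list[tuple[str, Path]] = []
    for fmt, paths, exts in (
        ("genbank", gb, (".gb", ".gbk", ".gbff", ".genbank")),
        ("gff", gff, (".gff", ".gff3")),
    ):
        for p in paths:
            p = Path(p)
            if p.is_dir():
                for child in sorted(p.iterdir()):
                    if child.suffix.lower() in exts:
                        out.append((fmt, child))
            elif p.exists():
                out.append((fmt, p))
            else:
                raise FileNotFoundError(f"input not found: {p}")
    if not out:
        raise ValueError("no input files given (need GenBank or extended GFF)")
    return out


def parse_inputs(
    gb: Sequence[str | Path] = (), gff: Sequence[str | Path] = ()
) -> list[Locus]:
    loci: list[Locus] = []
    for fmt, path in collect_input_files(gb, gff):
        if fmt == "genbank":
            loci.extend(annotation_io.parse_genbank(path))
        else:
            loci.extend(annotation_io.parse_extended_gff(path))
    seen: dict[str, int] = {}
    for locus in loci:
        if locus.locus_id in seen:
            raise ValueError(f"duplicate locus id {locus.locus_id!r} in input")
        seen[locus.locus_id] = 1
    disambiguate_feature_ids(loci)
    return loci


def disambiguate_feature_ids(loci: Sequence[Locus]) -> None:
    """Prefix colliding feature ids with their locus id.

    Group tables are keyed globally by feature id, so ids repeated across
    loci (common with generic locus_tag schemes) must be made unique.
    """
    counts: dict[str, int] = {}
    for locus in loci:
        for f in locus.features:
            counts[f.feature_id] = counts.get(f.feature_id, 0) + 1
    for locus in loci:
        for f in locus.features:
            if counts[f.feature_id] > 1:
                f.feature_id = f"{locus.locus_id}:{f.feature_id}"


def run_comparative(
    loci: Optional[list[Locus]] = None,
    gb: Sequence[str | Path] = (),
    gff: Sequence[str | Path] = (),
    outdir: Optional[str | Path] = None,
    params: Optional[Parameters] = None,
    feature_table: Optional[str | Path] = None,
    locus_table: Optional[str | Path] = None,
    cluster_table: Optional[str | Path] = None,
    no_cluster: bool = False,
    external_command: Optional[str] = None,
    render: bool = True,
) -> ComparativeResult:
    """Run the comparative pipeline; see the module docstring.

    ``loci`` may be passed directly (API use) instead of file inputs.  With
    ``no_cluster`` the group ids must come from the feature/cluster tables;
    uncovered CDS get singleton groups.
    """
    params = params or Parameters()
    if loci is None:
        loci = parse_inputs(gb, gff)
    mark_hypothetical(loci, params.hypothetical_patterns)
    overrides = annotation_io.load_tables(feature_table, locus_table, cluster_table)
    annotation_io.apply_overrides(loci, overrides)
    n_cds = sum(len(l.cds_features) for l in loci)
    logger.info("parsed %d loci, %d CDS features", len(loci), n_cds)

    # --- homology groups ---------------------------------------------------
    proteins = [
        (f.feature_id, f.protein_seq) for l in loci for f in l.cds_features
    ]
    table_groups = dict(overrides.groups)
    for l in loci:
        for f in l.cds_features:
            if f.group_id is not None:
                table_groups.setdefault(f.feature_id, f.group_id)
    if cluster_table is not None or (no_cluster and table_groups):
        assignment = homology.from_table(
            table_groups, all_cds_ids=[fid for fid, _ in proteins]
        )
    elif no_cluster:
        assignment = homology.from_table(
            {}, all_cds_ids=[fid for fid, _ in proteins]
        )
    elif external_command:
        assignment = homology.external_adapter(proteins, external_command)
    else:
        assignment = homology.cluster_builtin(
            proteins, params.min_identity, params.min_coverage
        )
    homology.assign_groups_to_loci(loci, assignment)
    logger.info(
        "homology: %d proteins in %d groups (%s)",
        len(proteins), assignment.n_groups(), assignment.method,
    )

    # --- proteome composition ----------------------------------------------
    group_sets = {l.locus_id: l.group_set() for l in loci}
    matrix = proteome.similarity_matrix(group_sets, params.similarity_formula)
    order_override = None
    if overrides.has_locus_order or any(l.row_order_hint is not None for l in loci):
        hinted = sorted(
            (l for l in loci if l.row_order_hint is not None),
            key=lambda l: (l.row_order_hint, l.locus_id),
        )
        rest = [l for l in loci if l.row_order_hint is None]
        order_override = [l.locus_id for l in hinted] + [
            l.locus_id for l in rest
        ]
    cluster_override = None
    if all(l.cluster_hint is not None for l in loci):
        cluster_override = {l.locus_id: l.cluster_hint for l in loci}
    proteome.analyze(
        matrix,
        max_distance=params.cluster_cut_distance,
        order_override=order_override,
        cluster_override=cluster_override,
    )
    members = proteome.cluster_membership(matrix.cluster_of)
    logger.info(
        "proteome: %d sequence cluster(s), leaf order %s",
        len(members), ",".join(matrix.leaf_order),
    )

    # --- classes ------------------------------------------------------------
    classes = proteome.classify_groups(
        members, group_sets, params.conserved_cutoff, params.variable_cutoff
    )
    proteome.apply_classes_to_loci(loci, classes, matrix.cluster_of)

    # --- layout + render ----------------------------------------------------
    canvas = params.canvas()
    layout = build_comparative_layout(loci, matrix.leaf_order, canvas)
    logger.info(
        "layout: %d rows, %d connectors, %d dropped label(s)",
        len(layout.rows), len(layout.connectors), len(layout.dropped_labels),
    )

    result = ComparativeResult(
        loci=loci, assignment=assignment, matrix=matrix, classes=classes,
        order=list(matrix.leaf_order), layout=layout,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out = result.outputs
        if render:
            style = params.style()
            group_classes = {
                gid: cls
                for table in classes.values()
                for gid, (_f, cls) in table.items()
            }
            colors = assign_colors(group_classes, style)
            out["pdf"] = render_pdf(
                layout, style, outdir / "figure.pdf", group_colors=colors
            )
        proteome.write_similarity_tsv(matrix, outdir / "similarity.tsv")
        out["similarity"] = outdir / "similarity.tsv"
        proteome.write_newick(matrix, outdir / "dendrogram.nwk")
        out["newick"] = outdir / "dendrogram.nwk"
        proteome.write_group_class_tsv(classes, outdir / "group_classes.tsv")
        out["classes"] = outdir / "group_classes.tsv"
        annotation_io.write_feature_table(loci, outdir / "feature_table.tsv")
        out["feature_table"] = outdir / "feature_table.tsv"
        row_order = {lid: i + 1 for i, lid in enumerate(matrix.leaf_order)}
        annotation_io.write_locus_table(
            loci, outdir / "locus_table.tsv",
            order=row_order, clusters=matrix.cluster_of,
        )
        out["locus_table"] = outdir / "locus_table.tsv"
    return result


def run_browser(
    locus: Optional[Locus] = None,
    gb: Sequence[str | Path] = (),
    gff: Sequence[str | Path] = (),
    record: Optional[str] = None,
    bedgraph: Sequence[str | Path] = (),
    bigwig: Sequence[str | Path] = (),
    window: Optional[tuple[int, int]] = None,
    gc: bool = True,
    outdir: Optional[str | Path] = None,
    params: Optional[Parameters] = None,
    render: bool = True,
):
    """Single-genome browser mode: gene map over property and signal tracks.

    ``window`` is (start, end), 1-based inclusive, converted internally.
    Exactly one locus must result; a multi-record input needs ``record``.
    """
    params = params or Parameters()
    if locus is None:
        loci = parse_inputs(gb, gff)
        if record is not None:
            match = [l for l in loci if l.locus_id == record]
            if not match:
                raise ValueError(f"no record {record!r} in input")
            locus = match[0]
        elif len(loci) == 1:
            locus = loci[0]
        else:
            raise ValueError(
                f"input has {len(loci)} records; select one with record=..., "
                "or use the comparative mode for multi-locus figures"
            )
    mark_hypothetical([locus], params.hypothetical_patterns)
    if window is not None:
        start1, end1 = window
        if not (1 <= start1 <= end1 <= locus.length_bp):
            raise ValueError(f"window {window} outside locus bounds")
        locus.regions = [Region(start1 - 1, end1)]
    span = locus.regions[0]

    canvas = params.canvas()
    canvas.mode = "browser"
    plot_width = canvas.usable_width

    gc_tracks: list[tracks.SignalTrack] = []
    if gc:
        if not locus.sequence:
            raise ValueError(
                f"locus {locus.locus_id} has no sequence; GC tracks need one"
            )
        sub = locus.sequence[span.start : span.end]
        w = min(params.gc_window, len(sub))
        if w % 2 == 0:
            w = max(1, w - 1)
        for maker in (tracks.gc_content, tracks.gc_skew):
            t = maker(sub, window=w, locus_id=locus.locus_id, span=span)
            t = tracks.smooth_adaptive(t, plot_width, params.points_per_unit)
            gc_tracks.append(tracks.centre_track(t))

    signal_tracks: list[tracks.SignalTrack] = []
    for path in bedgraph:
        t = tracks.parse_bedgraph(path, locus.locus_id, span)
        signal_tracks.append(
            tracks.smooth_adaptive(t, plot_width, params.points_per_unit)
        )
    for path in bigwig:
        t = tracks.bigwig_adapter(path, locus.locus_id, span)
        signal_tracks.append(
            tracks.smooth_adaptive(t, plot_width, params.points_per_unit)
        )
    logger.info(
        "browser: locus %s, span %d bp, %d GC track(s), %d signal track(s)",
        locus.locus_id, span.span(locus.length_bp), len(gc_tracks),
        len(signal_tracks),
    )

    layout = build_browser_layout(locus, signal_tracks, canvas, gc_tracks=gc_tracks)
    outputs: dict[str, Path] = {}
    if outdir is not None and render:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        outputs["pdf"] = render_pdf(
            layout, params.style(), outdir / "browser.pdf"
        )
    return layout, outputs
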