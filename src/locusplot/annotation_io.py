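"""Input/output of annotated loci and override tables.

Two input dialects are supported, matching what prokaryotic annotation
pipelines emit:

* GenBank flat files (possibly multi-record), parsed with Biopython;
* "extended GFF": GFF3 with the nucleotide sequence appended after a
  ``##FASTA`` directive, as written by prokka and pharokka.

Both are converted into the internal :class:`~locusplot.model.Locus` model
with 0-based half-open coordinates.  Manual overrides (sequence order,
clusters, protein-group ids and classes, labels, label visibility) are read
from tab-separated tables and take precedence over anything computed.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

from .model import (
    DEFAULT_HYPOTHETICAL_PATTERNS,
    Feature,
    Locus,
    Region,
    mark_hypothetical,
)

# table-11 initiator codons: a CDS starting with any of these begins with M
_START_CODONS_11 = {"TTG", "CTG", "ATT", "ATC", "ATA", "ATG", "GTG"}

# GFF3 row types that describe containers, not drawable elements
_GFF_SKIP_TYPES = {"region", "gene", "mRNA", "exon", "source", "sequence_region"}


class AnnotationError(ValueError):
    """Raised for unreadable or structurally invalid annotation input."""


def _translate_cds(nt: str, feature_name: str) -> str:
    """Conceptual translation under translation table 11.

    The trailing stop is removed; the initiator codon is rendered as M when
    it is a table-11 start codon; internal stops produce a warning but the
    feature is kept.
    """
    nt = nt.upper()
    trimmed = nt[: len(nt) - len(nt) % 3]
    prot = str(Seq(trimmed).translate(table=11))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        warnings.warn(
            f"internal stop codon in conceptual translation of {feature_name}",
            stacklevel=2,
        )
    if prot and trimmed[:3] in _START_CODONS_11:
        prot = "M" + prot[1:]
    return prot


def _wrap_from_parts(parts: list[tuple[int, int]], length: int):
    """Detect an origin-spanning join and return (start, end, wraps).

    ``parts`` are 0-based half-open (start, end) pairs in biological order.
    A two-part join whose first part runs to the sequence end and whose
    second part starts at 0 is a circular wrap and is kept as one feature.
    """
    if len(parts) == 1:
        s, e = parts[0]
        return s, e, False
    ordered = sorted(parts)
    if (
        len(parts) == 2
        and any(e == length for s, e in parts)
        and any(s == 0 for s, e in parts)
    ):
        first = next(p for p in parts if p[1] == length)
        second = next(p for p in parts if p[0] == 0)
        return first[0], second[1], True
    # simple non-wrapping join: take the outer envelope
    return ordered[0][0], ordered[-1][1], False


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------


def parse_genbank(path: str | Path) -> list[Locus]:
    """Parse a (multi-record) GenBank flat file into loci.

    CDS qualifiers map as ``/locus_tag`` (fallback ``/protein_id``, else a
    generated id) -> feature_id, ``/product`` -> label, ``/translation`` ->
    protein sequence (conceptually translated when absent).  ``circular``
    topology sets the circular flag; origin-spanning ``join`` locations are
    stored as single wrap-flagged features.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except (OSError, ValueError) as exc:
        raise AnnotationError(f"cannot read GenBank file {path}: {exc}") from exc
    if not records:
        raise AnnotationError(f"no GenBank records in {path}")
    loci = []
    for rec in records:
        loci.append(_locus_from_record(rec))
    mark_hypothetical(loci)
    return loci


def _locus_from_record(rec: SeqRecord) -> Locus:
    try:
        seq = str(rec.seq).upper()
    except Bio_UndefinedSequenceError:  # pragma: no cover - alias below
        seq = ""
    length = len(rec.seq) if seq else int(rec.annotations.get("length", 0))
    circular = rec.annotations.get("topology", "linear") == "circular"
    locus = Locus(
        locus_id=rec.id,
        length_bp=length or len(seq),
        sequence=seq,
        description=(rec.description or "").strip(),
        circular=circular,
    )
    counter = 0
    for sf in rec.features:
        if sf.type not in ("CDS", "tRNA"):
            continue
        counter += 1
        parts = [(int(p.start), int(p.end)) for p in sf.location.parts]
        if sf.location.strand == -1:
            parts = parts[::-1]  # biological order for minus-strand joins
        start, end, wraps = _wrap_from_parts(parts, locus.length_bp)
        strand = "-" if sf.location.strand == -1 else "+"
        quals = sf.qualifiers
        fid = (
            _first(quals.get("locus_tag"))
            or _first(quals.get("protein_id"))
            or f"{rec.id}_f{counter}"
        )
        label = _first(quals.get("product")) or ""
        protein = ""
        if sf.type == "CDS":
            protein = _first(quals.get("translation")) or ""
            if not protein:
                if not seq:
                    raise AnnotationError(
                        f"record {rec.id}: CDS {fid} lacks /translation and "
                        "the record has no ORIGIN sequence"
                    )
                nt = str(sf.extract(rec.seq))
                protein = _translate_cds(nt, f"{rec.id}:{fid}")
        locus.features.append(
            Feature(
                feature_id=fid,
                type=sf.type,
                start=start,
                end=end,
                strand=strand,
                label=label,
                protein_seq=protein,
                wraps_origin=wraps,
            )
        )
    return locus


def _first(values) -> Optional[str]:
    if not values:
        return None
    return str(values[0])


try:  # Biopython moved this exception between versions
    from Bio.Seq import UndefinedSequenceError as Bio_UndefinedSequenceError
except ImportError:  # pragma: no cover
    class Bio_UndefinedSequenceError(Exception):
        pass


# ---------------------------------------------------------------------------
# Extended GFF (GFF3 + ##FASTA)
# ---------------------------------------------------------------------------


def parse_extended_gff(path: str | Path) -> list[Locus]:
    """Parse a GFF3 file with an embedded ``##FASTA`` section.

    CDS rows are conceptually translated (table 11, spliced by ID for simple
    joins); tRNA rows become tRNA features.  The ``product`` attribute is
    preferred over ``Name`` for labels; ``ID`` becomes the feature id.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise AnnotationError(f"cannot read GFF file {path}: {exc}") from exc
    if "##FASTA" not in text:
        raise AnnotationError(
            f"{path}: no ##FASTA section; extended GFF requires the "
            "nucleotide sequence appended after a ##FASTA directive"
        )
    body, fasta = text.split("##FASTA", 1)
    seqs = {
        r.id: str(r.seq).upper()
        for r in SeqIO.parse(io.StringIO(fasta.lstrip("\n")), "fasta")
    }
    circular_ids = set()
    rows: dict[str, list[dict]] = {}
    order: dict[str, int] = {}
    for lineno, line in enumerate(body.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
        seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
        attrs = _parse_attrs(attrs_s)
        if ftype == "region" and attrs.get("Is_circular", "").lower() == "true":
            circular_ids.add(seqid)
        if ftype in _GFF_SKIP_TYPES:
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: bad coordinates") from exc
        if seqid not in seqs:
            raise AnnotationError(
                f"{path}:{lineno}: seqid {seqid!r} has no matching FASTA record"
            )
        fid = attrs.get("ID") or f"{seqid}_f{lineno}"
        key = f"{seqid}\t{fid}"
        rows.setdefault(key, []).append(
            dict(
                seqid=seqid,
                type=ftype,
                start=start1 - 1,
                end=end1,
                strand=strand,
                attrs=attrs,
            )
        )
        order.setdefault(key, lineno)

    loci: dict[str, Locus] = {
        sid: Locus(locus_id=sid, length_bp=len(s), sequence=s,
                   circular=sid in circular_ids)
        for sid, s in seqs.items()
    }
    for key in sorted(rows, key=order.__getitem__):
        parts_rows = rows[key]
        seqid = parts_rows[0]["seqid"]
        locus = loci[seqid]
        ftype = parts_rows[0]["type"]
        if ftype not in ("CDS", "tRNA"):
            ftype_internal = "other"
        else:
            ftype_internal = ftype
        strand = parts_rows[0]["strand"]
        strand = "-" if strand == "-" else "+"
        parts = [(r["start"], r["end"]) for r in parts_rows]
        if strand == "-":
            parts = parts[::-1]
        start, end, wraps = _wrap_from_parts(parts, locus.length_bp)
        attrs = parts_rows[0]["attrs"]
        fid = key.split("\t", 1)[1]
        label = attrs.get("product") or attrs.get("Name") or ""
        protein = ""
        if ftype_internal == "CDS":
            nt = "".join(
                locus.sequence[s:e] if s < e
                else locus.sequence[s:] + locus.sequence[:e]
                for (s, e) in parts
            )
            if strand == "-":
                nt = str(Seq(nt).reverse_complement())
            protein = _translate_cds(nt, f"{seqid}:{fid}")
        locus.features.append(
            Feature(
                feature_id=fid,
                type=ftype_internal,
                start=start,
                end=end,
                strand=strand,
                label=label,
                protein_seq=protein,
                wraps_origin=wraps,
            )
        )
    result = list(loci.values())
    mark_hypothetical(result)
    return result


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


# ---------------------------------------------------------------------------
# Override tables
# ---------------------------------------------------------------------------


@dataclass
class Overrides:
    """Manual overrides parsed from the feature / locus / group tables."""

    feature: dict[str, dict] = field(default_factory=dict)  # feature_id -> cols
    locus: dict[str, dict] = field(default_factory=dict)  # locus_id -> cols
    groups: dict[str, str] = field(default_factory=dict)  # feature_id -> group_id

    @property
    def has_locus_order(self) -> bool:
        return any("order" in v for v in self.locus.values())


def _read_tsv(path: str | Path) -> tuple[list[str], list[tuple[int, dict]]]:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise AnnotationError(f"{path}: empty table") from None
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) > len(header):
                raise AnnotationError(
                    f"{path}:{lineno}: {len(row)} fields but {len(header)} columns"
                )
            rows.append((lineno, dict(zip(header, row))))
    return header, rows


def load_tables(
    feature_table: Optional[str | Path] = None,
    locus_table: Optional[str | Path] = None,
    group_table: Optional[str | Path] = None,
) -> Overrides:
    """Load the optional tab-separated override tables.

    Feature table columns: feature_id, locus_id, group_id, group_class,
    label, category, show_label.  Locus table: locus_id, order, cluster,
    description, regions (comma-separated ``start:end``, 1-based inclusive).
    Group table: feature_id, group_id.
    """
    ov = Overrides()
    if feature_table:
        _, rows = _read_tsv(feature_table)
        for lineno, row in rows:
            fid = row.get("feature_id", "").strip()
            if not fid:
                raise AnnotationError(
                    f"{feature_table}:{lineno}: missing feature_id"
                )
            entry = {}
            for col in ("group_id", "group_class", "label", "category"):
                val = row.get(col, "").strip()
                if val:
                    entry[col] = val
            if "group_class" in entry and entry["group_class"] not in (
                "conserved", "intermediate", "variable"
            ):
                raise AnnotationError(
                    f"{feature_table}:{lineno}: invalid group_class "
                    f"{entry['group_class']!r}"
                )
            sl = row.get("show_label", "").strip().lower()
            if sl in ("true", "1", "yes"):
                entry["show_label"] = True
            elif sl in ("false", "0", "no"):
                entry["show_label"] = False
            ov.feature[fid] = entry
    if locus_table:
        _, rows = _read_tsv(locus_table)
        for lineno, row in rows:
            lid = row.get("locus_id", "").strip()
            if not lid:
                raise AnnotationError(f"{locus_table}:{lineno}: missing locus_id")
            entry = {}
            if row.get("order", "").strip():
                try:
                    entry["order"] = int(row["order"])
                except ValueError:
                    raise AnnotationError(
                        f"{locus_table}:{lineno}: order must be an integer"
                    ) from None
            for col in ("cluster", "description"):
                if row.get(col, "").strip():
                    entry[col] = row[col].strip()
            if row.get("regions", "").strip():
                regions = []
                for tok in row["regions"].split(","):
                    try:
                        a, b = tok.strip().split(":")
                        s1, e1 = int(a), int(b)
                    except ValueError:
                        raise AnnotationError(
                            f"{locus_table}:{lineno}: bad region {tok!r} "
                            "(expected start:end, 1-based inclusive)"
                        ) from None
                    # wrap is flagged later against the locus length
                    regions.append((s1 - 1, e1))
                entry["regions"] = regions
            ov.locus[lid] = entry
    if group_table:
        _, rows = _read_tsv(group_table)
        for lineno, row in rows:
            fid = row.get("feature_id", "").strip()
            gid = row.get("group_id", "").strip()
            if not fid or not gid:
                raise AnnotationError(
                    f"{group_table}:{lineno}: need feature_id and group_id"
                )
            if fid in ov.groups and ov.groups[fid] != gid:
                raise AnnotationError(
                    f"{group_table}:{lineno}: feature {fid} mapped to two "
                    f"groups ({ov.groups[fid]}, {gid})"
                )
            ov.groups[fid] = gid
    return ov


def apply_overrides(loci: list[Locus], ov: Overrides) -> None:
    """Merge table overrides onto parsed loci (tables win over computed)."""
    by_feature: dict[str, Feature] = {}
    for locus in loci:
        for f in locus.features:
            by_feature[f.feature_id] = f
    unknown = [fid for fid in ov.feature if fid not in by_feature]
    unknown += [fid for fid in ov.groups if fid not in by_feature]
    if unknown:
        warnings.warn(
            "override tables reference unknown feature ids: "
            + ", ".join(sorted(set(unknown))),
            stacklevel=2,
        )
    for fid, entry in ov.feature.items():
        f = by_feature.get(fid)
        if f is None:
            continue
        for col in ("group_id", "group_class", "label", "category"):
            if col in entry:
                setattr(f, col, entry[col])
        if "show_label" in entry:
            f.show_label = entry["show_label"]
        if "label" in entry:
            f.hypothetical = f.is_hypothetical_label()
    by_locus = {l.locus_id: l for l in loci}
    unknown_l = [lid for lid in ov.locus if lid not in by_locus]
    if unknown_l:
        warnings.warn(
            "locus table references unknown locus ids: "
            + ", ".join(sorted(unknown_l)),
            stacklevel=2,
        )
    for lid, entry in ov.locus.items():
        locus = by_locus.get(lid)
        if locus is None:
            continue
        if "order" in entry:
            locus.row_order_hint = entry["order"]
        if "cluster" in entry:
            locus.cluster_hint = entry["cluster"]
        if "description" in entry:
            locus.description = entry["description"]
        if "regions" in entry:
            locus.regions = [
                Region(s, e, wraps_origin=(s >= e))
                for (s, e) in entry["regions"]
            ]


# ---------------------------------------------------------------------------
# Writers (used by the synthetic generator and the pipeline's emitted tables)
# ---------------------------------------------------------------------------


def write_genbank(loci: Iterable[Locus], path: str | Path) -> None:
    records = []
    for locus in loci:
        rec = SeqRecord(
            Seq(locus.sequence),
            id=locus.locus_id,
            name=locus.locus_id[:16],
            description=locus.description,
            annotations={
                "molecule_type": "DNA",
                "topology": "circular" if locus.circular else "linear",
            },
        )
        for f in locus.features:
            strand = -1 if f.strand == "-" else 1
            if f.wraps_origin:
                loc = CompoundLocation(
                    [
                        SimpleLocation(f.start, locus.length_bp, strand),
                        SimpleLocation(0, f.end, strand),
                    ]
                )
            else:
                loc = SimpleLocation(f.start, f.end, strand)
            quals = {"locus_tag": [f.feature_id]}
            if f.label:
                quals["product"] = [f.label]
            if f.type == "CDS" and f.protein_seq:
                quals["translation"] = [f.protein_seq]
            rec.features.append(SeqFeature(loc, type=f.type, qualifiers=quals))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def write_extended_gff(loci: Iterable[Locus], path: str | Path) -> None:
    loci = list(loci)
    lines = ["##gff-version 3"]
    for locus in loci:
        lines.append(f"##sequence-region {locus.locus_id} 1 {locus.length_bp}")
    for locus in loci:
        circ = ";Is_circular=true" if locus.circular else ""
        lines.append(
            f"{locus.locus_id}\tlocusplot\tregion\t1\t{locus.length_bp}\t.\t+\t.\t"
            f"ID=region_{locus.locus_id}{circ}"
        )
        for f in locus.features:
            ftype = f.type if f.type in ("CDS", "tRNA") else "misc_feature"
            attrs = f"ID={f.feature_id}"
            if f.label:
                attrs += f";product={f.label}"
            if f.wraps_origin:
                lines.append(
                    f"{locus.locus_id}\tlocusplot\t{ftype}\t{f.start + 1}\t"
                    f"{locus.length_bp}\t.\t{f.strand}\t0\t{attrs}"
                )
                lines.append(
                    f"{locus.locus_id}\tlocusplot\t{ftype}\t1\t{f.end}\t.\t"
                    f"{f.strand}\t0\t{attrs}"
                )
            else:
                lines.append(
                    f"{locus.locus_id}\tlocusplot\t{ftype}\t{f.start + 1}\t"
                    f"{f.end}\t.\t{f.strand}\t0\t{attrs}"
                )
    lines.append("##FASTA")
    for locus in loci:
        lines.append(f">{locus.locus_id}")
        for i in range(0, locus.length_bp, 70):
            lines.append(locus.sequence[i : i + 70])
    Path(path).write_text("\n".join(lines) + "\n")


def write_feature_table(loci: Iterable[Locus], path: str | Path) -> None:
    rows = ["feature_id\tlocus_id\tgroup_id\tgroup_class\tlabel\tcategory\tshow_label"]
    for locus in loci:
        for f in locus.features:
            show = "" if f.show_label is None else str(f.show_label).lower()
            rows.append(
                "\t".join(
                    [
                        f.feature_id,
                        locus.locus_id,
                        f.group_id or "",
                        f.group_class or "",
                        f.label,
                        f.category or "",
                        show,
                    ]
                )
            )
    Path(path).write_text("\n".join(rows) + "\n")


def write_locus_table(
    loci: Iterable[Locus],
    path: str | Path,
    order: Optional[dict[str, int]] = None,
    clusters: Optional[dict[str, str]] = None,
) -> None:
    rows = ["locus_id\torder\tcluster\tdescription\tregions"]
    for locus in loci:
        o = "" if order is None else str(order.get(locus.locus_id, ""))
        c = "" if clusters is None else str(clusters.get(locus.locus_id, ""))
        regions = ",".join(f"{r.start + 1}:{r.end}" for r in locus.regions)
        rows.append("\t".join([locus.locus_id, o, c, locus.description, regions]))
    Path(path).write_text("\n".join(rows) + "\n")


def write_group_table(loci: Iterable[Locus], path: str | Path) -> None:
    rows = ["feature_id\tgroup_id"]
    for locus in loci:
        for f in locus.cds_features:
            if f.group_id is not None:
                rows.append(f"{f.feature_id}\t{f.group_id}")
    Path(path).write_text("\n".join(rows) + "\n")
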