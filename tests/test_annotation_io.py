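"""Parsing of GenBank and extended GFF, override tables, round trips."""

import warnings

import pytest

from locusplot import annotation_io as aio
from locusplot.model import Feature, Locus
from locusplot.synthetic import make_locus_set

GENBANK_ONE_CDS = """\
LOCUS       REC1                    1000 bp    DNA     linear   PHG 01-JAN-2025
DEFINITION  test record.
ACCESSION   REC1
VERSION     REC1
FEATURES             Location/Qualifiers
     CDS             10..108
                     /locus_tag="g1"
                     /product="terminase"
                     /translation="{prot}"
ORIGIN
{origin}
//
"""


def _origin_lines(seq):
    out = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        grouped = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        out.append(f"{i + 1:>9} {grouped}")
    return "\n".join(out)


def _write_gb(tmp_path, location="10..108", topology="linear", length=1000):
    prot = "M" + "A" * 31
    seq = "atg" + "gct" * 31 + "taa"
    seq = "a" * 9 + seq + "a" * (length - 9 - len(seq))
    text = GENBANK_ONE_CDS.format(prot=prot, origin=_origin_lines(seq))
    text = text.replace("10..108", location)
    if topology == "circular":
        # keep LOCUS-line column alignment when swapping the topology word
        text = text.replace("linear  ", "circular")
    path = tmp_path / "one.gbk"
    path.write_text(text)
    return path


class TestGenBank:
    def test_coordinate_convention(self, tmp_path):
        """1-based inclusive 10..108 becomes 0-based half-open [9, 108)."""
        loci = aio.parse_genbank(_write_gb(tmp_path))
        (locus,) = loci
        (feat,) = locus.features
        assert (feat.start, feat.end, feat.strand) == (9, 108, "+")
        assert feat.label == "terminase"
        assert len(feat.protein_seq) == 32  # 97 nt span -> 32 aa + stop
        assert locus.length_bp == 1000
        assert locus.regions[0].start == 0 and locus.regions[0].end == 1000

    def test_complement_strand(self, tmp_path):
        loci = aio.parse_genbank(_write_gb(tmp_path, "complement(10..108)"))
        (feat,) = loci[0].features
        assert (feat.start, feat.end, feat.strand) == (9, 108, "-")

    def test_origin_wrapping_join(self, tmp_path):
        """join(91..100,1..30) on a 100 bp circle -> one wrapped feature, 40 nt."""
        seq = "acgt" * 25
        text = (
            "LOCUS       REC1                     100 bp    DNA     circular"
            "PHG 01-JAN-2025\n".replace("circularPHG", "circular PHG")
            + "DEFINITION  wrap test.\nACCESSION   REC1\nVERSION     REC1\n"
            + "FEATURES             Location/Qualifiers\n"
            + "     CDS             join(91..100,1..30)\n"
            + '                     /locus_tag="g1"\n'
            + '                     /product="terminase"\n'
            + '                     /translation="MAAAAAAAAAAAA"\n'
            + "ORIGIN\n" + _origin_lines(seq) + "\n//\n"
        )
        path = tmp_path / "wrap.gbk"
        path.write_text(text)
        (locus,) = aio.parse_genbank(path)
        (feat,) = locus.features
        assert locus.circular
        assert feat.wraps_origin
        assert (feat.start, feat.end) == (90, 30)
        assert feat.span(locus.length_bp) == 40

    def test_missing_translation_is_conceptually_translated(self, tmp_path):
        text = _write_gb(tmp_path).read_text()
        lines = [l for l in text.splitlines() if "/translation" not in l]
        path = tmp_path / "notrans.gbk"
        path.write_text("\n".join(lines))
        (locus,) = aio.parse_genbank(path)
        assert locus.features[0].protein_seq == "M" + "A" * 31

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises(aio.AnnotationError):
            aio.parse_genbank(tmp_path / "missing.gbk")


EXT_GFF = """\
##gff-version 3
##sequence-region chr1 1 300
chr1\ttest\tCDS\t10\t108\t.\t+\t0\tID=g1;product=terminase
chr1\ttest\tCDS\t120\t200\t.\t-\t0\tID=g2;product=portal protein
chr1\ttest\tCDS\t210\t260\t.\t+\t0\tID=g3;Name=capsid
chr1\ttest\ttRNA\t270\t290\t.\t+\t.\tID=t1;product=tRNA-Leu
##FASTA
>chr1
{seq}
"""


class TestExtendedGff:
    def _write(self, tmp_path, seq=None):
        if seq is None:
            cds1 = "TTG" + "GCT" * 31 + "TAA"  # TTG start codon
            seq = "A" * 9 + cds1
            seq = seq + "A" * (300 - len(seq))
        path = tmp_path / "loci.gff"
        path.write_text(EXT_GFF.format(seq=seq))
        return path

    def test_row_parsing_and_counts(self, tmp_path):
        (locus,) = aio.parse_extended_gff(self._write(tmp_path))
        assert len(locus.features) == 4
        cds = [f for f in locus.features if f.type == "CDS"]
        assert len(cds) == 3
        g1 = next(f for f in locus.features if f.feature_id == "g1")
        assert (g1.start, g1.end, g1.label) == (9, 108, "terminase")
        trna = next(f for f in locus.features if f.type == "tRNA")
        assert trna.feature_id == "t1"

    def test_ttg_start_translates_to_initiator_met(self, tmp_path):
        """Table-11 initiator rule: a TTG start codon still yields M."""
        (locus,) = aio.parse_extended_gff(self._write(tmp_path))
        g1 = next(f for f in locus.features if f.feature_id == "g1")
        assert g1.protein_seq.startswith("M")
        assert g1.protein_seq == "M" + "A" * 31

    def test_name_attribute_fallback(self, tmp_path):
        (locus,) = aio.parse_extended_gff(self._write(tmp_path))
        g3 = next(f for f in locus.features if f.feature_id == "g3")
        assert g3.label == "capsid"

    def test_missing_fasta_section_raises(self, tmp_path):
        path = tmp_path / "nofasta.gff"
        path.write_text("##gff-version 3\nchr1\tt\tCDS\t1\t9\t.\t+\t0\tID=x\n")
        with pytest.raises(aio.AnnotationError, match="FASTA"):
            aio.parse_extended_gff(path)

    def test_unknown_seqid_raises(self, tmp_path):
        path = tmp_path / "bad.gff"
        path.write_text(
            "##gff-version 3\nchrX\tt\tCDS\t1\t9\t.\t+\t0\tID=x\n##FASTA\n>chr1\nACGT\n"
        )
        with pytest.raises(aio.AnnotationError, match="chrX"):
            aio.parse_extended_gff(path)


class TestRoundTrip:
    def test_genbank_gff_parse_equivalence(self, tmp_path):
        """The same loci written to both formats parse identically."""
        truth = make_locus_set(n_loci=3, seed=5, outdir=tmp_path)
        from_gb = aio.parse_genbank(truth.files["genbank"])
        from_gff = aio.parse_extended_gff(truth.files["gff"])
        assert len(from_gb) == len(from_gff) == 3
        for a, b in zip(from_gb, from_gff):
            assert a.locus_id == b.locus_id
            assert a.length_bp == b.length_bp
            assert a.sequence == b.sequence
            assert a.circular == b.circular
            assert len(a.features) == len(b.features)
            for fa, fb in zip(a.features, b.features):
                assert (fa.feature_id, fa.start, fa.end, fa.strand) == (
                    fb.feature_id, fb.start, fb.end, fb.strand
                )
                assert fa.label == fb.label
                assert fa.protein_seq == fb.protein_seq

    def test_parse_is_deterministic(self, tmp_path):
        truth = make_locus_set(n_loci=2, seed=6, outdir=tmp_path)
        a = aio.parse_genbank(truth.files["genbank"])
        b = aio.parse_genbank(truth.files["genbank"])
        assert [(f.feature_id, f.start, f.end) for l in a for f in l.features] == [
            (f.feature_id, f.start, f.end) for l in b for f in l.features
        ]


class TestTables:
    def _loci(self):
        return [
            Locus(
                locus_id=lid, length_bp=500, sequence="A" * 500,
                features=[
                    Feature(
                        feature_id=f"{lid}_g1", type="CDS", start=10, end=100,
                        strand="+", label="x", protein_seq="MAAA",
                    )
                ],
            )
            for lid in ("L1", "L2")
        ]

    def test_locus_order_override_wins(self, tmp_path):
        path = tmp_path / "locus.tsv"
        path.write_text(
            "locus_id\torder\tcluster\tdescription\tregions\nL1\t2\t\t\t\nL2\t1\t\t\t\n"
        )
        loci = self._loci()
        ov = aio.load_tables(locus_table=path)
        aio.apply_overrides(loci, ov)
        hinted = sorted(loci, key=lambda l: l.row_order_hint)
        assert [l.locus_id for l in hinted] == ["L2", "L1"]

    def test_group_table_assigns_shared_group(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("feature_id\tgroup_id\nL1_g1\tGRP7\nL2_g1\tGRP7\n")
        ov = aio.load_tables(group_table=path)
        assert ov.groups == {"L1_g1": "GRP7", "L2_g1": "GRP7"}

    def test_feature_class_override_precedence(self, tmp_path):
        path = tmp_path / "features.tsv"
        path.write_text(
            "feature_id\tlocus_id\tgroup_id\tgroup_class\tlabel\tcategory\tshow_label\n"
            "L1_g1\tL1\t\tconserved\t\t\ttrue\n"
        )
        loci = self._loci()
        aio.apply_overrides(loci, aio.load_tables(feature_table=path))
        assert loci[0].features[0].group_class == "conserved"
        assert loci[0].features[0].show_label is True

    def test_unknown_ids_warn(self, tmp_path):
        path = tmp_path / "features.tsv"
        path.write_text("feature_id\tlocus_id\nNOPE\tL1\n")
        loci = self._loci()
        with pytest.warns(UserWarning, match="NOPE"):
            aio.apply_overrides(loci, aio.load_tables(feature_table=path))

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "locus.tsv"
        path.write_text(
            "locus_id\torder\nL1\tnot_a_number\n"
        )
        with pytest.raises(aio.AnnotationError, match=":2"):
            aio.load_tables(locus_table=path)

    def test_duplicate_group_mapping_is_error(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("feature_id\tgroup_id\ng1\tX\ng1\tY\n")
        with pytest.raises(aio.AnnotationError, match="two groups"):
            aio.load_tables(group_table=path)
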