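"""Annotation parsing, circular coordinate arithmetic and gene geometry."""

import random
from dataclasses import replace

import pytest

from mitoprofile.genome_model import (
    PCG,
    TRNA,
    AnnotationParseError,
    GeneFeature,
    GenomeAnnotation,
    feature_length,
    geometry_summary,
    intergenic_gap,
    parse_annotation_table,
    read_genbank,
    strand_tally,
    write_annotation_table,
)

from conftest import coverage_oracle, random_annotation


class TestParsing:
    def test_reference_table_shape(self, ref_annotation):
        """38 features (37 genes + control region) spanning 16,141 bp."""
        assert len(ref_annotation) == 38
        assert ref_annotation.genome_length == 16141
        assert ref_annotation.control_region is not None

    def test_declared_sizes_match_coordinates(self, ref_annotation):
        for f in ref_annotation:
            assert f.declared_size == feature_length(
                f, ref_annotation.genome_length), f.name

    def test_empty_body_errors(self):
        with pytest.raises(AnnotationParseError, match="no features|empty"):
            parse_annotation_table("Gene\tDirection\tLocation\n")
        with pytest.raises(AnnotationParseError):
            parse_annotation_table("")

    @pytest.mark.parametrize("row,msg", [
        ("g1\tF\t10..20", "malformed location"),
        ("g1\tX\t10-20", "direction"),
        ("\tF\t10-20", "empty gene name"),
    ])
    def test_malformed_rows_name_the_row(self, row, msg):
        text = "Gene\tDirection\tLocation\n" + row + "\n"
        with pytest.raises(AnnotationParseError, match=msg):
            parse_annotation_table(text)

    def test_round_trip_is_identity_on_canonical_text(self):
        text = (
            "Gene\tDirection\tLocation\tSize\tAnticodon\tStart\tStop\tIntergenic\n"
            "tRNA-Ile\tF\t1-66\t66\t31-33GAT\n"
            "ND2\tF\t70-1086\t1017\t\tATT\tTAA\t3\n"
            "tRNA-Cys\tR\t1085-1147\t63\t1110-1112GCA\t\t\t-2\n"
            "lrRNA\tR\t1150-2479\t1330\t\t\t\t2\n"
            "control_region\t\t2480-3745\t1266\t\t\t\t0\n"
        )
        a = parse_annotation_table(text)
        assert write_annotation_table(a) == text
        # parse(write(.)) is a fixed point
        assert parse_annotation_table(write_annotation_table(a)) == a

    def test_en_dash_locations_accepted(self):
        a = parse_annotation_table("Gene\tDirection\tLocation\ng1\tF\t5–10\n")
        assert (a.features[0].start, a.features[0].end) == (5, 10)


class TestLengthsAndGaps:
    def test_simple_and_wrapping_lengths(self):
        f = GeneFeature("a", PCG, "J", 1, 66)
        assert feature_length(f, 16141) == 66
        f = GeneFeature("coi", PCG, "J", 1416, 2967)
        assert feature_length(f, 16141) == 1552
        wrap = GeneFeature("w", PCG, "J", 16140, 5)
        assert feature_length(wrap, 16141) == 7

    def test_signed_gap_examples(self):
        mk = lambda s, e: GeneFeature("x", PCG, "J", s, e)
        assert intergenic_gap(mk(1, 66), mk(64, 132), 16141) == -3
        assert intergenic_gap(mk(5987, 6050), mk(6077, 6142), 16141) == 26
        assert intergenic_gap(mk(50, 100), mk(101, 150), 16141) == 0

    def test_circular_closing_gap(self, ref_annotation):
        """The control-region → first-tRNA pair closes the circle exactly."""
        last = ref_annotation.features[-1]
        first = ref_annotation.features[0]
        assert intergenic_gap(last, first, ref_annotation.genome_length) == 0

    def test_gap_column_recomputed_exactly(self, ref_annotation):
        geom = geometry_summary(ref_annotation)
        declared = {f.name: f.declared_gap for f in ref_annotation
                    if f.declared_gap is not None}
        recomputed = {g.next: g.gap for g in geom.gaps}
        for name, want in declared.items():
            assert recomputed[name] == want, name


class TestGeometrySummary:
    def test_reference_spacer_and_overlap_census(self, ref_annotation):
        g = geometry_summary(ref_annotation)
        assert (g.spacer_count, g.spacer_total_bp, g.spacer_max_bp) == (14, 127, 26)
        assert (g.overlap_total_bp, g.overlap_max_bp) == (43, 8)

    def test_single_full_circle_feature(self):
        a = GenomeAnnotation((GeneFeature("g", PCG, "J", 1, 1000),), 1000)
        g = geometry_summary(a)
        assert g.spacer_count == 0 and g.overlap_count == 0

    def test_random_annotations_match_coverage_oracle(self):
        rng = random.Random(42)
        for _ in range(50):
            a, gaps = random_annotation(rng)
            g = geometry_summary(a)
            free, multi = coverage_oracle(a)
            assert g.spacer_total_bp == free
            assert g.overlap_total_bp == multi
            assert sorted(x.gap for x in g.gaps) == sorted(gaps)

    def test_rotation_invariance(self):
        """Rotating the origin preserves all lengths and gaps."""
        rng = random.Random(7)
        a, _ = random_annotation(rng)
        n = a.genome_length
        base = geometry_summary(a)
        for k in (1, 137, n // 2):
            rotated = GenomeAnnotation(tuple(
                replace(f, start=(f.start - 1 + k) % n + 1,
                        end=(f.end - 1 + k) % n + 1)
                for f in a.features), n)
            got = geometry_summary(rotated)
            assert [x.gap for x in got.gaps] == [x.gap for x in base.gaps]
            assert [feature_length(f, n) for f in rotated.features] == \
                   [feature_length(f, n) for f in a.features]


class TestStrandTally:
    def test_reference_tally(self, ref_annotation):
        t = strand_tally(ref_annotation)
        assert t["genes"] == (23, 14)
        assert t[PCG] == (9, 4)
        assert t[TRNA] == (14, 8)
        assert t["rRNA"] == (0, 2)

    def test_all_majority_strand(self):
        feats = tuple(GeneFeature(f"g{i}", PCG, "J", 10 * i + 1, 10 * i + 5)
                      for i in range(6))
        a = GenomeAnnotation(feats, 100)
        assert strand_tally(a)["genes"] == (6, 0)

    def test_random_assignment_matches_direct_count(self):
        rng = random.Random(3)
        a, _ = random_annotation(rng, n_features=10)
        t = strand_tally(a)
        assert t["genes"] == (sum(f.strand == "J" for f in a.features),
                              sum(f.strand == "N" for f in a.features))


class TestGenBankReader:
    def test_round_trip_through_genbank(self, tmp_path, synth):
        """A generated genome written as GenBank reads back consistently."""
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqFeature import FeatureLocation, SeqFeature
        from Bio.SeqRecord import SeqRecord

        genome, ann, _ = synth
        rec = SeqRecord(Seq(genome.seq), id="synth1", name="synth1",
                        description="", annotations={"molecule_type": "DNA",
                                                     "topology": "circular"})
        type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                   "control_region": "misc_feature"}
        for f in ann.features:
            rec.features.append(SeqFeature(
                FeatureLocation(f.start - 1, f.end,
                                strand=-1 if f.strand == "N" else 1),
                type=type_of[f.kind], qualifiers={"gene": [f.name]}))
        path = tmp_path / "synth.gb"
        SeqIO.write(rec, path, "genbank")

        seq2, ann2 = read_genbank(str(path))
        assert seq2.seq == genome.seq
        assert len(ann2) == len(ann)
        got = {(f.name, f.start, f.end, f.strand, f.kind) for f in ann2}
        want = {(f.name, f.start, f.end, f.strand, f.kind) for f in ann}
        assert got == want
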