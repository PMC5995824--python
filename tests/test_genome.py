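"""Annotation-table model: gaps, overlaps, census, extraction, IO."""

import io

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from mitocomp.genome import (
    AnnotationTable,
    Feature,
    GapRecord,
    Mitogenome,
    ParseError,
    TableOnlyGenomeError,
    extract_region,
    intergenic_gaps,
    overlap_summary,
    parse_feature_tsv,
    parse_genbank,
    spacer_summary,
    strand_census,
    write_feature_tsv,
)
from mitocomp.simulate import make_annotation_table, random_layout_spec


def _toy_table(features, length=None):
    length = length or max(f.end for f in features)
    return AnnotationTable(genome_length=length, features=list(features))


class TestReferenceAccounting:
    """The published annotation coordinates are the ground truth; the
    derived spacer/overlap/census statistics must follow from them."""

    def test_dimensions(self, ref_table):
        assert ref_table.genome_length == 16175
        assert len(ref_table) == 38
        assert len(ref_table.genes) == 37

    def test_named_gaps(self, ref_table):
        gaps = {(g.upstream, g.downstream): g.gap_bp
                for g in intergenic_gaps(ref_table)}
        assert gaps[("trnI", "trnQ")] == 3
        assert gaps[("trnE", "trnF")] == 19
        assert gaps[("trnW", "trnC")] == -8
        assert gaps[("ATP8", "ATP6")] == -7
        assert gaps[("control_region", "trnI")] == 0  # wrap pair

    def test_spacer_and_overlap_summaries(self, ref_table):
        sp = spacer_summary(ref_table)
        assert sp["count"] == 16
        assert sp["max_bp"] == 19
        assert sp["max_pair"] == ("trnE", "trnF")
        assert sp["total_bp"] == 66
        ov = overlap_summary(ref_table)
        assert ov["count"] == 6
        assert ov["max_bp"] == 8
        assert ov["max_pair"] == ("trnW", "trnC")

    def test_strand_census(self, ref_table):
        census = strand_census(ref_table)
        assert census["J"] == {"PCG": 9, "tRNA": 14, "rRNA": 0, "total": 23}
        assert census["N"] == {"PCG": 4, "tRNA": 8, "rRNA": 2, "total": 14}

    def test_feature_lengths(self, ref_table):
        trna_lens = {f.name: f.length() for f in ref_table.by_class("tRNA")}
        assert min(trna_lens.values()) == 63 and trna_lens["trnR"] == 63
        assert max(trna_lens.values()) == 72 and trna_lens["trnV"] == 72
        assert ref_table.get("rrnL").length() == 1323
        assert ref_table.get("rrnS").length() == 785
        assert ref_table.get("control_region").length() == 1367


class TestGaps:
    def test_contiguous_features(self):
        t = _toy_table([Feature("a", 1, 10, "J", "tRNA"),
                        Feature("b", 11, 20, "J", "tRNA")])
        gaps = intergenic_gaps(t)
        assert gaps[0] == GapRecord("a", "b", 0)

    def test_record_count_equals_feature_count(self):
        t = _toy_table([Feature("a", 1, 10, "J", "tRNA"),
                        Feature("b", 15, 20, "J", "tRNA"),
                        Feature("c", 22, 30, "N", "PCG")], length=33)
        gaps = intergenic_gaps(t)
        assert len(gaps) == 3
        assert gaps[-1] == GapRecord("c", "a", 3)  # circular wrap

    def test_singleton_and_empty(self):
        assert intergenic_gaps(_toy_table([Feature("a", 1, 10, "J", "tRNA")])) == []

    def test_disjoint_features_no_overlap(self):
        t = _toy_table([Feature("a", 1, 10, "J", "tRNA"),
                        Feature("b", 20, 30, "J", "tRNA")], length=40)
        ov = overlap_summary(t)
        assert ov["count"] == 0 and ov["max_bp"] == 0 and ov["max_pair"] is None


@pytest.mark.parametrize("seed", range(5))
def test_tiling_invariant_on_synthetic_tables(seed):
    """Feature lengths + spacers - overlaps close the circle exactly, and
    the computed gaps match the generator's ledger."""
    table, ledger = make_annotation_table(random_layout_spec(seed))
    gaps = intergenic_gaps(table)
    assert gaps == ledger["gaps"]
    total = sum(f.length() for f in table)
    total += sum(g.gap_bp for g in gaps if g.gap_bp > 0)
    total -= sum(-g.gap_bp for g in gaps if g.gap_bp < 0)
    assert total == table.genome_length
    assert strand_census(table) == ledger["census"]


def test_identical_start_sort_tie_break():
    t = _toy_table([Feature("short", 5, 10, "J", "tRNA"),
                    Feature("long", 5, 30, "J", "rRNA")], length=40)
    assert [f.name for f in t] == ["long", "short"]


class TestExtractRegion:
    genome = Mitogenome(
        table=AnnotationTable(genome_length=6,
                              features=[Feature("f", 1, 4, "J", "tRNA")]),
        sequence="ACGTAC",
    )

    def test_forward(self):
        assert extract_region(self.genome, Feature("f", 1, 4, "J", "tRNA")) == "ACGT"

    def test_reverse_palindrome(self):
        assert extract_region(self.genome, Feature("f", 1, 4, "N", "tRNA")) == "ACGT"

    def test_reverse(self):
        # region 2..5 is "CGTA"; N strand returns its reverse complement
        assert extract_region(self.genome, Feature("f", 2, 5, "N", "tRNA")) == "TACG"

    def test_wraparound(self):
        assert extract_region(self.genome, Feature("f", 5, 2, "J", "tRNA")) == "ACAC"

    def test_table_only_error(self):
        g = Mitogenome(table=self.genome.table)
        with pytest.raises(TableOnlyGenomeError, match="table-only"):
            extract_region(g, Feature("f", 1, 4, "J", "tRNA"))


class TestTsvIO:
    def test_roundtrip_reference(self, ref_table):
        buf = io.StringIO()
        write_feature_tsv(ref_table, buf)
        again = parse_feature_tsv(io.StringIO(buf.getvalue()))
        assert again == ref_table

    @pytest.mark.parametrize("seed", range(3))
    def test_roundtrip_synthetic(self, seed, tmp_path):
        table, _ = make_annotation_table(random_layout_spec(seed))
        path = tmp_path / "t.tsv"
        write_feature_tsv(table, path)
        assert parse_feature_tsv(path) == table

    def test_single_feature_default_length(self):
        t = parse_feature_tsv(io.StringIO("g\t1\t100\tJ\tPCG\tATG/TAA\n"))
        assert t.genome_length == 100
        assert t.features[0].start_codon == "ATG"

    def test_strand_synonyms(self):
        t = parse_feature_tsv(io.StringIO("a\t1\t5\tF\ttRNA\t.\nb\t6\t9\t-\ttRNA\t.\n"))
        assert [f.strand for f in t] == ["J", "N"]

    @pytest.mark.parametrize("text,message", [
        ("a\t1\t50\tJ\ttRNA\t.\n#genome_length=40\n", "exceed"),
        ("a\t1\t5\tX\ttRNA\t.\n", "strand"),
        ("a\t1\t5\tJ\ttRNA\t.\na\t1\t5\tJ\ttRNA\t.\n", "duplicate"),
        ("a\tone\t5\tJ\ttRNA\t.\n", "non-integer"),
        ("", "no features"),
    ])
    def test_parse_errors(self, text, message):
        with pytest.raises(ParseError, match=message):
            parse_feature_tsv(io.StringIO(text))


def test_genbank_reader_roundtrip(tmp_path):
    """A GenBank flat file written by biopython reads back into the same
    coordinates, strands and classes."""
    seq = Seq("ATGAAATTTCCCGGGTAAACGTACGT")
    record = SeqRecord(seq, id="SYNTEST1", annotations={"molecule_type": "DNA"})
    record.features = [
        SeqFeature(FeatureLocation(0, 9, strand=1), type="CDS",
                   qualifiers={"gene": ["g1"],
                               "note": ["start_codon:ATG; stop_codon:TAA"]}),
        SeqFeature(FeatureLocation(9, 18, strand=-1), type="tRNA",
                   qualifiers={"product": ["trnX"]}),
        SeqFeature(FeatureLocation(18, 26, strand=1), type="misc_feature",
                   qualifiers={"note": ["control region"]}),
    ]
    path = tmp_path / "x.gb"
    SeqIO.write(record, path, "genbank")
    genome = parse_genbank(path)
    assert genome.accession == "SYNTEST1"
    assert genome.sequence == str(seq)
    g1 = genome.table.get("g1")
    assert (g1.start, g1.end, g1.strand, g1.feature_class) == (1, 9, "J", "PCG")
    assert g1.start_codon == "ATG" and g1.stop_codon == "TAA"
    trn = genome.table.get("trnX")
    assert (trn.start, trn.end, trn.strand) == (10, 18, "N")
    cr = genome.table.by_class("control_region")[0]
    assert (cr.start, cr.end) == (19, 26)
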