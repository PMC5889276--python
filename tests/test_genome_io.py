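import pytest
from hypothesis import given
from hypothesis import strategies as st

from phagekit import GenomeRecord, read_fasta, reverse_complement, write_gff3
from phagekit.genome_io import IUPAC_LETTERS, SequenceError
from phagekit.motifs import PromoterHit
from phagekit.orfs import CdsFeature
from phagekit.terminators import TerminatorCandidate


class TestReadFasta:
    def test_basic_concatenation_and_uppercase(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">g\nacgt\nACGT\n")
        (rec,) = read_fasta(path)
        assert rec.seq == "ACGTACGT"
        assert rec.length == 8
        assert rec.id == "g"

    def test_headerless_dialect_synthesizes_id(self, tmp_path):
        path = tmp_path / "bare_seq.txt"
        path.write_text("GATC\nGATC\n")
        (rec,) = read_fasta(path)
        assert rec.id == "bare_seq"
        assert rec.seq == "GATCGATC"
        assert rec.length == 8

    def test_digits_and_whitespace_stripped(self, tmp_path):
        path = tmp_path / "origin.txt"
        path.write_text("1 gatcga tcaa\n61 ttgg\n")
        (rec,) = read_fasta(path)
        assert rec.seq == "GATCGATCAATTGG"

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(SequenceError, match="no sequence"):
            read_fasta(path)

    def test_illegal_character_names_offset(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">g\nACXGT\n")
        with pytest.raises(SequenceError, match="offset 2"):
            read_fasta(path)

    def test_u_mapped_to_t(self, tmp_path):
        path = tmp_path / "rna.fasta"
        path.write_text(">g\nACGU\n")
        (rec,) = read_fasta(path)
        assert rec.seq == "ACGT"

    def test_multi_record(self, tmp_path):
        path = tmp_path / "two.fasta"
        path.write_text(">a\nACGT\n>b\nGGCC\n")
        recs = read_fasta(path)
        assert [r.id for r in recs] == ["a", "b"]


class TestGenomeRecord:
    def test_length_matches_seq(self):
        rec = GenomeRecord("x", "ACGTN")
        assert rec.length == 5
        assert rec.ambiguous_positions == (5,)

    def test_rejects_non_iupac(self):
        with pytest.raises(SequenceError, match="offset 1"):
            GenomeRecord("x", "AZGT")

    def test_slice_is_one_based_inclusive(self):
        rec = GenomeRecord("x", "ACGTACGT")
        assert rec.slice(1, 8) == "ACGTACGT"
        assert rec.slice(2, 4) == "CGT"
        with pytest.raises(SequenceError):
            rec.slice(0, 3)
        with pytest.raises(SequenceError):
            rec.slice(5, 9)


class TestReverseComplement:
    def test_palindrome(self):
        assert reverse_complement("ACGT") == "ACGT"

    def test_degenerate_palindrome(self):
        # complement C->G, Y->R, C->G, G->C, R->Y, G->C then reverse
        assert reverse_complement("CYCGRG") == "CYCGRG"

    def test_non_palindrome(self):
        assert reverse_complement("CCCAGC") == "GCTGGG"

    def test_rejects_illegal(self):
        with pytest.raises(SequenceError):
            reverse_complement("ACXGT")

    @given(st.text(alphabet=sorted(IUPAC_LETTERS), min_size=0, max_size=80))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestWriteGff3:
    def _genome(self, n=1000):
        return GenomeRecord("g1", "ACGT" * (n // 4))

    def test_cds_coordinates_verbatim(self, tmp_path):
        path = tmp_path / "out.gff3"
        write_gff3(self._genome(), [CdsFeature("TP84_01", 13, 579, "+")], path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        cols = lines[2].split("\t")
        assert (cols[2], cols[3], cols[4], cols[6]) == ("CDS", "13", "579", "+")

    def test_empty_feature_list_header_only(self, tmp_path):
        path = tmp_path / "out.gff3"
        write_gff3(self._genome(), [], path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        assert all(line.startswith("#") for line in lines)

    def test_tie_break_cds_promoter_terminator(self, tmp_path):
        path = tmp_path / "out.gff3"
        feats = [
            TerminatorCandidate(10, 40, 5, 4, -9.0, 1.0),
            PromoterHit(10, 31, 15, 0, 0, "+"),
            CdsFeature("c", 10, 45, "+"),
        ]
        write_gff3(self._genome(), feats, path)
        types = [l.split("\t")[2] for l in path.read_text().splitlines() if not l.startswith("#")]
        assert types == ["CDS", "promoter", "terminator"]

    def test_out_of_range_feature_raises(self, tmp_path):
        with pytest.raises(SequenceError):
            write_gff3(self._genome(), [CdsFeature("c", 990, 1005, "+")], tmp_path / "x.gff3")

    def test_reparses_with_strict_parser(self, tmp_path):
        gffutils = pytest.importorskip("gffutils")
        path = tmp_path / "out.gff3"
        feats = [
            CdsFeature("a", 5, 103, "+"),
            PromoterHit(120, 141, 15, 1, 0, "+"),
            TerminatorCandidate(200, 240, 6, 4, -10.0, 0.9),
        ]
        write_gff3(self._genome(), feats, path)
        db = gffutils.create_db(str(path), ":memory:")
        assert sum(1 for _ in db.all_features()) == 3


def test_read_genbank_sequence_and_cds(tmp_path):
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    from phagekit import read_genbank

    rec = SeqRecord(Seq("ATGGCTTAA" + "ACGT" * 10), id="gb1", name="gb1",
                    annotations={"molecule_type": "DNA"})
    rec.features.append(
        SeqFeature(FeatureLocation(0, 9, strand=1), type="CDS",
                   qualifiers={"locus_tag": ["orf1"]})
    )
    path = tmp_path / "g.gb"
    SeqIO.write(rec, path, "genbank")

    genome, cds = read_genbank(path)
    assert genome.seq.startswith("ATGGCTTAA")
    assert cds == [(1, 9, "+", "orf1")]


def test_fasta_roundtrip(tmp_path, make_genome):
    genome = make_genome(seed=42, length=500)
    path = tmp_path / "rt.fasta"
    path.write_text(f">{genome.id}\n{genome.seq}\n")
    (back,) = read_fasta(path)
    assert back.seq == genome.slice(1, genome.length)
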