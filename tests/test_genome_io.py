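import numpy as np
import pytest

from mitocompare.genome_io import (
    CircularGenome,
    GeneFeature,
    attach_gff3,
    gc_content,
    read_fasta,
    read_genbank,
    revcomp,
    rotate,
    split_gene_name,
    write_fasta,
    write_gff3,
)
from tests.conftest import random_dna


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">g\nACGT\n")
        (g,) = read_fasta(p)
        assert g.length == 4 and gc_content(g) == 0.5

    def test_multi_record_order_preserved(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">one\nAAAA\n>two\nCCCC\n")
        genomes = read_fasta(p)
        assert [g.id for g in genomes] == ["one", "two"]

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">g\nacgt\n")
        assert read_fasta(p)[0].seq == "ACGT"

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_round_trip(self, tmp_path, rng):
        g = CircularGenome(id="x", seq=random_dna(rng, 500))
        write_fasta(g, tmp_path / "x.fasta")
        assert read_fasta(tmp_path / "x.fasta")[0].seq == g.seq


MINIMAL_GB = """LOCUS       TESTREC    120 bp    DNA    circular PLN 01-JAN-2020
DEFINITION  test.
ACCESSION   TESTREC
FEATURES             Location/Qualifiers
     CDS             11..100
                     /gene="nad3"
     CDS             complement(101..115)
                     /gene="nad2a"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


class TestGenBank:
    def test_coordinates_and_name_split(self, tmp_path):
        p = tmp_path / "t.gb"
        p.write_text(MINIMAL_GB)
        g = read_genbank(p)
        assert g.circular
        nad3 = next(f for f in g.genes if f.name == "nad3")
        assert (nad3.start, nad3.end, nad3.strand) == (10, 100, "+")
        nad2 = next(f for f in g.genes if f.name == "nad2")
        assert nad2.part_suffix == "a" and nad2.strand == "-"

    def test_origin_spanning_join_length_preserved(self, tmp_path):
        gb = MINIMAL_GB.replace(
            'CDS             complement(101..115)\n                     /gene="nad2a"',
            'CDS             join(111..120,1..10)\n                     /gene="cox1"',
        )
        p = tmp_path / "t.gb"
        p.write_text(gb)
        g = read_genbank(p)
        cox1 = next(f for f in g.genes if f.name == "cox1")
        assert cox1.end - cox1.start == 20  # sum of the join segments


@pytest.mark.parametrize(
    "label, base, suffix",
    [
        ("nad2ab", "nad2", "ab"),
        ("cob", "cob", None),
        ("trnM", "trnM", None),
        ("nad4L", "nad4L", None),
        ("ccmFN", "ccmFN", None),
        ("nad3-D2", "nad3", "D2"),
        ("rps10ab", "rps10", "ab"),
        ("nad1e", "nad1", "e"),
        ("mat-R", "mat-R", None),
    ],
)
def test_split_gene_name(label, base, suffix):
    assert split_gene_name(label) == (base, suffix)


class TestGcContent:
    @pytest.mark.parametrize("seq, gc", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGTN", 0.5)])
    def test_values(self, seq, gc):
        assert gc_content(seq) == pytest.approx(gc)

    def test_all_n_undefined(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")

    def test_invariant_under_rotation_and_revcomp(self, rng):
        g = CircularGenome(id="x", seq=random_dna(rng, 300))
        assert gc_content(rotate(g, 137)) == pytest.approx(gc_content(g))
        assert gc_content(revcomp(g.seq)) == pytest.approx(gc_content(g))


class TestRotate:
    def test_sequence_rotation(self):
        g = CircularGenome(id="x", seq="ACGT")
        assert rotate(g, 2).seq == "GTAC"

    def test_identity_cases(self, rng):
        g = CircularGenome(id="x", seq=random_dna(rng, 100))
        assert rotate(g, 0).seq == g.seq
        assert rotate(rotate(g, 37), 100 - 37).seq == g.seq

    def test_feature_remap_matches_bruteforce(self, rng):
        seq = random_dna(rng, 50)
        g = CircularGenome(
            id="x", seq=seq, genes=[GeneFeature("nad3", 10, 20, "+", "protein")]
        )
        for k in (5, 25, 45):
            r = rotate(g, k)
            f = r.genes[0]
            # the feature sequence must be unchanged under rotation
            assert r.seq[f.start : f.end] == seq[10:20]

    def test_cutting_a_feature_rejected(self):
        g = CircularGenome(
            id="x", seq="ACGTACGTAC", genes=[GeneFeature("g", 2, 8, "+", "protein")]
        )
        with pytest.raises(ValueError):
            rotate(g, 5)

    def test_linear_genome_rejected(self):
        g = CircularGenome(id="x", seq="ACGT", circular=False)
        with pytest.raises(ValueError):
            rotate(g, 1)


def test_gff3_round_trip(tmp_path, rng):
    genes = [
        GeneFeature("nad2", 10, 100, "+", "protein", "a"),
        GeneFeature("trnM", 200, 275, "-", "tRNA"),
        GeneFeature("nad3", 300, 360, "+", "protein", "D2"),
    ]
    g = CircularGenome(id="x", seq=random_dna(rng, 400), genes=genes)
    write_gff3(g, tmp_path / "x.gff3")
    g2 = CircularGenome(id="x", seq=g.seq)
    g2 = attach_gff3(g2, tmp_path / "x.gff3")
    assert [(f.name, f.part_suffix, f.start, f.end, f.strand) for f in g2.genes] == [
        (f.name, f.part_suffix, f.start, f.end, f.strand) for f in genes
    ]
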