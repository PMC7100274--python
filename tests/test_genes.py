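from itertools import product

import pytest
from Bio.Seq import Seq

from mitocompare.genes import (
    classify_substitution,
    compare_gene,
    copy_numbers,
    gene_copies,
    intersect_candidates,
    match_homologs,
)
from mitocompare.genome_io import CircularGenome, GeneFeature
from tests.conftest import random_dna

SENSE = [
    "".join(t) for t in product("ACGT", repeat=3)
    if "".join(t) not in ("TAA", "TAG", "TGA")
]


def make_cds(rng, n_codons, fixed=None):
    s = ["ATG"] + [SENSE[i] for i in rng.integers(0, len(SENSE), n_codons - 2)] + ["TAA"]
    seq = list("".join(s))
    for pos1, codon in (fixed or {}).items():
        seq[pos1 - 1 : pos1 + 2] = codon
    return "".join(seq)


class TestClassifySubstitution:
    def test_codon_classification_examples(self):
        assert classify_substitution("TAT", "TCT") == "nonsynonymous"  # Y -> S
        assert classify_substitution("TCT", "TCC") == "synonymous"     # S -> S

    def test_identical_codons_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("ATG", "ATG")

    def test_ambiguous_codon_unclassified(self):
        assert classify_substitution("ANT", "AGT") == "unclassified"

    def test_agrees_with_translation_for_all_sense_pairs(self):
        for a in SENSE:
            for b in SENSE:
                if a == b:
                    continue
                expected = (
                    "synonymous"
                    if str(Seq(a).translate()) == str(Seq(b).translate())
                    else "nonsynonymous"
                )
                assert classify_substitution(a, b) == expected


class TestCompareGene:
    def test_identical_no_events(self, rng):
        a = make_cds(rng, 200)
        rec = compare_gene(a, a)
        assert rec.events == [] and rec.length_a == rec.length_b

    def test_codon_start_positions_and_synonymy(self, rng):
        a = make_cds(rng, 389, fixed={58: "TAT", 766: "TCT"})
        b = a[:58] + "C" + a[59:767] + "C" + a[768:]
        rec = compare_gene(a, b, gene="atp6")
        ev = {e.position: e for e in rec.events}
        assert ev[58].codon_before == "tAt" and ev[58].codon_after == "tCt"
        assert ev[58].synonymy == "nonsynonymous"
        assert ev[766].codon_before == "tcT" and ev[766].codon_after == "tcC"
        assert ev[766].synonymy == "synonymous"

    def test_ninety_bp_deletion(self, rng):
        a = make_cds(rng, 489)
        b = a[:455] + a[545:]
        rec = compare_gene(a, b)
        assert (rec.length_a, rec.length_b) == (1467, 1377)
        dels = [e for e in rec.events if e.kind == "deletion"]
        assert len(dels) == 1 and dels[0].length == 90
        assert rec.length_b - rec.length_a == rec.net_indel

    def test_insertion_reported_against_maintainer_frame(self, rng):
        a = make_cds(rng, 261)
        ins = make_cds(rng, 13)[3:-3]  # 33 nt
        b = a[:382] + ins + a[382:]
        rec = compare_gene(a, b)
        (e,) = [e for e in rec.events if e.kind == "insertion"]
        assert e.length == 33 and e.synonymy == "indel"

    def test_antisymmetric(self, rng):
        a = make_cds(rng, 150, fixed={58: "TAT"})
        b = a[:58] + "C" + a[59:]
        fwd = compare_gene(a, b).events[0]
        rev = compare_gene(b, a).events[0]
        assert (fwd.codon_before, fwd.codon_after) == (rev.codon_after, rev.codon_before)


def _genome_with(rng, genes):
    """genes: list of (name, part, seq). Builds a genome with spaced genes."""
    chunks = []
    feats = []
    pos = 0
    for name, part, seq in genes:
        gap = random_dna(rng, 100)
        chunks += [gap, seq]
        pos += len(gap)
        feats.append(GeneFeature(name, pos, pos + len(seq), "+", "protein", part))
        pos += len(seq)
    chunks.append(random_dna(rng, 100))
    return CircularGenome(id=f"g{rng.integers(1e6)}", seq="".join(chunks), genes=feats)


class TestHomologsAndCopies:
    def test_single_copy_pairing(self, rng):
        atp6 = make_cds(rng, 100)
        gA = _genome_with(rng, [("atp6", None, atp6)])
        gB = _genome_with(rng, [("atp6", None, atp6)])
        hp = match_homologs(gA, gB)
        assert len(hp.pairs) == 1 and not hp.only_a and not hp.only_b

    def test_extra_maintainer_copy_reported(self, rng):
        nad3 = make_cds(rng, 119)
        gA = _genome_with(rng, [("nad3", None, nad3), ("nad3", "D2", nad3)])
        gB = _genome_with(rng, [("nad3", None, nad3)])
        hp = match_homologs(gA, gB)
        assert len(hp.pairs) == 1 and hp.only_a == [("nad3", "D2")]

    def test_gene_absent_from_cms(self, rng):
        gA = _genome_with(rng, [("rpl2", None, make_cds(rng, 80))])
        gB = _genome_with(rng, [("atp6", None, make_cds(rng, 80))])
        hp = match_homologs(gA, gB)
        assert ("rpl2", "D1") in hp.only_a

    def test_parts_are_one_copy_but_d_labels_are_copies(self, rng):
        nad2 = make_cds(rng, 100)
        atp9 = make_cds(rng, 75)
        g = _genome_with(rng, [
            ("nad2", "a", nad2[:150]), ("nad2", "b", nad2[150:]),
            ("atp9", None, atp9), ("atp9", "D2", atp9), ("atp9", "D3", atp9),
        ])
        cp = gene_copies(g)
        assert len(cp["nad2"]) == 1 and cp["nad2"][0][1] == nad2
        assert len(cp["atp9"]) == 3
        df = copy_numbers([g])
        assert df.loc["nad2", g.id] == 1 and df.loc["atp9", g.id] == 3


class TestIntersectCandidates:
    def test_planted_overlap(self):
        a = ["atp6", "cox2", "nad2", "sdh3", "atp1", "ccmB"]
        b = ["atp6", "cox2", "nad2", "sdh3", "rps3", "ccmC"]
        assert intersect_candidates([a, b]) == ["atp6", "cox2", "nad2", "sdh3"]

    def test_disjoint_and_identical(self):
        assert intersect_candidates([{"a"}, {"b"}]) == []
        assert intersect_candidates([{"x", "y"}, {"x", "y"}]) == ["x", "y"]
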