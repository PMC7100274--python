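import numpy as np
import pytest

from mitocompare.genome_io import CircularGenome, revcomp, rotate
from mitocompare.synteny import (
    UniqueRegion,
    aligned_fraction,
    annotate_region,
    build_synteny_blocks,
    classify_blocks,
    find_unique_regions,
)
from tests.conftest import random_dna


def G(seq, gid="g"):
    return CircularGenome(id=gid, seq=seq)


@pytest.fixture(scope="module")
def base_seq():
    return random_dna(np.random.default_rng(5), 100_000)


class TestBlockBuilding:
    def test_identical_genomes_single_collinear_block(self, base_seq):
        blocks = classify_blocks(build_synteny_blocks(G(base_seq, "a"), G(base_seq, "b")))
        assert len(blocks) == 1
        b = blocks[0]
        assert b.orientation == "forward" and b.rearrangement_class == "collinearity"
        assert b.a_interval == (0, 100_000)
        assert aligned_fraction(blocks, "a", 100_000) == pytest.approx(100.0)

    def test_internal_inversion(self, base_seq):
        s = base_seq
        other = s[:40_000] + revcomp(s[40_000:50_000]) + s[50_000:]
        blocks = classify_blocks(build_synteny_blocks(G(s, "a"), G(other, "b")))
        classes = [b.rearrangement_class for b in blocks]
        assert classes == ["collinearity", "inversion", "collinearity"]
        assert blocks[1].orientation == "reverse"

    def test_translocation_same_strand(self, base_seq):
        s = base_seq
        seg = s[20_000:30_000]
        other = s[:20_000] + s[30_000:70_000] + seg + s[70_000:]
        blocks = classify_blocks(build_synteny_blocks(G(s, "a"), G(other, "b")))
        moved = [b for b in blocks if b.rearrangement_class == "translocation"]
        assert len(moved) == 1
        assert abs(moved[0].a_start - 20_000) < 100 and abs(moved[0].a_end - 30_000) < 100

    def test_every_block_has_exactly_one_class(self, base_seq):
        s = base_seq
        other = s[:30_000] + revcomp(s[30_000:40_000]) + s[50_000:80_000] \
            + s[40_000:50_000] + s[80_000:]
        blocks = classify_blocks(build_synteny_blocks(G(s, "a"), G(other, "b")))
        assert all(b.rearrangement_class in
                   ("collinearity", "translocation", "inversion", "trans_inv")
                   for b in blocks)
        # non-overlapping block spans on both genomes
        for which in ("a", "b"):
            ivs = sorted(
                (b.a_interval if which == "a" else b.b_interval) for b in blocks
            )
            assert all(x[1] <= y[0] for x, y in zip(ivs, ivs[1:]))

    def test_mirror_pair_symmetry(self, base_seq):
        s = base_seq
        other = s[:40_000] + revcomp(s[40_000:50_000]) + s[50_000:]
        fwd = classify_blocks(build_synteny_blocks(G(s, "a"), G(other, "b")))
        rev = classify_blocks(build_synteny_blocks(G(other, "b"), G(s, "a")))
        assert sorted(b.rearrangement_class for b in fwd) == \
            sorted(b.rearrangement_class for b in rev)
        assert len(fwd) == len(rev)

    def test_classification_rotation_invariant(self, base_seq):
        s = base_seq
        other = s[:40_000] + revcomp(s[40_000:50_000]) + s[50_000:]
        rotated = rotate(G(other, "b"), 63_000)
        blocks = classify_blocks(build_synteny_blocks(G(s, "a"), rotated))
        classes = sorted(b.rearrangement_class for b in blocks)
        assert classes.count("inversion") == 1
        assert "trans_inv" not in classes

    def test_aligned_fraction_with_planted_deletion(self, base_seq):
        s = base_seq
        other = s[:50_000] + s[60_000:]  # 10% of a missing from b
        blocks = build_synteny_blocks(G(s, "a"), G(other, "b"))
        assert aligned_fraction(blocks, "a", len(s)) == pytest.approx(90.0, abs=1.0)
        assert aligned_fraction(blocks, "b", len(other)) == pytest.approx(100.0, abs=1.0)

    def test_disjoint_genomes_no_blocks(self, rng):
        a, b = random_dna(rng, 20_000), random_dna(rng, 20_000)
        blocks = build_synteny_blocks(G(a, "a"), G(b, "b"))
        assert blocks == []
        assert aligned_fraction(blocks, "a", 20_000) == 0.0


class TestUniqueRegions:
    def test_insertion_recovered(self, base_seq, rng):
        ins = random_dna(rng, 41_000)
        cms = G(base_seq[:60_000] + ins + base_seq[60_000:], "cms")
        (r,) = find_unique_regions([cms], [G(base_seq, "m")], annotate=False)
        assert r.length == pytest.approx(41_000, abs=300)
        assert abs(r.start - 60_000) < 300

    def test_identical_pair_no_regions(self, base_seq):
        assert find_unique_regions(
            [G(base_seq, "cms")], [G(base_seq, "m")], annotate=False
        ) == []

    def test_only_shared_regions_survive_with_two_cms(self, base_seq, rng):
        shared = random_dna(rng, 8_000)
        p1, p2 = random_dna(rng, 6_000), random_dna(rng, 6_000)
        c1 = G(base_seq[:30_000] + shared + base_seq[30_000:80_000] + p1 + base_seq[80_000:], "c1")
        c2 = G(base_seq[:50_000] + p2 + base_seq[50_000:90_000] + shared + base_seq[90_000:], "c2")
        regs = find_unique_regions([c1, c2], [G(base_seq, "m1"), G(base_seq, "m2")],
                                   annotate=False)
        assert len(regs) == 2 and all(r.shared for r in regs)
        assert {r.genome_id for r in regs} == {"c1", "c2"}
        assert all(abs(r.length - 8_000) < 300 for r in regs)


class TestAnnotateRegion:
    def test_overlap_rules(self, rng):
        from mitocompare.genome_io import GeneFeature

        seq = random_dna(rng, 5_000)
        genome = CircularGenome(
            id="g", seq=seq,
            genes=[GeneFeature("atp6", 999, 1500, "+", "protein"),  # 1 bp overlap
                   GeneFeature("cob", 3_000, 3_600, "+", "protein")],  # outside
        )
        region = UniqueRegion("g", 100, 1000)
        annotate_region(region, genome, orfs=[], repeats=[])
        assert [g[0] for g in region.genes] == ["atp6"]
        empty = UniqueRegion("g", 1600, 2900)
        annotate_region(empty, genome, orfs=[], repeats=[])
        assert empty.genes == [] and empty.orfs == []
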