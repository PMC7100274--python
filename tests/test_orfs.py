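import numpy as np
import pytest

from mitocompare.genome_io import CircularGenome, revcomp
from mitocompare.orfs import (
    OrfRecord,
    STOPS,
    assign_orf_names,
    find_orfs,
    name_orf,
    screen_specific_orfs,
    shared_specific_orfs,
)
from tests.conftest import random_dna


def make_orf(rng, aa: int) -> str:
    codons = [c for c in
              ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
              if c not in STOPS]
    body = "".join(codons[i] for i in rng.integers(0, len(codons), aa - 1))
    return "ATG" + body + "TAA"


def brute_force_orfs(seq: str, min_len: int):
    """Exhaustive position x strand x frame enumeration on a circle."""
    L = len(seq)
    best = {}
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        d = s + s
        for start in range(L):
            if d[start : start + 3] != "ATG":
                continue
            p = start
            while p + 3 <= start + L:
                codon = d[p : p + 3]
                if codon in STOPS:
                    nt = p + 3 - start
                    if nt > min_len:
                        key = (strand, (p + 3) % L)
                        if key not in best or nt > best[key][1]:
                            best[key] = (start, nt)
                    break
                p += 3
    out = set()
    for (strand, _stop), (start, nt) in best.items():
        fwd_start = start if strand == "+" else (L - (start + nt)) % L
        out.add((strand, fwd_start, nt))
    return out


class TestFindOrfs:
    def test_minimal_example(self):
        (o,) = find_orfs("ATGAAATAA", min_len=0)
        assert (o.nt_length, o.aa_length, o.strand) == (9, 2, "+")

    def test_reverse_strand_forward_coordinates(self, rng):
        orf = make_orf(rng, 121)
        g = random_dna(rng, 2000) + revcomp(orf) + random_dna(rng, 1000)
        hits = [o for o in find_orfs(g, 300) if o.seq == orf]
        assert len(hits) == 1 and hits[0].strand == "-"
        assert hits[0].start == 2000

    def test_origin_spanning_orf_found_once(self, rng):
        orf = make_orf(rng, 121)
        # "TAA" frames the wrapped start so no upstream ATG can extend it
        g = CircularGenome(id="t", seq=orf[200:] + random_dna(rng, 3000) + "TAA" + orf[:200])
        hits = [o for o in find_orfs(g, 300) if o.seq == orf]
        assert len(hits) == 1
        assert hits[0].end > g.length  # wraps explicitly

    def test_exactly_300_nt_excluded(self, rng):
        orf = make_orf(rng, 99)  # 300 nt including the stop
        g = "TAA" + orf + random_dna(rng, 600)
        assert all(o.nt_length != 300 for o in find_orfs(g, 300))
        assert any(o.nt_length == 300 for o in find_orfs(g, 299))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            seq = random_dna(rng, 3000)
            mine = {(o.strand, o.start, o.nt_length) for o in find_orfs(seq, 120)}
            assert mine == brute_force_orfs(seq, 120)

    def test_translation_clean(self, rng):
        from Bio.Seq import Seq

        seq = random_dna(rng, 3000)
        for o in find_orfs(seq, 120):
            aa = str(Seq(o.seq).translate())
            assert aa.endswith("*") and "*" not in aa[:-1]
            assert o.aa_length == o.nt_length // 3 - 1


class TestNaming:
    def test_collision_suffixes(self):
        names = set()
        for expected in ("orf115", "orf115b", "orf115c"):
            o = OrfRecord(0, 348, "+", 0, 348, 115, "")
            got = name_orf(o, names)
            assert got == expected
            names.add(got)

    def test_assignment_in_genomic_order(self):
        a = OrfRecord(100, 448, "+", 0, 348, 115, "")
        b = OrfRecord(900, 1248, "+", 0, 348, 115, "")
        assign_orf_names([b, a])
        assert a.id == "orf115" and b.id == "orf115b"


class TestSpecificityScreen:
    def _pair(self, rng, planted_aa=121):
        maint = random_dna(rng, 20000)
        shared_orf = make_orf(rng, 150)
        maint = maint[:5000] + shared_orf + maint[5000:]
        novel = make_orf(rng, planted_aa)
        cms = maint[:12000] + "TAA" + novel + maint[12000:]
        return (CircularGenome(id="c", seq=cms), CircularGenome(id="m", seq=maint),
                novel, shared_orf)

    def test_verbatim_match_excluded_novel_retained(self, rng):
        cms, maint, novel, shared = self._pair(rng)
        spec = screen_specific_orfs(cms, maint)
        seqs = {o.seq for o in spec}
        assert novel in seqs and shared not in seqs

    def test_boundary_two_mismatches_in_300_excluded(self, rng):
        # identity 298/300 = 0.9933 >= 0.99 -> not specific
        orf = make_orf(rng, 99)
        cms_orf = orf[:150] + ("A" if orf[150] != "A" else "C") + orf[151:250] \
            + ("G" if orf[250] != "G" else "T") + orf[251:]
        maint = random_dna(rng, 8000) + orf + random_dna(rng, 8000)
        cms = random_dna(rng, 6000) + "TAA" + cms_orf + random_dna(rng, 6000)
        spec = screen_specific_orfs(
            CircularGenome(id="c", seq=cms), CircularGenome(id="m", seq=maint),
            min_len=250,
        )
        assert cms_orf not in {o.seq for o in spec}

    def test_threshold_monotone(self, rng):
        cms, maint, _n, _s = self._pair(rng)
        sizes = [
            len(screen_specific_orfs(cms, maint, sim_threshold=t))
            for t in (0.95, 0.99, 0.999)
        ]
        assert sizes == sorted(sizes)


class TestSharedSpecific:
    def test_shared_and_private(self, rng):
        shared = make_orf(rng, 140)
        priv1 = make_orf(rng, 130)
        priv2 = make_orf(rng, 135)

        def rec(seq, start):
            return OrfRecord(start, start + len(seq), "+", 0, len(seq),
                             len(seq) // 3 - 1, seq)

        sets = {
            "c1": [rec(shared, 0), rec(priv1, 1000)],
            "c2": [rec(shared, 50), rec(priv2, 2000)],
        }
        result = shared_specific_orfs(sets)
        assert result.shared_count == 1
        assert result.shared[0]["c1"].seq == shared

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            shared_specific_orfs({"c1": []})
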