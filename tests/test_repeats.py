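import numpy as np
import pytest

from mitocompare.align import local_align_dp
from mitocompare.genome_io import CircularGenome, revcomp
from mitocompare.repeats import (
    canonical_motif,
    classify_repeat_size,
    find_dispersed_repeats,
    find_palindromes,
    find_ssrs,
    fraction_aligned_to,
    merge_intervals,
    summarize_repeats,
    union_length,
)
from tests.conftest import random_dna


@pytest.mark.parametrize(
    "length, cls",
    [(1, "small"), (49, "small"), (50, "intermediate"), (500, "intermediate"),
     (501, "large"), (5000, "large")],
)
def test_size_class_boundaries(length, cls):
    assert classify_repeat_size(length) == cls


def test_size_class_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_repeat_size(0)


class TestDispersedRepeats:
    def test_planted_direct_repeat(self, rng):
        X = random_dna(rng, 600)
        g = random_dna(rng, 3000) + X + random_dna(rng, 2000) + X + random_dna(rng, 3000)
        (p,) = find_dispersed_repeats(g)
        assert p.orientation == "DR" and p.size_class == "large"
        assert abs(p.interval_1[0] - 3000) < 20 and abs(p.interval_2[0] - 5600) < 20

    def test_planted_inverted_repeat(self, rng):
        X = random_dna(rng, 600)
        g = random_dna(rng, 3000) + X + random_dna(rng, 2000) + revcomp(X) + random_dna(rng, 3000)
        (p,) = find_dispersed_repeats(g)
        assert p.orientation == "IR"

    def test_mutated_copy_identity_and_oracle(self, rng):
        X = random_dna(rng, 600)
        X2 = list(X)
        for i in rng.choice(600, size=30, replace=False):  # 5% divergence
            X2[i] = [c for c in "ACGT" if c != X2[i]][rng.integers(3)]
        g = random_dna(rng, 2000) + X + random_dna(rng, 1500) + "".join(X2) + random_dna(rng, 2000)
        (p,) = find_dispersed_repeats(g)
        assert 0.93 <= p.identity <= 0.97
        # oracle re-validation on the two arms
        arm1 = g[p.interval_1[0] : p.interval_1[1]]
        arm2 = g[p.interval_2[0] : p.interval_2[1]]
        oracle = local_align_dp(arm1, arm2)
        assert abs(oracle.identity - p.identity) < 0.01

    def test_identity_at_exactly_090_excluded(self, rng):
        # 20 matching columns of 22 = 0.909 passes; 18/20 = 0.90 must not
        X = random_dna(rng, 200)
        X2 = list(X)
        for i in range(0, 200, 10):  # exactly 10% mismatches
            X2[i] = [c for c in "ACGT" if c != X2[i]][0]
        g = random_dna(rng, 1000) + X + random_dna(rng, 800) + "".join(X2) + random_dna(rng, 1000)
        for p in find_dispersed_repeats(g):
            assert p.identity > 0.90  # strict: 0.90 itself never reported

    def test_rotation_invariance_on_planted_case(self, rng):
        X = random_dna(rng, 400)
        g = CircularGenome(
            id="g",
            seq=random_dna(rng, 2000) + X + random_dna(rng, 1500) + X + random_dna(rng, 2000),
        )
        base = find_dispersed_repeats(g)
        from mitocompare.genome_io import rotate

        rot = rotate(g, 1000)
        rotated = find_dispersed_repeats(rot)
        assert len(base) == len(rotated) == 1
        assert base[0].length == pytest.approx(rotated[0].length, abs=10)
        assert (base[0].interval_1[0] - rotated[0].interval_1[0]) % g.length == 1000


class TestPalindromes:
    def test_abutting_arms_flagged(self, rng):
        Y = random_dna(rng, 1491)
        g = random_dna(rng, 3000) + Y + revcomp(Y) + random_dna(rng, 3000)
        (p,) = find_palindromes(g, min_len=1000)
        assert p.palindromic and abs(p.length - 1491) <= 10
        assert p.spacer == 0

    def test_distant_ir_not_palindromic(self, rng):
        Y = random_dna(rng, 1491)
        g = random_dna(rng, 2000) + Y + random_dna(rng, 10000) + revcomp(Y) + random_dna(rng, 2000)
        assert find_palindromes(g, min_len=1000, max_spacer=0) == []
        (p,) = find_dispersed_repeats(g, min_len=1000)
        assert p.orientation == "IR" and not p.palindromic

    def test_tiny_exhaustive_case(self):
        (p,) = find_palindromes("ACGCGT", min_len=3)
        assert p.interval_1 == (0, 3) and p.interval_2 == (3, 6)


def brute_force_ssrs(seq, max_motif=6, min_total=12,
                     min_copies={1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}):
    """Reference scanner: try every motif at every position; maximal runs
    only, then the documented longest-first leftmost overlap resolution."""
    cands = []
    n = len(seq)
    for m in range(1, max_motif + 1):
        for start in range(n - 2 * m + 1):
            motif = seq[start : start + m]
            if motif in (motif + motif)[1:-1]:
                continue
            if start > 0 and seq[start - 1] == seq[start + m - 1]:
                continue  # run continues to the left: not maximal
            end = start + m
            while end < n and seq[end] == seq[end - m]:
                end += 1
            span = end - start
            if span >= min_total and span / m >= min_copies[m]:
                cands.append((start, end, m))
    cands.sort(key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    kept = []
    for s, e, _m in cands:
        if all(e <= ks or s >= ke for ks, ke in kept):
            kept.append((s, e))
    return kept


class TestSsrs:
    def test_dimer_example(self):
        (r,) = find_ssrs("ACACACACACAC")
        assert (r.motif, r.copies, r.motif_class) == ("AC", 6.0, "dimer")

    def test_planted_tetramer_canonicalized(self, rng):
        g = random_dna(rng, 800) + "CTTA" * 4 + random_dna(rng, 800)
        hits = [r for r in find_ssrs(g) if len(r.motif) == 4]
        assert len(hits) == 1
        assert hits[0].motif == canonical_motif("CTTA") == "ACTT"

    def test_below_copy_threshold_not_reported(self):
        assert find_ssrs("AAAAAA" + "ACGTGCTTGCA" * 10) == []

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            seq = random_dna(rng, 2000)
            # salt with a couple of true SSRs
            seq = seq[:500] + "TA" * 8 + seq[500:1200] + "GGC" * 5 + seq[1200:]
            mine = {(r.start, r.end) for r in find_ssrs(seq)}
            ref = set(brute_force_ssrs(seq))
            assert mine == ref


class TestSummaries:
    def test_planted_counts(self, rng):
        X, Y = random_dna(rng, 600), random_dna(rng, 100)
        g = CircularGenome(
            id="g",
            seq=(random_dna(rng, 2000) + X + random_dna(rng, 1500) + X
                 + random_dna(rng, 1500) + Y + random_dna(rng, 1200) + revcomp(Y)
                 + random_dna(rng, 500) + "AC" * 7 + random_dna(rng, 1500)),
        )
        s = summarize_repeats(g)
        assert s.by_size["large"] == 1 and s.by_size["intermediate"] == 1
        assert s.by_orientation == {"DR": 1, "IR": 1, "SSR": 1}

    def test_repeat_free_genome_fraction_zero(self, rng):
        g = CircularGenome(id="g", seq=random_dna(rng, 3000))
        s = summarize_repeats(g, repeats=find_dispersed_repeats(g, min_len=60), ssrs=[])
        assert s.repeat_fraction == 0.0

    def test_union_counts_positions_once(self):
        assert union_length([(0, 600), (500, 1100)]) == 1100
        assert merge_intervals([(0, 10), (20, 30)]) == [(0, 10), (20, 30)]


class TestFractionAlignedTo:
    def test_self_is_100(self, rng):
        g = random_dna(rng, 5000)
        assert fraction_aligned_to(g, g) == pytest.approx(100.0)

    def test_unrelated_is_0(self, rng):
        assert fraction_aligned_to(random_dna(rng, 5000), random_dna(rng, 5000)) == 0.0

    def test_planted_fraction(self, rng):
        ref = random_dna(rng, 30000)
        block = ref[5000:15000]
        g = random_dna(rng, 45000) + block + random_dna(rng, 45000)
        assert fraction_aligned_to(g, ref) == pytest.approx(10.0, abs=0.2)
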