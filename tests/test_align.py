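import numpy as np
import pytest
from Bio import Align

from mitocompare.align import (
    AlignmentHit,
    ScoringScheme,
    anchored_align,
    local_align_dp,
    percent_identity,
)
from mitocompare.genome_io import revcomp
from tests.conftest import random_dna


def biopython_local_score(a, b, scoring):
    """Independent Smith-Waterman reference (affine, same cost model)."""
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open + scoring.gap_extend
    al.extend_gap_score = scoring.gap_extend
    try:
        return al.score(a, b)
    except Exception:
        return 0.0


class TestLocalAlignDp:
    def test_self_alignment_full_identity(self):
        h = local_align_dp("ACGTACGT", "ACGTACGT")
        assert h.identity == 1.0 and h.q_interval == (0, 8) and h.score == 8

    def test_no_similarity_zero_hit(self):
        h = local_align_dp("AAAA", "TTTT")
        assert h.score == 0 and h.columns == 0

    def test_hand_filled_matrix(self):
        h = local_align_dp("ACGTTGCA", "ACGATGCA", ScoringScheme(1, -1, -2, -1))
        assert h.score == 6
        assert h.identity == pytest.approx(7 / 8)

    def test_cap_enforced(self, rng):
        with pytest.raises(ValueError):
            local_align_dp(random_dna(rng, 2000), random_dna(rng, 2000), cap=10_000)

    def test_matches_independent_sw_implementation(self, rng):
        scoring = ScoringScheme()
        for _ in range(40):
            n = int(rng.integers(20, 120))
            a = random_dna(rng, n)
            if rng.random() < 0.5:
                b = list(a)
                for p in rng.choice(n, size=max(1, n // 10), replace=False):
                    b[p] = random_dna(rng, 1)
                b = "".join(b)
            else:
                b = random_dna(rng, int(rng.integers(20, 120)))
            assert local_align_dp(a, b, scoring).score == pytest.approx(
                biopython_local_score(a, b, scoring)
            )


class TestAnchoredAlign:
    def test_exact_copy_single_forward_hit(self, rng):
        a = random_dna(rng, 5000)
        (h,) = anchored_align(a, a)
        assert h.orientation == "forward" and h.identity == 1.0
        assert h.q_interval == (0, 5000) and h.s_interval == (0, 5000)

    def test_reverse_complement_single_reverse_hit(self, rng):
        a = random_dna(rng, 5000)
        (h,) = anchored_align(a, revcomp(a))
        assert h.orientation == "reverse" and h.identity == 1.0

    def test_internal_inversion_three_hits(self, rng):
        a = random_dna(rng, 20000)
        b = a[:9000] + revcomp(a[9000:11000]) + a[11000:]
        hits = anchored_align(a, b, min_len=500)
        assert [h.orientation for h in hits] == ["forward", "reverse", "forward"]
        mid = hits[1]
        assert abs(mid.q_start - 9000) < 50 and abs(mid.q_end - 11000) < 50

    def test_strand_mirror_property(self, rng):
        a = random_dna(rng, 6000)
        b = a[:3000] + revcomp(random_dna(rng, 100)) + a[3000:]
        fwd = anchored_align(a, b)
        swapped = anchored_align(a, revcomp(b))
        assert sorted(h.orientation for h in fwd) == sorted(
            {"forward": "reverse", "reverse": "forward"}[h.orientation]
            for h in swapped
        )

    def test_deterministic(self, rng):
        a = random_dna(rng, 4000)
        b = a[:2000] + random_dna(rng, 500) + a[2000:]
        h1 = anchored_align(a, b)
        h2 = anchored_align(a, b)
        assert [(h.q_interval, h.s_interval, h.score) for h in h1] == [
            (h.q_interval, h.s_interval, h.score) for h in h2
        ]

    def test_k_too_small_rejected(self):
        with pytest.raises(ValueError):
            anchored_align("ACGTACGTACGT", "ACGTACGTACGT", k=4)


def test_anchored_never_beats_dp_and_matches_when_seeded():
    """On random pairs <= 300 bp the anchored aligner never exceeds the
    exact DP score and equals it whenever the optimal alignment contains an
    exact run of at least k columns (a seed)."""
    rng = np.random.default_rng(42)
    scoring = ScoringScheme()
    k = 12
    n_equal = 0
    for trial in range(200):
        n = int(rng.integers(60, 300))
        a = random_dna(rng, n)
        mode = trial % 3
        if mode == 0:  # mutated copy
            b = list(a)
            for p in rng.choice(n, size=int(n * 0.05) + 1, replace=False):
                b[p] = random_dna(rng, 1)
            b = "".join(b)
        elif mode == 1:  # shared planted segment in random context
            seg = a[n // 4 : n // 4 + n // 2]
            b = random_dna(rng, 40) + seg + random_dna(rng, 40)
        else:  # unrelated
            b = random_dna(rng, n)
        best_dp = local_align_dp(a, b, scoring)
        hits = anchored_align(a, b, k=k, min_identity=0.0, min_len=1,
                              scoring=scoring, both_strands=False)
        best_anchored = max((h.score for h in hits), default=0.0)
        assert best_anchored <= best_dp.score + 1e-9
        ops = best_dp.ops
        has_seed = False
        if ops is not None and len(ops):
            run = best = 0
            for op in ops:
                run = run + 1 if op == 0 else 0
                best = max(best, run)
            has_seed = best >= k
        if has_seed:
            assert best_anchored == pytest.approx(best_dp.score)
            n_equal += 1
    assert n_equal > 100  # the equality branch was exercised


class TestPercentIdentity:
    def test_boundary_90(self):
        h = AlignmentHit(0, 100, 0, 100, "forward", 90, 100, 80.0)
        assert percent_identity(h) == pytest.approx(0.90)
        assert not percent_identity(h) > 0.90  # NOT "more than 90%"

    def test_gap_columns_count(self):
        # 100-mer vs same with 2 bp deleted: 100 columns + 2 gap columns
        h = AlignmentHit(0, 100, 0, 98, "forward", 98, 100, 90.0)
        assert percent_identity(h) == pytest.approx(0.98)

    def test_zero_columns_error(self):
        h = AlignmentHit(0, 0, 0, 0, "forward", 0, 0, 0.0)
        with pytest.raises(ZeroDivisionError):
            percent_identity(h)

    def test_real_two_bp_deletion(self, rng):
        a = random_dna(rng, 100)
        b = a[:50] + a[52:]
        h = local_align_dp(a, b, ScoringScheme(1, -2, -2, -1))
        assert h.identity == pytest.approx(100 / 102, abs=0.02)


def test_scoring_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(match=-1)
    with pytest.raises(ValueError):
        ScoringScheme(mismatch=2)
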