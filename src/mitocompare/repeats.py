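"""Repeat landscape of a single genome.

Dispersed repeats are discovered by aligning the genome against itself and
against its own reverse complement (seed-and-extend); a pair counts as a
repeat only above 90% identity (strict), following the definition used for
organelle repeat libraries. Pairs are classed by arm length as small
(<50 bp), intermediate (50-500 bp) or large (>500 bp), and by orientation
as direct (DR) or inverted (IR); an IR whose arms are contiguous is a
palindrome. SSRs (motif 1-6 bp tandem arrays) are detected separately and
are excluded from the dispersed-pair inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitocompare.align import (
    DEFAULT_SCORING,
    AlignmentHit,
    ScoringScheme,
    _extend_chain,
    chain_seeds,
    encode,
    seed_matches,
)
from mitocompare.genome_io import CircularGenome, revcomp

SIZE_SMALL = "small"
SIZE_INTERMEDIATE = "intermediate"
SIZE_LARGE = "large"

DEFAULT_MIN_COPIES = {1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}


def classify_repeat_size(length_bp: int) -> str:
    """<50 -> small, 50-500 inclusive -> intermediate, >500 -> large."""
    if length_bp < 1:
        raise ValueError("repeat length must be positive")
    if length_bp < 50:
        return SIZE_SMALL
    if length_bp <= 500:
        return SIZE_INTERMEDIATE
    return SIZE_LARGE


@dataclass
class RepeatPair:
    """A dispersed repeat: two intervals of one genome plus orientation."""

    interval_1: tuple[int, int]
    interval_2: tuple[int, int]
    orientation: str  # 'DR' | 'IR'
    identity: float
    length: int  # alignment columns of the arm-vs-arm alignment
    matches: int = 0
    score: float = 0.0
    palindromic: bool = False

    def __post_init__(self) -> None:
        if self.interval_1[0] > self.interval_2[0]:
            self.interval_1, self.interval_2 = self.interval_2, self.interval_1
        if not self.identity > 0.0:
            raise ValueError("repeat identity must be positive")

    @property
    def size_class(self) -> str:
        return classify_repeat_size(self.length)

    @property
    def spacer(self) -> int:
        return self.interval_2[0] - self.interval_1[1]


@dataclass
class SSRRecord:
    """A simple sequence repeat (tandem array of a 1-6 bp motif)."""

    motif: str  # canonical (lexicographically least rotation)
    copies: float
    start: int
    end: int
    motif_observed: str = ""

    _CLASS = {1: "monomer", 2: "dimer", 3: "trimer", 4: "tetramer",
              5: "pentamer", 6: "hexamer"}

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def motif_class(self) -> str:
        return self._CLASS[len(self.motif)]


@dataclass
class RepeatSummary:
    genome_id: str
    genome_length: int
    by_size: dict = field(default_factory=dict)
    by_orientation: dict = field(default_factory=dict)
    ssr_count: int = 0
    total_repeat_bp: int = 0

    @property
    def repeat_fraction(self) -> float:
        return self.total_repeat_bp / self.genome_length


def _interval_overlap(a, b) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of half-open intervals."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def union_length(intervals) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def _dedup_pairs(pairs: list[RepeatPair], contain: float = 0.8) -> list[RepeatPair]:
    kept: list[RepeatPair] = []
    for p in sorted(pairs, key=lambda p: (-p.score, p.interval_1, p.interval_2)):
        redundant = False
        for q in kept:
            if q.orientation != p.orientation:
                continue
            o1 = _interval_overlap(p.interval_1, q.interval_1)
            o2 = _interval_overlap(p.interval_2, q.interval_2)
            l1 = p.interval_1[1] - p.interval_1[0]
            l2 = p.interval_2[1] - p.interval_2[0]
            if o1 >= contain * l1 and o2 >= contain * l2:
                redundant = True
                break
        if not redundant:
            kept.append(p)
    return sorted(kept, key=lambda p: (p.interval_1, p.interval_2))


def find_dispersed_repeats(
    genome: CircularGenome | str,
    min_identity: float = 0.90,
    min_len: int = 20,
    k: int = 12,
    band: int = 32,
    max_chain_gap: int = 200,
    max_occ: int = 200,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[RepeatPair]:
    """Self-comparison repeat discovery; identity threshold is strict (>).

    The trivial full-length self-match and (i,j)/(j,i) mirror duplicates
    are removed; forward pairs whose arms overlap each other (tandem
    self-similarity) are left to the SSR detector.
    """
    seq = genome.seq if isinstance(genome, CircularGenome) else genome
    n = len(seq)
    ca = encode(seq)
    pairs: list[RepeatPair] = []

    # forward strand: canonical seeds i < j (excludes the trivial diagonal)
    ia, jb = seed_matches(ca, ca, k, max_occ)
    keep = jb > ia
    for ch in chain_seeds(ia[keep], jb[keep], k, band, max_chain_gap):
        h = _extend_chain(ca, ca, ch, k, scoring, band, pad=100)
        if h is None or h.columns < min_len or not h.identity > min_identity:
            continue
        if _interval_overlap(h.q_interval, h.s_interval) > 0:
            continue  # tandem self-similarity -> SSR territory
        pairs.append(
            RepeatPair(h.q_interval, h.s_interval, "DR", h.identity,
                       h.columns, h.matches, h.score)
        )

    # reverse strand: genome vs its own reverse complement
    car = encode(revcomp(seq))
    ia, jb = seed_matches(ca, car, k, max_occ)
    # forward-coordinate start of the reverse-strand seed
    s_fwd = n - jb - k
    keep = ia <= s_fwd  # one of each mirrored seed pair
    for ch in chain_seeds(ia[keep], jb[keep], k, band, max_chain_gap):
        h = _extend_chain(ca, car, ch, k, scoring, band, pad=100)
        if h is None or h.columns < min_len or not h.identity > min_identity:
            continue
        i1 = h.q_interval
        i2 = (n - h.s_end, n - h.s_start)
        if _interval_overlap(i1, i2) > 0:
            # palindrome-spanning self-hit: split the union at its midpoint
            u0 = min(i1[0], i2[0])
            u1 = max(i1[1], i2[1])
            mid = (u0 + u1) // 2
            arm = mid - u0
            if arm < max(min_len, 1):
                continue
            pairs.append(
                RepeatPair(
                    (u0, mid), (mid, u1), "IR", h.identity,
                    arm, int(round(h.identity * arm)), h.score,
                )
            )
        else:
            pairs.append(
                RepeatPair(i1, i2, "IR", h.identity, h.columns, h.matches, h.score)
            )

    return _dedup_pairs(pairs)


def find_palindromes(
    genome: CircularGenome | str,
    min_len: int = 500,
    max_spacer: int = 0,
    **kwargs,
) -> list[RepeatPair]:
    """Inverted-repeat pairs whose arms are adjacent (spacer <= max_spacer).

    For arms shorter than the seeding k-mer (or tiny inputs) an exhaustive
    center-expansion scan is used instead of the seeded detector.
    """
    seq = genome.seq if isinstance(genome, CircularGenome) else genome
    n = len(seq)
    out: list[RepeatPair] = []
    if min_len < 12 or n < 200:
        # exhaustive: expand around every center / spacer
        for t in range(max_spacer + 1):
            for c in range(n):  # arm1 ends at c, arm2 starts at c + t
                l = 0
                while (
                    c - l - 1 >= 0
                    and c + t + l < n
                    and seq[c - l - 1] == _COMP.get(seq[c + t + l], "?")
                ):
                    l += 1
                if l >= min_len:
                    out.append(
                        RepeatPair(
                            (c - l, c), (c + t, c + t + l), "IR", 1.0, l, l,
                            palindromic=True,
                        )
                    )
        return _dedup_pairs(out, contain=0.99)
    for p in find_dispersed_repeats(genome, min_len=min_len, **kwargs):
        if p.orientation == "IR" and p.length >= min_len and p.spacer <= max_spacer:
            p.palindromic = True
            out.append(p)
    return out


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _is_primitive(motif: str) -> bool:
    return motif not in (motif + motif)[1:-1]


def canonical_motif(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_ssrs(
    genome: CircularGenome | str,
    max_motif: int = 6,
    min_total_len: int = 12,
    min_copies: dict[int, int] | None = None,
) -> list[SSRRecord]:
    """Maximal tandem arrays of primitive 1-6 bp motifs.

    Per-motif-size copy minimums default to MISA-style values
    (mono >= 12, di >= 6, tri >= 4, tetra/penta/hexa >= 3); overlapping
    calls are resolved longest-first, then leftmost.
    """
    if min_copies is None:
        min_copies = DEFAULT_MIN_COPIES
    seq = genome.seq if isinstance(genome, CircularGenome) else genome
    codes = encode(seq)
    n = len(seq)
    cands: list[SSRRecord] = []
    for m in range(1, max_motif + 1):
        if n < 2 * m:
            continue
        eq = (codes[: n - m] == codes[m:]) & (codes[: n - m] < 4)
        # run-length encode eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        for r0, r1 in zip(starts, ends):
            span = int(r1 - r0) + m
            copies = span / m
            if span < min_total_len or copies < min_copies.get(m, 3):
                continue
            motif = seq[r0 : r0 + m]
            if not _is_primitive(motif):
                continue
            cands.append(
                SSRRecord(
                    motif=canonical_motif(motif),
                    copies=round(copies, 2),
                    start=int(r0),
                    end=int(r0) + span,
                    motif_observed=motif,
                )
            )
    # longest-first, leftmost greedy overlap resolution
    cands.sort(key=lambda r: (-(r.end - r.start), r.start, len(r.motif)))
    kept: list[SSRRecord] = []
    for c in cands:
        if all(
            _interval_overlap(c.interval, k.interval) == 0 for k in kept
        ):
            kept.append(c)
    kept.sort(key=lambda r: r.start)
    return kept


def summarize_repeats(
    genome: CircularGenome,
    repeats: list[RepeatPair] | None = None,
    ssrs: list[SSRRecord] | None = None,
    **detector_kwargs,
) -> RepeatSummary:
    """Counts by size class and orientation plus the union repeat fraction.

    ``total_repeat_bp`` counts each genomic position at most once (union of
    all dispersed-pair arms and SSR spans).
    """
    if repeats is None:
        repeats = find_dispersed_repeats(genome, **detector_kwargs)
    if ssrs is None:
        ssrs = find_ssrs(genome)
    by_size = {SIZE_SMALL: 0, SIZE_INTERMEDIATE: 0, SIZE_LARGE: 0}
    by_orient = {"DR": 0, "IR": 0, "SSR": len(ssrs)}
    intervals = []
    for p in repeats:
        by_size[p.size_class] += 1
        by_orient[p.orientation] += 1
        intervals.append(p.interval_1)
        intervals.append(p.interval_2)
    intervals.extend(s.interval for s in ssrs)
    return RepeatSummary(
        genome_id=genome.id if isinstance(genome, CircularGenome) else "seq",
        genome_length=len(genome.seq) if isinstance(genome, CircularGenome) else len(genome),
        by_size=by_size,
        by_orientation=by_orient,
        ssr_count=len(ssrs),
        total_repeat_bp=union_length(intervals),
    )


def fraction_aligned_to(
    genome: CircularGenome | str,
    reference: CircularGenome | str,
    min_identity: float = 0.90,
    min_len: int = 100,
    **kwargs,
) -> float:
    """Percent of genome positions covered by alignments to a reference.

    Used e.g. for the chloroplast-derived fraction of a mitochondrial
    genome, or for the cross-line homologous fraction.
    """
    from mitocompare.align import anchored_align

    seq = genome.seq if isinstance(genome, CircularGenome) else genome
    hits = anchored_align(seq, reference, min_identity=min_identity,
                          min_len=min_len, **kwargs)
    if not hits:
        return 0.0
    return 100.0 * union_length([h.q_interval for h in hits]) / len(seq)
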