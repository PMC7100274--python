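"""Pairwise alignment engines.

Two routes with one contract:

* :func:`local_align_dp` — exact Smith-Waterman with affine gaps over the
  full DP matrix. Intended as the small-input oracle; refuses inputs above
  a configurable cell cap.
* :func:`anchored_align` — k-mer seed, greedy chain, banded-DP extension.
  The production engine for genome-scale self- and cross-comparisons.

Identity convention (BLAST-like): matches / alignment columns, where gap
columns count in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitocompare._sw import OP_D, OP_EQ, OP_I, OP_X, sw_banded
from mitocompare.genome_io import CircularGenome, revcomp

_CODE = np.full(256, 4, np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A,C,G,T -> 0..3; anything else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """BLASTN-like affine scoring; a gap of length L costs open + extend*L."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("match must be positive; penalties must be <= 0")


DEFAULT_SCORING = ScoringScheme()


@dataclass
class AlignmentHit:
    """One local alignment between a query interval and a subject interval.

    Intervals are 0-based half-open on the forward strand of each sequence;
    for ``orientation='reverse'`` the subject interval is still reported in
    forward coordinates. ``ops`` (optional) stores per-column operations in
    query order; for reverse hits the subject is consumed from its 3' end.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    orientation: str  # 'forward' | 'reverse'
    matches: int
    columns: int
    score: float
    ops: np.ndarray | None = field(default=None, repr=False)

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)

    @property
    def identity(self) -> float:
        if self.columns == 0:
            raise ZeroDivisionError("identity of a zero-column alignment")
        return self.matches / self.columns

    @property
    def aligned_length(self) -> int:
        return self.columns

    def __post_init__(self) -> None:
        if self.columns < 0 or self.matches < 0 or self.matches > self.columns:
            raise ValueError("inconsistent match/column counts")


def percent_identity(hit: AlignmentHit) -> float:
    """Fraction of identical columns (gaps count as columns)."""
    return hit.identity


def _as_seq(x) -> str:
    return x.seq if isinstance(x, CircularGenome) else x


def _ops_stats(ops: np.ndarray) -> tuple[int, int]:
    matches = int(np.count_nonzero(ops == OP_EQ))
    return matches, int(ops.shape[0])


def local_align_dp(
    a,
    b,
    scoring: ScoringScheme = DEFAULT_SCORING,
    cap: int = 1_000_000,
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment (forward strand only).

    Raises ValueError when len(a)*len(b) exceeds ``cap`` DP cells — use
    :func:`anchored_align` for genome-scale inputs.
    """
    sa, sb = _as_seq(a), _as_seq(b)
    if len(sa) * len(sb) > cap:
        raise ValueError(
            f"DP matrix {len(sa)}x{len(sb)} exceeds oracle cap {cap}; "
            "use anchored_align for large inputs"
        )
    ca, cb = encode(sa), encode(sb)
    score, a0, a1, b0, b1, ops = sw_banded(
        ca,
        cb,
        -len(sa),
        len(sb),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    matches, columns = _ops_stats(ops)
    return AlignmentHit(a0, a1, b0, b1, "forward", matches, columns, float(score), ops)


# ---------------------------------------------------------------------------
# seeding and chaining
# ---------------------------------------------------------------------------

def kmer_positions(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer values and their start positions (N-containing excluded)."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    vals = np.zeros(n - k + 1, np.int64)
    for off in range(k):
        vals = vals * 4 + codes[off : n - k + 1 + off]
    bad = (codes >= 4).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    window_bad = cbad[k:] - cbad[:-k]
    ok = window_bad == 0
    pos = np.nonzero(ok)[0].astype(np.int64)
    return vals[ok], pos


def seed_matches(
    ca: np.ndarray,
    cb: np.ndarray,
    k: int = 12,
    max_occ: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact shared k-mers between coded sequences; returns (i_a, j_b).

    k-mers occurring more than ``max_occ`` times in ``a`` are skipped
    (low-complexity / high-copy guard, as seed-and-extend mappers do).
    """
    va, pa = kmer_positions(ca, k)
    vb, pb = kmer_positions(cb, k)
    if va.size == 0 or vb.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    order = np.argsort(va, kind="stable")
    va_s = va[order]
    pa_s = pa[order]
    lo = np.searchsorted(va_s, vb, side="left")
    hi = np.searchsorted(va_s, vb, side="right")
    counts = hi - lo
    keep = (counts > 0) & (counts <= max_occ)
    idx_b = np.nonzero(keep)[0]
    total = int(counts[keep].sum())
    ia = np.empty(total, np.int64)
    jb = np.empty(total, np.int64)
    out = 0
    lo_k = lo[keep]
    ct_k = counts[keep]
    for t in range(idx_b.size):
        c = ct_k[t]
        ia[out : out + c] = pa_s[lo_k[t] : lo_k[t] + c]
        jb[out : out + c] = pb[idx_b[t]]
        out += c
    return ia, jb


@dataclass
class _Chain:
    i0: int
    j0: int
    i1: int  # last seed start in a
    j1: int
    d_min: int
    d_max: int
    n_seeds: int


def chain_seeds(
    ia: np.ndarray,
    jb: np.ndarray,
    k: int,
    band: int = 32,
    max_gap: int = 500,
) -> list[_Chain]:
    """Greedy co-linear chaining of seed matches.

    Seeds are processed in query order and attached to the nearest active
    chain whose last seed is within ``max_gap`` on both sequences and whose
    diagonal differs by at most ``band``.
    """
    if ia.size == 0:
        return []
    order = np.lexsort((jb, ia))
    ia = ia[order]
    jb = jb[order]
    active: list[_Chain] = []
    done: list[_Chain] = []
    for t in range(ia.size):
        i = int(ia[t])
        j = int(jb[t])
        d = j - i
        # retire chains too far behind
        still = []
        for ch in active:
            if i - ch.i1 > max_gap:
                done.append(ch)
            else:
                still.append(ch)
        active = still
        best = None
        best_key = None
        for ch in active:
            if ch.d_min - band <= d <= ch.d_max + band and j > ch.j1 and i >= ch.i1:
                key = (abs(d - (ch.j1 - ch.i1)), i - ch.i1)
                if best is None or key < best_key:
                    best = ch
                    best_key = key
        if best is None:
            active.append(_Chain(i, j, i, j, d, d, 1))
        else:
            best.i1 = i
            best.j1 = j
            best.d_min = min(best.d_min, d)
            best.d_max = max(best.d_max, d)
            best.n_seeds += 1
    done.extend(active)
    return done


def _extend_chain(
    ca: np.ndarray,
    cb: np.ndarray,
    ch: _Chain,
    k: int,
    scoring: ScoringScheme,
    band: int,
    pad: int,
) -> AlignmentHit | None:
    a0 = max(0, ch.i0 - pad)
    a1 = min(ca.shape[0], ch.i1 + k + pad)
    b0 = max(0, ch.j0 - pad)
    b1 = min(cb.shape[0], ch.j1 + k + pad)
    # window-local diagonal range around the chain's diagonals
    d_lo = (ch.d_min - band) - (b0 - a0)
    d_hi = (ch.d_max + band) - (b0 - a0)
    wa = ca[a0:a1]
    wb = cb[b0:b1]
    d_lo = max(d_lo, -wa.shape[0])
    d_hi = min(d_hi, wb.shape[0])
    if d_lo > d_hi:
        return None
    score, qa0, qa1, qb0, qb1, ops = sw_banded(
        wa, wb, d_lo, d_hi,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    if qa1 <= qa0:
        return None
    matches, columns = _ops_stats(ops)
    return AlignmentHit(
        a0 + qa0, a0 + qa1, b0 + qb0, b0 + qb1,
        "forward", matches, columns, float(score), ops,
    )


def _flip_s(hit: AlignmentHit, blen: int) -> AlignmentHit:
    """Map a hit computed against revcomp(b) back to forward-b coordinates."""
    return AlignmentHit(
        hit.q_start, hit.q_end,
        blen - hit.s_end, blen - hit.s_start,
        "reverse", hit.matches, hit.columns, hit.score, hit.ops,
    )


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def dedup_hits(hits: list[AlignmentHit], contain: float = 0.9) -> list[AlignmentHit]:
    """Suppress hits whose query and subject intervals are both largely
    contained in a higher-scoring hit of the same orientation."""
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.q_start, h.s_start)):
        redundant = False
        for g in kept:
            if g.orientation != h.orientation:
                continue
            qo = _overlap(h.q_start, h.q_end, g.q_start, g.q_end)
            so = _overlap(h.s_start, h.s_end, g.s_start, g.s_end)
            if (
                qo >= contain * (h.q_end - h.q_start)
                and so >= contain * (h.s_end - h.s_start)
            ):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.q_start, h.s_start))


def anchored_align(
    a,
    b,
    k: int = 12,
    min_identity: float = 0.90,
    min_len: int = 20,
    scoring: ScoringScheme = DEFAULT_SCORING,
    band: int = 32,
    max_chain_gap: int = 500,
    max_occ: int = 64,
    pad: int = 200,
    both_strands: bool = True,
) -> list[AlignmentHit]:
    """Seed-and-extend local alignment of b against a (both strands).

    Emits hits with identity >= ``min_identity`` and >= ``min_len``
    alignment columns, sorted by query interval. Reverse-orientation hits
    report the subject interval on the forward strand. Deterministic for
    fixed inputs.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    sa, sb = _as_seq(a), _as_seq(b)
    if not sa or not sb:
        raise ValueError("empty input sequence")
    ca = encode(sa)
    cb = encode(sb)
    hits: list[AlignmentHit] = []
    ia, jb = seed_matches(ca, cb, k, max_occ)
    for ch in chain_seeds(ia, jb, k, band, max_chain_gap):
        h = _extend_chain(ca, cb, ch, k, scoring, band, pad)
        if h is not None:
            hits.append(h)
    if both_strands:
        cbr = encode(revcomp(sb))
        ia, jb = seed_matches(ca, cbr, k, max_occ)
        for ch in chain_seeds(ia, jb, k, band, max_chain_gap):
            h = _extend_chain(ca, cbr, ch, k, scoring, band, pad)
            if h is not None:
                hits.append(_flip_s(h, len(sb)))
    good = [
        h
        for h in hits
        if h.columns >= min_len and h.identity >= min_identity
    ]
    return dedup_hits(good)
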