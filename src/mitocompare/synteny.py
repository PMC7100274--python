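"""Pairwise synteny blocks, rearrangement typing, CMS-specific regions.

Alignment hits between two genomes are chained into maximal co-oriented
blocks; each block is then classed as collinearity, translocation,
inversion, or combined translocation+inversion by asking whether it sits
inside the longest order-consistent run of blocks once the best circular
rotation (and overall strand) of the second genome has been chosen — this
makes classification invariant to where either circle was linearized.

Regions of a CMS genome not covered by any block to its maintainer are its
unique (non-syntenic) regions; those recurring across CMS lines (reciprocal
identity > 0.90) are the shared CMS-specific regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mitocompare.align import AlignmentHit, anchored_align
from mitocompare.genome_io import CircularGenome
from mitocompare.orfs import OrfRecord, find_orfs, global_identity
from mitocompare.repeats import RepeatPair, merge_intervals, union_length

COLLINEARITY = "collinearity"
TRANSLOCATION = "translocation"
INVERSION = "inversion"
TRANS_INV = "trans_inv"


@dataclass
class SyntenyBlock:
    genome_a_id: str
    genome_b_id: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # forward | reverse
    matches: int
    columns: int
    score: float
    segments: list[AlignmentHit] = field(default_factory=list, repr=False)
    rearrangement_class: str | None = None

    @property
    def a_interval(self) -> tuple[int, int]:
        return (self.a_start, self.a_end)

    @property
    def b_interval(self) -> tuple[int, int]:
        return (self.b_start, self.b_end)

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def length(self) -> int:
        return self.a_end - self.a_start


def _chain_hits_into_blocks(
    hits: list[AlignmentHit],
    a_id: str,
    b_id: str,
    block_gap: int,
    overlap_slack: int = 600,
) -> list[SyntenyBlock]:
    blocks: list[dict] = []
    for h in sorted(hits, key=lambda h: (h.q_start, h.s_start)):
        best = None
        best_gap = None
        for blk in blocks:
            if blk["orientation"] != h.orientation:
                continue
            qgap = h.q_start - blk["a_end"]
            if qgap > block_gap or qgap < -overlap_slack:
                continue
            if h.orientation == "forward":
                sgap = h.s_start - blk["b_end"]
            else:
                sgap = blk["b_start"] - h.s_end
            if sgap > block_gap or sgap < -overlap_slack:
                continue
            gap = max(qgap, 0) + max(sgap, 0)
            if best is None or gap < best_gap:
                best = blk
                best_gap = gap
        if best is None:
            blocks.append(
                dict(
                    orientation=h.orientation,
                    a_start=h.q_start, a_end=h.q_end,
                    b_start=h.s_start, b_end=h.s_end,
                    matches=h.matches, columns=h.columns, score=h.score,
                    segments=[h],
                )
            )
        else:
            best["a_end"] = max(best["a_end"], h.q_end)
            best["b_start"] = min(best["b_start"], h.s_start)
            best["b_end"] = max(best["b_end"], h.s_end)
            best["matches"] += h.matches
            best["columns"] += h.columns
            best["score"] += h.score
            best["segments"].append(h)
    return [
        SyntenyBlock(
            genome_a_id=a_id, genome_b_id=b_id,
            a_start=b["a_start"], a_end=b["a_end"],
            b_start=b["b_start"], b_end=b["b_end"],
            orientation=b["orientation"],
            matches=b["matches"], columns=b["columns"], score=b["score"],
            segments=b["segments"],
        )
        for b in blocks
    ]


def _resolve_overlaps(blocks: list[SyntenyBlock], slack: int = 700) -> list[SyntenyBlock]:
    """Keep the highest-scoring of any pair of blocks overlapping by more
    than ``slack`` on either genome, then trim residual small overlaps so
    block spans are mutually disjoint."""
    kept: list[SyntenyBlock] = []
    for b in sorted(blocks, key=lambda b: -b.score):
        clash = False
        for g in kept:
            ao = min(b.a_end, g.a_end) - max(b.a_start, g.a_start)
            bo = min(b.b_end, g.b_end) - max(b.b_start, g.b_start)
            if ao > slack or bo > slack:
                clash = True
                break
        if not clash:
            kept.append(b)
    kept.sort(key=lambda b: (b.a_start, b.b_start))
    for prev, cur in zip(kept, kept[1:]):
        ov = prev.a_end - cur.a_start
        if ov > 0:
            cur.a_start += ov
            if cur.orientation == "forward":
                cur.b_start = min(cur.b_start + ov, cur.b_end)
            else:
                cur.b_end = max(cur.b_end - ov, cur.b_start)
    by_b = sorted(kept, key=lambda b: (b.b_start, b.a_start))
    for prev, cur in zip(by_b, by_b[1:]):
        ov = prev.b_end - cur.b_start
        if ov > 0:
            cur.b_start += ov
            if cur.orientation == "forward":
                cur.a_start = min(cur.a_start + ov, cur.a_end)
            else:
                cur.a_end = max(cur.a_end - ov, cur.a_start)
    return sorted(kept, key=lambda b: (b.a_start, b.b_start))


def build_synteny_blocks(
    gA: CircularGenome,
    gB: CircularGenome,
    min_block: int = 3000,
    min_identity: float = 0.90,
    k: int = 12,
    band: int = 32,
    max_chain_gap: int = 500,
    block_gap: int = 3000,
    seg_min_len: int = 100,
    max_occ: int = 64,
) -> list[SyntenyBlock]:
    """Chain alignment hits into non-overlapping synteny blocks.

    ``min_block`` filters on the block span in genome A (default 3 kb, the
    granularity used for CMS-region analysis; 1 kb reproduces a finer
    block inventory).
    """
    hits = anchored_align(
        gA.seq, gB.seq, k=k, min_identity=min_identity, min_len=seg_min_len,
        band=band, max_chain_gap=max_chain_gap, max_occ=max_occ,
    )
    blocks = _chain_hits_into_blocks(hits, gA.id, gB.id, block_gap)
    blocks = [
        b
        for b in blocks
        if b.length >= min_block and b.identity >= min_identity
    ]
    return _resolve_overlaps(blocks)


def _lis_members(values: list[int], weights: list[int]) -> set[int]:
    """Indices of the maximum-cardinality (weight tie-break) strictly
    increasing subsequence."""
    n = len(values)
    if n == 0:
        return set()
    count = [1] * n
    wsum = list(weights)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if values[j] < values[i]:
                c, w = count[j] + 1, wsum[j] + weights[i]
                if c > count[i] or (c == count[i] and w > wsum[i]):
                    count[i], wsum[i], prev[i] = c, w, j
    best = max(range(n), key=lambda i: (count[i], wsum[i], -i))
    out = set()
    while best != -1:
        out.add(best)
        best = prev[best]
    return out


def classify_blocks(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Assign rearrangement classes (in place; returns the list).

    The rotation of genome B's block order (circular) and the overall
    strand of B are chosen to maximize the number (then total length) of
    collinear blocks; order consistency is the longest increasing run of
    B-ranks along A.
    """
    n = len(blocks)
    if n == 0:
        return blocks
    order = sorted(range(n), key=lambda i: blocks[i].a_start)
    b_rank_of = {
        i: r
        for r, i in enumerate(sorted(range(n), key=lambda i: blocks[i].b_start))
    }
    lengths = [blocks[i].length for i in order]
    best_choice = None
    for flip in (False, True):
        ranks = []
        for i in order:
            r = b_rank_of[i]
            fwd = blocks[i].orientation == "forward"
            if flip:
                r = n - 1 - r
                fwd = not fwd
            ranks.append((r, fwd))
        for rot in range(n):
            vals = [(r - rot) % n for r, _f in ranks]
            members = _lis_members(vals, lengths)
            collinear = [
                t for t in members if ranks[t][1]
            ]
            coll_len = sum(lengths[t] for t in collinear)
            key = (len(collinear), coll_len)
            if best_choice is None or key > best_choice[0]:
                best_choice = (key, flip, rot, members)
    _key, flip, rot, members = best_choice
    for t, i in enumerate(order):
        fwd = blocks[i].orientation == "forward"
        if flip:
            fwd = not fwd
        in_order = t in members
        if in_order and fwd:
            blocks[i].rearrangement_class = COLLINEARITY
        elif in_order and not fwd:
            blocks[i].rearrangement_class = INVERSION
        elif fwd:
            blocks[i].rearrangement_class = TRANSLOCATION
        else:
            blocks[i].rearrangement_class = TRANS_INV
    return blocks


def aligned_fraction(
    blocks: list[SyntenyBlock], which: str, genome_length: int
) -> float:
    """Percent of a genome's positions covered by block alignments."""
    ivals = []
    for b in blocks:
        for seg in b.segments:
            ivals.append(seg.q_interval if which == "a" else seg.s_interval)
        if not b.segments:
            ivals.append(b.a_interval if which == "a" else b.b_interval)
    return 100.0 * union_length(ivals) / genome_length if ivals else 0.0


@dataclass
class UniqueRegion:
    """A CMS-genome interval with no synteny to its maintainer."""

    genome_id: str
    start: int
    end: int
    shared: bool = False
    genes: list = field(default_factory=list)
    orfs: list = field(default_factory=list)
    repeats: list = field(default_factory=list)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def _uncovered(covered: list[tuple[int, int]], length: int, slack: int) -> list[tuple[int, int]]:
    cov = [iv for iv in merge_intervals(covered) if iv[1] - iv[0] > slack]
    out = []
    pos = 0
    for s, e in cov:
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


def find_unique_regions(
    cms_list: list[CircularGenome],
    maintainer_list: list[CircularGenome],
    min_len: int = 3000,
    slack: int = 200,
    shared_min_identity: float = 0.90,
    min_block: int = 3000,
    annotate: bool = True,
    blocks_by_cms: dict[str, list[SyntenyBlock]] | None = None,
    **block_kwargs,
) -> list[UniqueRegion]:
    """Maximal non-syntenic CMS intervals; with several CMS genomes, only
    regions recurring in every CMS line (identity > 0.90) are kept."""
    per_cms: dict[str, list[UniqueRegion]] = {}
    for cms, maint in zip(cms_list, maintainer_list):
        if blocks_by_cms is not None and cms.id in blocks_by_cms:
            blocks = blocks_by_cms[cms.id]
        else:
            blocks = build_synteny_blocks(cms, maint, min_block=min_block, **block_kwargs)
        covered = [b.a_interval for b in blocks]
        regions = [
            UniqueRegion(cms.id, s, e)
            for s, e in _uncovered(covered, cms.length, slack)
            if e - s >= min_len
        ]
        per_cms[cms.id] = regions
    ids = [g.id for g in cms_list]
    if len(cms_list) == 1:
        result = per_cms[ids[0]]
    else:
        seq_of = {g.id: g.seq for g in cms_list}
        result = []
        for r in per_cms[ids[0]]:
            rseq = seq_of[ids[0]][r.start : r.end]
            everywhere = True
            for other in ids[1:]:
                found = False
                for q in per_cms[other]:
                    qseq = seq_of[other][q.start : q.end]
                    if min(len(rseq), len(qseq)) / max(len(rseq), len(qseq)) < 0.5:
                        continue
                    if global_identity(rseq, qseq) > shared_min_identity:
                        q.shared = True
                        found = True
                        break
                if not found:
                    everywhere = False
                    break
            if everywhere:
                r.shared = True
                result.append(r)
        # include the partner regions from the other CMS genomes
        for other in ids[1:]:
            result.extend(q for q in per_cms[other] if q.shared)
    if annotate:
        genome_of = {g.id: g for g in cms_list}
        for r in result:
            annotate_region(r, genome_of[r.genome_id])
    return sorted(result, key=lambda r: (r.genome_id, r.start))


def annotate_region(
    region: UniqueRegion,
    genome: CircularGenome,
    orfs: list[OrfRecord] | None = None,
    repeats: list[RepeatPair] | None = None,
) -> UniqueRegion:
    """Fill a region with overlapping genes, ORFs and repeats (>= 1 bp),
    each reported with region-relative coordinates."""
    s, e = region.start, region.end
    region.genes = [
        (g.full_name, max(g.start, s) - s, min(g.end, e) - s)
        for g in genome.genes
        if g.start < e and g.end > s
    ]
    if orfs is None:
        orfs = find_orfs(genome)
    region.orfs = []
    for o in orfs:
        for i0, i1 in o.interval_on(genome.length):
            if i0 < e and i1 > s:
                region.orfs.append((o.id or f"orf@{o.start}", max(i0, s) - s, min(i1, e) - s))
                break
    if repeats is not None:
        region.repeats = [
            (p.orientation, max(iv[0], s) - s, min(iv[1], e) - s)
            for p in repeats
            for iv in (p.interval_1, p.interval_2)
            if iv[0] < e and iv[1] > s
        ]
    return region
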