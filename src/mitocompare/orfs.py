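"""Six-frame ORF prediction and the CMS-specificity screen.

An ORF is ATG-to-stop (stop included in the nucleotide length, excluded
from the amino-acid length) and must exceed a length floor (default 300 nt,
strict). Prediction is circular-aware: ORFs may run across the origin.

The specificity screen drops every ORF of a CMS genome that has a
near-identical home (best alignment identity >= 0.99) anywhere in the
paired maintainer genome — coding or not; ORFs specific to each CMS line
are then intersected across lines by reciprocal best matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from mitocompare.genome_io import CircularGenome, revcomp

STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfRecord:
    """A predicted reading frame.

    ``start`` is in [0, L); ``end`` = start + nt_length and may exceed the
    genome length for origin-spanning ORFs (wrapping is explicit via
    :attr:`wraps`). Coordinates are forward-strand regardless of strand.
    """

    start: int
    end: int
    strand: str
    frame: int
    nt_length: int
    aa_length: int
    seq: str
    genome_id: str = ""
    id: str | None = None

    def interval_on(self, genome_length: int) -> list[tuple[int, int]]:
        """Forward-strand interval(s), split at the origin if wrapping."""
        if self.end <= genome_length:
            return [(self.start, self.end)]
        return [(self.start, genome_length), (0, self.end - genome_length)]


def _scan_frames(seq: str, min_len: int):
    """Yield (start, stop_end) of maximal ATG..stop frames in a linear seq."""
    n = len(seq)
    for f in range(3):
        atg = -1
        for p in range(f, n - 2, 3):
            codon = seq[p : p + 3]
            if codon in STOPS:
                if atg >= 0:
                    length = p + 3 - atg
                    if length > min_len:
                        yield atg, p + 3
                atg = -1
            elif codon == "ATG" and atg < 0:
                atg = p
    return


def find_orfs(genome: CircularGenome | str, min_len: int = 300) -> list[OrfRecord]:
    """All maximal ORFs > min_len nt on both strands, circular-aware.

    For nested starts sharing one stop only the longest (first ATG after
    the previous stop) is reported. ORFs longer than the genome are
    impossible and discarded.
    """
    if isinstance(genome, CircularGenome):
        seq, circular, gid = genome.seq, genome.circular, genome.id
    else:
        seq, circular, gid = genome, True, ""
    L = len(seq)
    scan_seq = seq + seq if circular else seq
    found: dict[tuple, OrfRecord] = {}

    def add(start_fwd_raw: int, nt: int, strand: str):
        if nt > L:
            return
        start = start_fwd_raw % L
        orf_seq = (seq + seq)[start : start + nt] if circular else seq[start : start + nt]
        stop_norm = (start + nt) % L if circular else start + nt
        key = (strand, stop_norm, start % 3 if strand == "+" else (L - stop_norm) % 3)
        rec = OrfRecord(
            start=start,
            end=start + nt,
            strand=strand,
            frame=start % 3,
            nt_length=nt,
            aa_length=nt // 3 - 1,
            seq=orf_seq if strand == "+" else revcomp(orf_seq),
            genome_id=gid,
        )
        old = found.get(key)
        if old is None or rec.nt_length > old.nt_length:
            found[key] = rec

    for a, b in _scan_frames(scan_seq, min_len):
        if a < L:
            add(a, b - a, "+")
        elif circular:
            add(a - L, b - a, "+")
    rc = revcomp(scan_seq)
    m = len(scan_seq)
    for a, b in _scan_frames(rc, min_len):
        # rc interval [a, b) maps to forward [m-b, m-a)
        fstart = m - b
        if fstart < L:
            add(fstart, b - a, "-")
        elif circular:
            add(fstart - L, b - a, "-")

    orfs = sorted(found.values(), key=lambda o: (o.start, o.end, o.strand))
    # strand-specific sequence was built from forward seq; for '-' the
    # coding sequence is the reverse complement (already applied in add()).
    return orfs


def name_orf(orf: OrfRecord, existing_names: set[str]) -> str:
    """"orf<aa_length>", with b, c, ... suffixes on collisions."""
    base = f"orf{orf.aa_length}"
    if base not in existing_names:
        return base
    for suffix in "bcdefghijklmnopqrstuvwxyz":
        cand = base + suffix
        if cand not in existing_names:
            return cand
    raise ValueError(f"too many ORFs of aa length {orf.aa_length}")


def assign_orf_names(orfs: list[OrfRecord]) -> list[OrfRecord]:
    """Assign ids in genomic order (in place); returns the list."""
    names: set[str] = set()
    for o in sorted(orfs, key=lambda o: (o.start, o.end)):
        o.id = name_orf(o, names)
        names.add(o.id)
    return orfs


def _cigar_columns(cigar: str) -> int:
    return sum(int(x) for x in re.findall(r"(\d+)", cigar))


def best_identity_in(query: str, target: str, max_div: float = 0.05) -> float:
    """Identity of the best infix alignment of query (either strand) in
    target; 0.0 if nothing within ``max_div`` divergence is found."""
    best = 0.0
    k = int(len(query) * max_div) + 2
    for q in (query, revcomp(query)):
        r = edlib.align(q, target, mode="HW", task="path", k=k)
        if r["editDistance"] < 0:
            continue
        cols = _cigar_columns(r["cigar"])
        ident = (cols - r["editDistance"]) / cols
        best = max(best, ident)
    return best


def global_identity(a: str, b: str, both_strands: bool = True) -> float:
    """Identity of the global (NW) alignment of two sequences."""
    best = 0.0
    for q in (a, revcomp(a)) if both_strands else (a,):
        r = edlib.align(q, b, mode="NW", task="path")
        cols = _cigar_columns(r["cigar"])
        best = max(best, (cols - r["editDistance"]) / cols)
    return best


def screen_specific_orfs(
    cms_genome: CircularGenome,
    maintainer_genome: CircularGenome,
    min_len: int = 300,
    sim_threshold: float = 0.99,
    orfs: list[OrfRecord] | None = None,
) -> list[OrfRecord]:
    """CMS ORFs without a near-identical match in the whole maintainer.

    Retained (specific) iff the best maintainer alignment identity is
    strictly below ``sim_threshold``; an ORF matching at exactly 0.99 is
    dropped.
    """
    if orfs is None:
        orfs = find_orfs(cms_genome, min_len)
    target = maintainer_genome.seq
    if maintainer_genome.circular:
        wrap = min(max((o.nt_length for o in orfs), default=0), maintainer_genome.length)
        target = target + target[:wrap]
    specific = []
    for o in orfs:
        if best_identity_in(o.seq, target) < sim_threshold:
            specific.append(o)
    return assign_orf_names(specific)


@dataclass
class SpecificOrfSet:
    """Cross-line intersection of CMS-specific ORFs."""

    per_genome: dict[str, list[OrfRecord]]
    shared: list[dict[str, OrfRecord]] = field(default_factory=list)

    @property
    def shared_count(self) -> int:
        return len(self.shared)


def shared_specific_orfs(
    specific_sets: dict[str, list[OrfRecord]],
    min_identity: float = 0.99,
) -> SpecificOrfSet:
    """ORFs of the first CMS line with a reciprocal best match of identity
    >= min_identity in every other line's specific set."""
    if len(specific_sets) < 2:
        raise ValueError("need specific ORF sets from >= 2 CMS genomes")
    ids = list(specific_sets)
    first = specific_sets[ids[0]]
    shared: list[dict[str, OrfRecord]] = []

    def best_match(o: OrfRecord, pool: list[OrfRecord]):
        scored = [(global_identity(o.seq, p.seq), -p.nt_length, i, p)
                  for i, p in enumerate(pool)]
        if not scored:
            return 0.0, None
        ident, _, _, p = max(scored, key=lambda t: (t[0], t[1], -t[2]))
        return ident, p

    for o in first:
        partners = {ids[0]: o}
        ok = True
        for gid in ids[1:]:
            ident, p = best_match(o, specific_sets[gid])
            if p is None or ident < min_identity:
                ok = False
                break
            back_ident, back = best_match(p, first)
            if back is not o or back_ident < min_identity:
                ok = False
                break
            partners[gid] = p
        if ok:
            shared.append(partners)
    return SpecificOrfSet(per_genome=dict(specific_sets), shared=shared)
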