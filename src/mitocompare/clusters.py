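"""Gene clusters: runs of closely spaced genes and their conservation.

Neighboring mitochondrial genes (gap <= max_gap) are grouped into clusters
— putative co-transcriptional units. Cluster signatures are compared across
genomes on base gene names (trans-spliced part suffixes dropped) and up to
orientation (a signature equals its reversal); a cluster conserved in every
genome may appear as a contiguous sub-run of a larger cluster. Conserved
clusters are then located within synteny blocks to ask whether
rearrangement moved or flipped them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mitocompare.genome_io import CircularGenome, GeneFeature
from mitocompare.synteny import SyntenyBlock

CLUSTER_KINDS = ("protein", "tRNA", "rRNA")


@dataclass
class GeneCluster:
    genome_id: str
    members: list[GeneFeature]
    start: int
    end: int  # may exceed genome length for origin-spanning clusters

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def signature(self) -> tuple[str, ...]:
        return collapse_names([m.name for m in self.members])

    @property
    def strand_pattern(self) -> str:
        return "".join(m.strand for m in self.members)

    def __len__(self) -> int:
        return len(self.members)


def collapse_names(names: list[str]) -> tuple[str, ...]:
    """Adjacent duplicate base names (exon parts / tandem copies) collapse
    to a single signature element."""
    out: list[str] = []
    for n in names:
        if not out or out[-1] != n:
            out.append(n)
    return tuple(out)


def canonical_signature(sig: tuple[str, ...]) -> tuple[str, ...]:
    """Orientation-normalized signature: a run equals its reversal."""
    return min(sig, tuple(reversed(sig)))


def detect_clusters(
    genome: CircularGenome,
    max_gap: int = 2000,
    kinds: tuple[str, ...] = CLUSTER_KINDS,
) -> list[GeneCluster]:
    """Maximal runs of genes with inter-gene gaps <= max_gap.

    Circular-aware: a run may span the origin. Runs whose signature has a
    single element (singletons, or one gene's exon parts) are excluded.
    """
    genes = sorted(
        (g for g in genome.genes if g.kind in kinds), key=lambda g: (g.start, g.end)
    )
    n = len(genes)
    if n < 2:
        return []
    L = genome.length
    gaps = []  # gap after gene i (to gene i+1, circular)
    for i in range(n):
        nxt = genes[(i + 1) % n]
        gap = nxt.start - genes[i].end
        if i == n - 1:
            gap = nxt.start + L - genes[i].end if genome.circular else max_gap + 1
        gaps.append(gap)
    # cut at every gap > max_gap
    cuts = [i for i in range(n) if gaps[i] > max_gap]
    clusters = []
    if not cuts:
        runs = [list(range(n))]
    else:
        runs = []
        for c_idx in range(len(cuts)):
            start = (cuts[c_idx] + 1) % n
            stop = cuts[(c_idx + 1) % len(cuts)]
            idx = []
            i = start
            while True:
                idx.append(i)
                if i == stop:
                    break
                i = (i + 1) % n
            runs.append(idx)
    for idx in runs:
        members = [genes[i] for i in idx]
        if len(collapse_names([m.name for m in members])) < 2:
            continue
        start = members[0].start
        end = members[-1].end
        if end < start:  # wraps the origin
            end += L
        clusters.append(GeneCluster(genome.id, members, start, end))
    return sorted(clusters, key=lambda c: c.start)


@dataclass
class ConservedCluster:
    """A gene-run signature present (as run or sub-run) in every genome."""

    signature: tuple[str, ...]
    instances: dict[str, tuple[int, int]] = field(default_factory=dict)
    instance_members: dict[str, list[GeneFeature]] = field(default_factory=dict)
    block_context: dict[str, str] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return "-".join(self.signature)


def _subruns_with_spans(cluster: GeneCluster):
    """All contiguous sub-runs (length >= 2) of a cluster's signature, with
    the genomic span of the underlying member features."""
    names = [m.name for m in cluster.members]
    # collapsed element -> feature index range
    elems: list[tuple[str, int, int]] = []
    for t, nm in enumerate(names):
        if elems and elems[-1][0] == nm:
            elems[-1] = (nm, elems[-1][1], t)
        else:
            elems.append((nm, t, t))
    m = len(elems)
    for i in range(m):
        for j in range(i + 2, m + 1):
            sig = tuple(e[0] for e in elems[i:j])
            f0 = elems[i][1]
            f1 = elems[j - 1][2]
            span = (cluster.members[f0].start, cluster.members[f1].end)
            feats = cluster.members[f0 : f1 + 1]
            yield sig, span, feats


def conserved_clusters(
    genomes: list[CircularGenome],
    clusters_per_genome: dict[str, list[GeneCluster]] | None = None,
    max_gap: int = 2000,
) -> list[ConservedCluster]:
    """Maximal gene-run signatures shared by every genome.

    Signatures are orientation-normalized; a shared signature contained in
    a longer shared signature is not reported separately.
    """
    if len(genomes) < 2:
        raise ValueError("need >= 2 genomes")
    if clusters_per_genome is None:
        clusters_per_genome = {g.id: detect_clusters(g, max_gap) for g in genomes}
    per_genome_runs: dict[str, dict[tuple, tuple]] = {}
    for g in genomes:
        runs: dict[tuple, tuple] = {}
        for cl in clusters_per_genome[g.id]:
            for sig, span, feats in _subruns_with_spans(cl):
                runs.setdefault(canonical_signature(sig), (span, feats))
        per_genome_runs[g.id] = runs
    common = set.intersection(*(set(r) for r in per_genome_runs.values()))

    def contained(small: tuple, big: tuple) -> bool:
        if len(small) >= len(big):
            return False
        s = list(small)
        b = list(big)
        for seq in (b, b[::-1]):
            for off in range(len(seq) - len(s) + 1):
                if seq[off : off + len(s)] == s:
                    return True
        return False

    maximal = [
        sig for sig in common
        if not any(contained(sig, other) for other in common if other != sig)
    ]
    out = []
    for sig in sorted(maximal):
        cc = ConservedCluster(signature=sig)
        for gid, runs in per_genome_runs.items():
            span, feats = runs[sig]
            cc.instances[gid] = span
            cc.instance_members[gid] = feats
        out.append(cc)
    return out


def map_clusters_to_blocks(
    conserved: list[ConservedCluster],
    blocks_by_genome: dict[str, list[SyntenyBlock]],
) -> list[ConservedCluster]:
    """Fill block_context: the rearrangement class of the block holding
    each cluster instance (majority-overlap rule; 'none' if uncovered).

    ``blocks_by_genome`` maps a genome id to classified blocks whose *a*
    side is that genome.
    """
    for cc in conserved:
        for gid, (s, e) in cc.instances.items():
            if gid not in blocks_by_genome:
                continue
            best_ov = 0
            best_class = "none"
            for b in blocks_by_genome[gid]:
                ov = min(e, b.a_end) - max(s, b.a_start)
                if ov > best_ov:
                    best_ov = ov
                    best_class = b.rearrangement_class or "none"
            cc.block_context[gid] = best_class
    return conserved


def gene_overlaps(genome: CircularGenome) -> list[tuple[str, str, int]]:
    """All gene pairs overlapping by >= 1 bp, with the overlap length."""
    genes = sorted(genome.genes, key=lambda g: g.start)
    out = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if b.start >= a.end:
                break
            ov = min(a.end, b.end) - b.start
            if ov >= 1:
                out.append((a.full_name, b.full_name, ov))
    return out
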