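"""Synthetic maintainer/CMS mitochondrial genome pairs with planted truth.

The generator emulates the structure observed in tobacco
maintainer-vs-CMS comparisons: a ~430 kb circular maintainer genome at
GC 0.40 carrying a conserved gene inventory arranged in co-transcribed
clusters, dispersed repeat families (direct and inverted, in three size
classes), SSRs, and chloroplast-derived tracts; and a CMS derivative built
from it by planted inversions, translocations, combined events,
non-homologous insertions (including one large region carrying a cluster
of CMS-specific ORFs, and a large palindrome), candidate-gene edits with
exact codon-level event patterns, gene-copy losses/gains and SSR gains —
with every planted element recorded in a machine-checkable truth table.

Two-cultivar quartets share one "alien cytoplasm" haplotype: both CMS
genomes carry identical candidate-gene sequences and identical inserted
CMS-specific regions, while each maintainer differs from that haplotype in
its own way; cultivar backgrounds additionally diverge by intergenic SNPs.

The model is deliberately simple where simplicity does not affect the
detectors: background sequence is i.i.d. at the target GC, and planted
repeat copies differ by substitutions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from mitocompare.genome_io import CircularGenome, GeneFeature, revcomp
from mitocompare.orfs import find_orfs
from mitocompare.repeats import find_ssrs

# ---------------------------------------------------------------------------
# gene inventory and cluster layout
# ---------------------------------------------------------------------------

#: CDS length (nt, incl. stop) per conserved protein-coding gene; the four
#: candidate genes carry lengths compatible with their planted event tables.
GENE_LENGTHS = {
    "atp1": 1530, "atp6": 1167, "atp9": 225,
    "ccmB": 621, "ccmC": 753, "ccmFC": 1332, "ccmFN": 1734,
    "cob": 1182, "cox1": 1584, "cox3": 798,
    "mat-R": 1989, "nad1": 975, "nad3": 357, "nad4": 1488, "nad4L": 303,
    "nad5": 2010, "nad6": 618, "nad7": 1185, "nad9": 573,
    "rpl5": 555, "rpl16": 537, "rps3": 1683, "rps4": 1068, "rps10": 378,
    "rps12": 378, "rps13": 351, "rps14": 303, "rps19": 288,
    "sdh3": 312,       # CMS-haplotype length; maintainers carry 327 / 315
    "nad2": 1377,      # CMS-haplotype length; maintainer A carries 1467
    "cox2": 816,       # CMS-haplotype length; maintainer B carries 783
}
#: trans-spliced genes: part suffix -> part length (CMS-haplotype frame)
GENE_PARTS = {
    "nad1": {"a": 195, "b": 195, "c": 195, "d": 195, "e": 195},
    "nad2": {"a": 390, "b": 480, "c": 210, "d": 150, "e": 147},
    "nad5": {"a": 1005, "b": 1005},
    "rps3": {"a": 900, "b": 783},
    "cox2": {"a": 420, "b": 396},
    "rps10": {"a": 189, "b": 189},
}
RNA_LENGTHS = {"rrn26": 3400, "rrn18": 1900, "rrn5": 120}
TRNA_LENGTH = 75

#: the 13 cluster layouts planted in every genome; each entry is a list of
#: (gene base name, part suffix or None, kind); cluster-internal gaps are
#: drawn from 100-500 bp. Clusters holding candidate genes are forced onto
#: the forward strand so CDS edit positions map directly to the genome.
CLUSTER_PLAN = [
    [("mat-R", None, "protein"), ("nad1", "a", "protein")],
    [("cob", None, "protein"), ("rps14", None, "protein"),
     ("rpl5", None, "protein"), ("nad1", "b", "protein")],
    [("trnM", None, "tRNA"), ("rrn26", None, "rRNA")],
    [("nad3", None, "protein"), ("rps12", None, "protein")],
    [("rrn18", None, "rRNA"), ("rrn5", None, "rRNA")],
    [("cox1", None, "protein"), ("rps10", "a", "protein"), ("rps10", "b", "protein")],
    [("rps19", None, "protein"), ("rps3", "a", "protein"), ("rps3", "b", "protein"),
     ("rpl16", None, "protein"), ("cox2", "a", "protein"), ("cox2", "b", "protein")],
    [("trnS", None, "tRNA"), ("trnD", None, "tRNA")],
    [("trnC", None, "tRNA"), ("trnN", None, "tRNA"), ("trnY", None, "tRNA"),
     ("nad2", "a", "protein"), ("nad2", "b", "protein")],
    [("nad2", "c", "protein"), ("nad2", "d", "protein"), ("nad2", "e", "protein"),
     ("sdh3", None, "protein")],
    [("nad6", None, "protein"), ("rps4", None, "protein")],
    [("trnP", None, "tRNA"), ("trnF", None, "tRNA"), ("trnS", None, "tRNA"),
     ("trnE", None, "tRNA")],
    [("nad9", None, "protein"), ("trnP", None, "tRNA"), ("trnW", None, "tRNA")],
]
#: clusters that must stay forward-strand (they carry genes with planted
#: CDS edit presets, whose positions must map directly onto the genome)
_FORWARD_CLUSTERS = {0, 1, 5, 6, 8, 9, 10}

SINGLE_GENES = [
    ("atp1", None, "protein"), ("atp6", None, "protein"), ("atp9", None, "protein"),
    ("ccmB", None, "protein"), ("ccmC", None, "protein"), ("ccmFC", None, "protein"),
    ("ccmFN", None, "protein"), ("cox3", None, "protein"),
    ("nad1", "c", "protein"), ("nad1", "d", "protein"), ("nad1", "e", "protein"),
    ("nad4", None, "protein"), ("nad4L", None, "protein"),
    ("nad5", "a", "protein"), ("nad5", "b", "protein"),
    ("nad7", None, "protein"), ("rps13", None, "protein"),
]

#: expected rpl16/rps3 overlap (bp) inside the rps19-rps3-rpl16-cox2 cluster
RPL16_RPS3_OVERLAP = 108

#: genes whose CDS differs between each maintainer and the common CMS
#: haplotype (per cultivar); the four shared ones are the candidates.
POLYMORPHIC_A = [
    "atp1", "atp6", "atp9", "ccmB", "ccmFN", "cox1", "cox2", "cox3",
    "mat-R", "nad1", "nad2", "nad4", "nad6", "rpl5", "rps10", "rps13",
    "rps4", "sdh3",
]
POLYMORPHIC_B = ["atp6", "ccmC", "cox2", "nad2", "rps3", "sdh3"]
CANDIDATE_GENES = ["atp6", "cox2", "nad2", "sdh3"]

#: CMS-haplotype codons that the preset event tables rely on
#: (1-based codon-start position in the CDS -> codon)
_FIXED_CMS_CODONS = {
    "atp6": {58: "TCT", 91: "ACG", 253: "CTG", 418: "CCA", 766: "TCC", 1156: "TAT"},
    "nad2": {790: "GGA"},
    "cox2": {769: "AGC", 772: "ACG"},
}

#: per-genome copy plan: gene -> copy count in (maintA, cmsA, maintB, cmsB)
COPY_PLAN = {
    "nad3": (2, 1, 2, 1),
    "sdh3": (3, 1, 1, 1),
    "cob": (1, 1, 2, 1),
    "rpl5": (1, 1, 2, 1),
    "rps14": (1, 1, 2, 1),
    "atp9": (1, 1, 1, 3),
    "mat-R": (1, 1, 1, 2),
}

#: amino-acid lengths of the planted shared CMS-specific ORFs (two of 115
#: so that naming produces an "orf115b")
SPECIFIC_ORF_AA = [100, 115, 115, 103, 121, 134, 142, 156,
                   168, 177, 189, 204, 118, 126, 110, 148]


@dataclass
class SimConfig:
    """Study conditions for the synthetic genomes (defaults = the
    conditions the pipeline is validated under)."""

    seed: int
    maintainer_length: int = 430_000
    gc: float = 0.40
    include_genes: bool = True  # a gene-free scaffold is useful for tests
    # dispersed repeat families planted in the maintainer: (n_families,
    # min_arm, max_arm, per-copy mutation rate)
    small_repeats: tuple = (80, 20, 40, 0.0)
    intermediate_repeats: tuple = (20, 60, 400, 0.01)
    large_repeats: tuple = (3, 600, 2500, 0.01)
    repeat_ir_fraction: float = 0.5
    ssr_counts: dict = field(default_factory=lambda: {1: 3, 2: 4, 3: 4, 4: 8, 5: 6, 6: 9})
    cp_fraction: float = 0.026
    cp_ref_length: int = 20_000
    divergence_rate: float = 0.002       # cultivar B background vs base
    divergence_rate_a: float = 0.001     # cultivar A background vs base
    reference_divergence: float = 0.004  # outgroup reference vs base
    n_inversions: int = 3
    n_translocations: int = 6
    n_trans_inv: int = 3
    inversion_len: tuple = (8_000, 20_000)
    translocation_len: tuple = (5_000, 15_000)
    region_lengths: tuple = (41_000, 3_400, 3_300)
    n_specific_orfs: int = 16
    palindrome_arms: dict = field(default_factory=lambda: {"A": 5778, "B": 1491})
    cms_ssr_gains: dict = field(default_factory=lambda: {"A": 8, "B": 5})
    maintainer_b_ssr_gains: int = 3
    amplified_families: dict = field(default_factory=lambda: {"A": 1, "B": 2})


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")


def _bg_probs(gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    return np.array([at, gc / 2, gc / 2, at])


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.40) -> str:
    return "".join(rng.choice(_BASES, size=n, p=_bg_probs(gc)))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    n_mut = rng.binomial(len(seq), rate)
    pos = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def random_cds(
    rng: np.random.Generator,
    nt_length: int,
    gc: float = 0.40,
    fixed_codons: dict[int, str] | None = None,
) -> str:
    """A valid CDS (ATG .. stop, no internal stop, SSR-free), with optional
    codon constraints at given 1-based codon-start positions."""
    assert nt_length % 3 == 0 and nt_length >= 9
    n_codons = nt_length // 3
    for _attempt in range(50):
        codons = ["ATG"]
        while len(codons) < n_codons - 1:
            c = random_seq(rng, 3, gc)
            if c not in STOPS:
                codons.append(c)
        codons.append(STOPS[rng.integers(3)])
        seq = list("".join(codons))
        if fixed_codons:
            for pos1, codon in fixed_codons.items():
                seq[pos1 - 1 : pos1 + 2] = codon
        seq = "".join(seq)
        body = seq[3:-3]
        if any(body[i : i + 3] in STOPS for i in range(0, len(body), 3)):
            continue
        if find_ssrs(seq):
            continue
        return seq
    raise RuntimeError("could not generate a clean CDS")


def _clean_ssrs(seq: str, rng: np.random.Generator, protected=()) -> str:
    """Disrupt accidental SSR runs (outside protected intervals)."""
    s = list(seq)
    for _round in range(8):
        hits = [
            r for r in find_ssrs("".join(s))
            if not any(r.start < e and r.end > b for b, e in protected)
        ]
        if not hits:
            return "".join(s)
        for r in hits:
            mid = (r.start + r.end) // 2
            m = len(r.motif)
            avoid = {s[mid]}
            if mid - m >= 0:
                avoid.add(s[mid - m])
            if mid + m < len(s):
                avoid.add(s[mid + m])
            choices = [b for b in "ACGT" if b not in avoid] or ["A"]
            s[mid] = choices[rng.integers(len(choices))]
    return "".join(s)


def _clean_orfs(seq: str, rng: np.random.Generator, protected=(), min_len: int = 300) -> str:
    """Plant stop codons so a linear payload has no accidental ORF > min_len
    outside the protected intervals."""
    s = list(seq)
    for _round in range(60):
        g = CircularGenome(id="tmp", seq="".join(s), circular=False)
        bad = None
        for o in find_orfs(g, min_len):
            if any(o.start < e and o.end > b for b, e in protected):
                continue
            bad = o
            break
        if bad is None:
            return "".join(s)
        # place a stop codon mid-ORF, outside protected spans
        placed = False
        for frac in (0.5, 0.35, 0.65, 0.2, 0.8):
            cpos = bad.start + 3 * int(bad.nt_length * frac // 3)
            if bad.strand == "+":
                a, b = cpos, cpos + 3
                stop = STOPS[rng.integers(3)]
            else:
                a, b = cpos, cpos + 3
                stop = revcomp(STOPS[rng.integers(3)])
            if not any(a < e2 and b > b2 for b2, e2 in protected) and b <= len(s):
                s[a:b] = stop
                placed = True
                break
        if not placed:
            return "".join(s)
    return "".join(s)


# ---------------------------------------------------------------------------
# marks, state, placement
# ---------------------------------------------------------------------------

@dataclass
class Mark:
    """A tracked planted element (non-gene)."""

    kind: str  # repeat | ssr | cp | orf | region | palindrome | cluster
    name: str
    start: int
    end: int
    strand: str = "+"
    meta: dict = field(default_factory=dict)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GenomeState:
    id: str
    seq: str
    features: list[GeneFeature]
    marks: list[Mark]

    def to_genome(self) -> CircularGenome:
        return CircularGenome(
            id=self.id, seq=self.seq, circular=True,
            genes=sorted(self.features, key=lambda g: g.start),
        )


class _Placer:
    """Non-overlapping placement of items on a circle, margin-aware."""

    def __init__(self, length: int, rng: np.random.Generator):
        self.length = length
        self.rng = rng
        self.occupied: list[tuple[int, int]] = []

    def reserve(self, start: int, end: int, margin: int) -> None:
        self.occupied.append((start - margin, end + margin))

    def free_spot(self, size: int, margin: int, tries: int = 4000) -> int:
        for _ in range(tries):
            pos = int(self.rng.integers(0, self.length - size))
            a, b = pos - margin, pos + size + margin
            if all(b <= s or a >= e for s, e in self.occupied):
                self.reserve(pos, pos + size, margin)
                return pos
        raise RuntimeError("placement failed: genome too crowded")


# ---------------------------------------------------------------------------
# edit presets (maintainer <-> CMS haplotype), in the M -> CMS direction
# ---------------------------------------------------------------------------

@dataclass
class GeneEdit:
    """How a maintainer version of a gene differs from the CMS haplotype.

    ``to_maintainer`` turns the CMS-haplotype CDS into the maintainer CDS;
    ``expected_events`` is what compare_gene(maintainer, cms) must report:
    tuples (kind, position, payload) where payload is
    (codon_before, codon_after, synonymy) for substitutions and the length
    for indels.
    """

    gene: str
    to_maintainer: callable
    expected_events: list


def _sub_codon(seq: str, pos1: int, codon: str) -> str:
    return seq[: pos1 - 1] + codon + seq[pos1 + 2 :]


def _preset_atp6_a() -> GeneEdit:
    maint = {58: "TAT", 91: "ATG", 253: "TTG", 418: "TCA", 766: "TCT", 1156: "TCT"}

    def f(cms):
        for p, c in maint.items():
            cms = _sub_codon(cms, p, c)
        return cms

    ev = [
        ("substitution", 58, ("tAt", "tCt", "nonsynonymous")),
        ("substitution", 91, ("aTg", "aCg", "nonsynonymous")),
        ("substitution", 253, ("Ttg", "Ctg", "synonymous")),
        ("substitution", 418, ("Tca", "Cca", "nonsynonymous")),
        ("substitution", 766, ("tcT", "tcC", "synonymous")),
        ("substitution", 1156, ("tCt", "tAt", "nonsynonymous")),
    ]
    return GeneEdit("atp6", f, ev)


def _preset_atp6_b() -> GeneEdit:
    return GeneEdit(
        "atp6",
        lambda cms: _sub_codon(cms, 766, "TCT"),
        [("substitution", 766, ("tcT", "tcC", "synonymous"))],
    )


def _preset_nad2_a(rng) -> GeneEdit:
    ins = random_cds(rng, 96)[3:-3]  # 90 nt of stop-free codons

    def f(cms):
        filler = ins
        # maintainer = cms + 90 nt inserted so that positions 456-545 are
        # the novel block; guard against indel left-shifts
        if filler[-1] == cms[454]:
            filler = filler[:-1] + ("A" if cms[454] != "A" else "C")
        m = cms[:455] + filler + cms[455:]
        # the ggG -> ggA substitution: maintainer codon 880 is GGG
        m = m[:881] + "G" + m[882:]
        return m

    return GeneEdit(
        "nad2", f,
        [("deletion", 456, 90), ("substitution", 880, ("ggG", "ggA", "synonymous"))],
    )


def _preset_nad2_b() -> GeneEdit:
    def f(cms):
        ins = "AGT"
        if ins[-1] == cms[454]:
            ins = "AGC"
        return cms[:455] + ins + cms[455:]

    return GeneEdit("nad2", f, [("deletion", 456, 3)])


def _preset_sdh3_a() -> GeneEdit:
    ins = "GGATTTTTCGGTCAG"  # 15 nt

    def f(cms):
        filler = ins
        if filler[-1] == cms[275]:
            filler = filler[:-1] + ("A" if cms[275] != "A" else "C")
        return cms[:276] + filler + cms[276:]

    return GeneEdit("sdh3", f, [("deletion", 277, 15)])


def _preset_sdh3_b() -> GeneEdit:
    def f(cms):
        ins = "ACG"
        if ins[-1] == cms[272]:
            ins = "ACT"
        return cms[:273] + ins + cms[273:]

    return GeneEdit("sdh3", f, [("deletion", 274, 3)])


def _preset_cox2_a() -> GeneEdit:
    def f(cms):
        cms = _sub_codon(cms, 769, "ACC")
        cms = _sub_codon(cms, 772, "GGG")
        return cms

    return GeneEdit(
        "cox2", f,
        [
            ("substitution", 769, ("aCc", "aGc", "nonsynonymous")),
            ("substitution", 772, ("GGg", "ACg", "nonsynonymous")),
        ],
    )


def _preset_cox2_b() -> GeneEdit:
    def f(cms):
        # maintainer B lacks the 33 nt the CMS haplotype carries at 383-415
        return cms[:382] + cms[415:]

    return GeneEdit("cox2", f, [("insertion", 382, 33)])


def _preset_single_sub(gene: str, cds: str, rng) -> GeneEdit:
    """A random 1-substitution difference (maintainer vs CMS haplotype)."""
    n_codons = len(cds) // 3
    for _ in range(100):
        ci = int(rng.integers(2, n_codons - 1))
        off = int(rng.integers(3))
        pos = ci * 3 + off
        old = cds[pos]
        new = "ACGT"[rng.integers(4)]
        if new == old:
            continue
        codon_cms = cds[ci * 3 : ci * 3 + 3]
        codon_m = codon_cms[:off] + new + codon_cms[off + 1 :]
        if codon_m in STOPS:
            continue
        from mitocompare.genes import classify_substitution

        syn = classify_substitution(codon_m, codon_cms)

        def f(cms, pos=pos, new=new):
            return cms[:pos] + new + cms[pos + 1 :]

        def fmt(codon, o):
            return "".join(c.upper() if i == o else c.lower() for i, c in enumerate(codon))

        return GeneEdit(
            gene, f,
            [("substitution", ci * 3 + 1, (fmt(codon_m, off), fmt(codon_cms, off), syn))],
        )
    raise RuntimeError("failed to draw a substitution")


# ---------------------------------------------------------------------------
# assembly machinery
# ---------------------------------------------------------------------------

@dataclass
class InsertPayload:
    name: str
    kind: str  # region | palindrome | repeat_copy | ssr | gene_copy
    seq: str
    features: list[GeneFeature] = field(default_factory=list)
    marks: list[Mark] = field(default_factory=list)


@dataclass
class StructuralPlan:
    inversions: list = field(default_factory=list)        # (start, end)
    translocations: list = field(default_factory=list)    # (start, end, dest, flip)
    insertions: list = field(default_factory=list)        # (anchor, InsertPayload)
    splices: list = field(default_factory=list)           # (pos, del_len, ins_seq)
    feature_removals: list = field(default_factory=list)  # GeneFeature identity keys
    substitutions: list = field(default_factory=list)     # (pos, base)


def _feature_key(f: GeneFeature) -> tuple:
    return (f.name, f.part_suffix, f.start, f.end)


def _shift_items(items, pos: int, delta: int, del_len: int, kind: str):
    """Remap features/marks across an in-segment splice at local ``pos``."""
    out = []
    for it in items:
        s, e = it.start, it.end
        if e <= pos:
            out.append(it)
        elif s >= pos + del_len:
            if kind == "feature":
                out.append(replace(it, start=s + delta, end=e + delta))
            else:
                it.start, it.end = s + delta, e + delta
                out.append(it)
        elif s <= pos and e >= pos + del_len:
            # edit inside the item: its span stretches/shrinks
            if kind == "feature":
                out.append(replace(it, end=e + delta))
            else:
                it.end = e + delta
                out.append(it)
        else:
            raise ValueError("splice partially overlaps a tracked item")
    return out


def _flip_items(items, seg_len: int, kind: str):
    out = []
    for it in items:
        ns, ne = seg_len - it.end, seg_len - it.start
        strand = "-" if it.strand == "+" else "+"
        if kind == "feature":
            out.append(replace(it, start=ns, end=ne, strand=strand))
        else:
            it.start, it.end, it.strand = ns, ne, strand
            out.append(it)
    return out


def assemble(
    parent: GenomeState,
    new_id: str,
    plan: StructuralPlan,
) -> tuple[GenomeState, list[tuple[int, int, str]]]:
    """Apply a structural plan; returns the new state and the truth blocks
    [(parent_start, parent_end, rearrangement_class)] in parent frame."""
    L = len(parent.seq)
    arr = np.frombuffer(parent.seq.encode(), dtype="S1").astype("U1")
    for pos, base in plan.substitutions:
        arr[pos] = base
    seq = "".join(arr)

    removal_keys = set(plan.feature_removals)
    feats = [f for f in parent.features if _feature_key(f) not in removal_keys]
    marks = [replace(m, meta=dict(m.meta)) for m in parent.marks]

    moved = {}
    for t, (s, e, d, flip) in enumerate(plan.translocations):
        moved[(s, e)] = (d, flip)
    inverted = {tuple(iv) for iv in plan.inversions}

    bps = {0, L}
    for s, e in inverted:
        bps |= {s, e}
    for s, e in moved:
        bps |= {s, e}
    for s, e, d, flip in plan.translocations:
        bps.add(d)
    for anchor, _p in plan.insertions:
        bps.add(anchor)
    bps = sorted(bps)
    segments = [(bps[i], bps[i + 1]) for i in range(len(bps) - 1)]

    # output order: backbone minus moved segments; moved segments placed at
    # their destination breakpoints; insertions at their anchors
    items: list[tuple] = []  # ('seg', s, e, flip, klass) | ('ins', payload)
    ins_at = {}
    for anchor, payload in plan.insertions:
        ins_at.setdefault(anchor, []).append(payload)
    moved_at = {}
    for (s, e), (d, flip) in moved.items():
        moved_at.setdefault(d, []).append((s, e, flip))
    for s, e in segments:
        for payload in ins_at.get(s, []):
            items.append(("ins", payload))
        for ms, me, flip in moved_at.get(s, []):
            items.append(("seg", ms, me, flip, "trans_inv" if flip else "translocation"))
        if (s, e) in moved:
            continue
        if (s, e) in inverted:
            items.append(("seg", s, e, True, "inversion"))
        else:
            items.append(("seg", s, e, False, "collinearity"))
    for payload in ins_at.get(L, []):
        items.append(("ins", payload))
    for ms, me, flip in moved_at.get(L, []):
        items.append(("seg", ms, me, flip, "trans_inv" if flip else "translocation"))

    splices_in = {}
    for pos, dlen, ins in plan.splices:
        for s, e in segments:
            if s <= pos < e:
                if pos + dlen > e:
                    raise ValueError("splice crosses a segment boundary")
                splices_in.setdefault((s, e), []).append((pos - s, dlen, ins))
                break

    out_seq: list[str] = []
    out_feats: list[GeneFeature] = []
    out_marks: list[Mark] = []
    truth_blocks: list[tuple[int, int, str]] = []
    offset = 0
    for item in items:
        if item[0] == "ins":
            payload: InsertPayload = item[1]
            out_seq.append(payload.seq)
            for f in payload.features:
                out_feats.append(replace(f, start=f.start + offset, end=f.end + offset))
            for m in payload.marks:
                out_marks.append(
                    replace(m, start=m.start + offset, end=m.end + offset,
                            meta=dict(m.meta))
                )
            if payload.kind in ("region", "palindrome"):
                out_marks.append(
                    Mark(payload.kind, payload.name, offset, offset + len(payload.seq))
                )
            offset += len(payload.seq)
            continue
        _tag, s, e, flip, klass = item
        loc_seq = seq[s:e]
        loc_feats = [
            replace(f, start=f.start - s, end=f.end - s)
            for f in feats
            if s <= f.start and f.end <= e
        ]
        loc_marks = [
            replace(m, start=m.start - s, end=m.end - s, meta=dict(m.meta))
            for m in marks
            if s <= m.start and m.end <= e
        ]
        for pos, dlen, ins in sorted(splices_in.get((s, e), []), reverse=True):
            delta = len(ins) - dlen
            loc_seq = loc_seq[:pos] + ins + loc_seq[pos + dlen :]
            loc_feats = _shift_items(loc_feats, pos, delta, dlen, "feature")
            loc_marks = _shift_items(loc_marks, pos, delta, dlen, "mark")
        if flip:
            loc_seq = revcomp(loc_seq)
            n = len(loc_seq)
            loc_feats = _flip_items(loc_feats, n, "feature")
            loc_marks = _flip_items(loc_marks, n, "mark")
        out_seq.append(loc_seq)
        out_feats.extend(replace(f, start=f.start + offset, end=f.end + offset)
                         for f in loc_feats)
        for m in loc_marks:
            m.start += offset
            m.end += offset
            out_marks.append(m)
        truth_blocks.append((s, e, klass))
        offset += len(loc_seq)

    # sanity: every feature inside the parent must have been carried over
    # unless it sat in a removed span (feature_removals handle gene copies)
    state = GenomeState(new_id, "".join(out_seq), out_feats, out_marks)
    return state, truth_blocks


# ---------------------------------------------------------------------------
# base maintainer construction
# ---------------------------------------------------------------------------

@dataclass
class Registry:
    """Generator-internal shared state for a quartet."""

    gene_cds: dict = field(default_factory=dict)       # (gene, part|None) -> CMS-haplotype seq
    gene_concat: dict = field(default_factory=dict)    # gene -> concatenated CMS CDS
    rna_seq: dict = field(default_factory=dict)
    repeat_consensus: dict = field(default_factory=dict)  # family -> (seq, mut_rate)
    cp_ref: str = ""
    shared_payloads: list = field(default_factory=list)
    maintainer_edits: dict = field(default_factory=dict)  # cultivar -> {gene: GeneEdit}


def _build_gene_sequences(cfg: SimConfig, rng: np.random.Generator, reg: Registry) -> None:
    for gene, total in GENE_LENGTHS.items():
        fixed = _FIXED_CMS_CODONS.get(gene)
        cds = random_cds(rng, total, cfg.gc, fixed)
        reg.gene_concat[gene] = cds
        if gene in GENE_PARTS:
            off = 0
            for part, plen in GENE_PARTS[gene].items():
                reg.gene_cds[(gene, part)] = cds[off : off + plen]
                off += plen
            assert off == total
        else:
            reg.gene_cds[(gene, None)] = cds
    for rna, n in RNA_LENGTHS.items():
        reg.rna_seq[rna] = _clean_ssrs(random_seq(rng, n, cfg.gc), rng)
    for trna in ("trnM", "trnP", "trnW", "trnC", "trnN", "trnY",
                 "trnS", "trnD", "trnF", "trnE"):
        reg.rna_seq[trna] = _clean_ssrs(random_seq(rng, TRNA_LENGTH, cfg.gc), rng)


def _cluster_payload(
    idx: int, plan: list, cfg: SimConfig, rng: np.random.Generator, reg: Registry
) -> InsertPayload:
    strand = "+" if idx in _FORWARD_CLUSTERS else ("+" if rng.random() < 0.5 else "-")
    members = plan if strand == "+" else plan[::-1]
    chunks: list[str] = []
    feats: list[GeneFeature] = []
    pos = 0
    prev_overlap = 0
    for t, (gene, part, kind) in enumerate(members):
        if t > 0 and prev_overlap == 0:
            gap = int(rng.integers(100, 500))
            chunks.append(_clean_ssrs(random_seq(rng, gap, cfg.gc), rng))
            pos += gap
        if kind == "protein":
            seq = reg.gene_cds[(gene, part)]
        else:
            seq = reg.rna_seq[gene]
        gseq = seq if strand == "+" else revcomp(seq)
        overlap_next = 0
        if idx == 6 and gene == "rps3" and part == "b":
            overlap_next = RPL16_RPS3_OVERLAP
        if prev_overlap:
            # rpl16 starts inside rps3b: its leading bases are rps3b's tail
            tail = chunks[-1][-prev_overlap:]
            gseq = tail + gseq[prev_overlap:]
            reg.gene_cds[(gene, part)] = gseq if strand == "+" else revcomp(gseq)
            reg.gene_concat[gene] = reg.gene_cds[(gene, part)]
            start = pos - prev_overlap
            chunks.append(gseq[prev_overlap:])
            feats.append(GeneFeature(gene, start, start + len(gseq), strand, kind, part))
            pos = start + len(gseq)
        else:
            chunks.append(gseq)
            feats.append(GeneFeature(gene, pos, pos + len(gseq), strand, kind, part))
            pos += len(gseq)
        prev_overlap = overlap_next
    marks = [Mark("cluster", f"cluster{idx}", 0, pos)]
    return InsertPayload(f"cluster{idx}", "cluster", "".join(chunks), feats, marks)


def _repeat_family_payloads(
    fam: str, cfg_entry: tuple, rng: np.random.Generator, reg: Registry,
    ir_fraction: float, gc: float,
) -> list[list[InsertPayload]]:
    n_fam, lo, hi, mu = cfg_entry
    out = []
    for i in range(n_fam):
        arm = int(rng.integers(lo, hi + 1))
        consensus = _clean_ssrs(random_seq(rng, arm, gc), rng)
        name = f"{fam}{i}"
        reg.repeat_consensus[name] = (consensus, mu)
        ir = rng.random() < ir_fraction
        copies = []
        for c in range(2):
            s = _mutate(rng, consensus, mu)
            strand = "+"
            if ir and c == 1:
                s = revcomp(s)
                strand = "-"
            copies.append(
                InsertPayload(
                    f"{name}.{c}", "repeat_copy", s,
                    marks=[Mark("repeat", f"{name}.{c}", 0, len(s), strand,
                                {"family": name})],
                )
            )
        out.append(copies)
    return out


def _ssr_payload(name: str, motif: str, copies: int) -> InsertPayload:
    seq = motif * copies
    from mitocompare.repeats import canonical_motif

    return InsertPayload(
        name, "ssr", seq,
        marks=[Mark("ssr", name, 0, len(seq), "+",
                    {"motif": canonical_motif(motif), "copies": copies})],
    )


def _random_primitive_motif(rng: np.random.Generator, m: int) -> str:
    from mitocompare.repeats import _is_primitive

    while True:
        s = "".join(_BASES[rng.integers(0, 4, m)])
        if _is_primitive(s) and len(set(s)) > (1 if m > 1 else 0):
            return s


_SSR_COPIES = {1: (12, 15), 2: (6, 8), 3: (4, 6), 4: (3, 5), 5: (3, 4), 6: (3, 4)}


def build_base(cfg: SimConfig) -> tuple[GenomeState, Registry]:
    """The neutral scaffold genome carrying the shared gene layout,
    repeat families, SSRs and chloroplast-derived tracts."""
    rng = np.random.default_rng([cfg.seed, 1])
    reg = Registry()
    _build_gene_sequences(cfg, rng, reg)

    payload_specs: list[tuple[InsertPayload, int]] = []  # (payload, margin)
    gene_specs = CLUSTER_PLAN if cfg.include_genes else []
    for idx, plan in enumerate(gene_specs):
        payload_specs.append((_cluster_payload(idx, plan, cfg, rng, reg), 1100))
    for gene, part, kind in (SINGLE_GENES if cfg.include_genes else []):
        seq = reg.gene_cds[(gene, part)] if kind == "protein" else reg.rna_seq[gene]
        strand = "+" if gene in set(POLYMORPHIC_A + POLYMORPHIC_B) else (
            "+" if rng.random() < 0.5 else "-")
        gseq = seq if strand == "+" else revcomp(seq)
        payload_specs.append(
            (InsertPayload(gene, "gene", gseq,
                           [GeneFeature(gene, 0, len(gseq), strand, kind, part)]),
             1100)
        )
    for fam, entry in (("S", cfg.small_repeats), ("I", cfg.intermediate_repeats),
                       ("L", cfg.large_repeats)):
        for copies in _repeat_family_payloads(fam, entry, rng, reg,
                                              cfg.repeat_ir_fraction, cfg.gc):
            for p in copies:
                payload_specs.append((p, 150))
    s_idx = 0
    for m, count in cfg.ssr_counts.items():
        for _ in range(count):
            lo, hi = _SSR_COPIES[m]
            payload_specs.append(
                (_ssr_payload(f"ssr{s_idx}", _random_primitive_motif(rng, m),
                              int(rng.integers(lo, hi + 1))), 100)
            )
            s_idx += 1
    reg.cp_ref = _clean_ssrs(random_seq(rng, cfg.cp_ref_length, 0.38), rng)
    cp_total = int(cfg.cp_fraction * cfg.maintainer_length)
    cp_lengths = [int(cp_total * f) for f in (0.36, 0.27, 0.22, 0.15)]
    cp_off = 0
    for t, cl in enumerate(cp_lengths):
        seg = reg.cp_ref[cp_off : cp_off + cl]
        cp_off += cl + 400
        payload_specs.append(
            (InsertPayload(f"cp{t}", "cp", seg,
                           marks=[Mark("cp", f"cp{t}", 0, cl)]), 250)
        )

    L = cfg.maintainer_length
    placer = _Placer(L, rng)
    arr = np.frombuffer(random_seq(rng, L, cfg.gc).encode(), dtype="S1").astype("U1")
    feats: list[GeneFeature] = []
    marks: list[Mark] = []
    payload_specs.sort(key=lambda t: -(len(t[0].seq) + 2 * t[1]))
    for payload, margin in payload_specs:
        pos = placer.free_spot(len(payload.seq), margin)
        arr[pos : pos + len(payload.seq)] = list(payload.seq)
        for f in payload.features:
            feats.append(replace(f, start=f.start + pos, end=f.end + pos))
        for m in payload.marks:
            marks.append(replace(m, start=m.start + pos, end=m.end + pos,
                                 meta=dict(m.meta)))
    seq = "".join(arr)
    protected = [(f.start, f.end) for f in feats] + [m.interval for m in marks]
    seq = _clean_ssrs(seq, rng, protected)
    seq = _disrupt_chance_repeats(seq, feats, marks, rng)
    state = GenomeState("base", seq, feats, marks)
    return state, reg


def _duplicate_feature_buckets(feats: list[GeneFeature]) -> dict:
    """Features that are genuine sequence duplicates of each other
    (extra gene copies, repeated tRNAs) — bucketed by base name."""
    from mitocompare.genome_io import is_copy_label

    buckets: dict[tuple, list[GeneFeature]] = {}
    for f in feats:
        part = None if (f.part_suffix is None or is_copy_label(f.part_suffix)) \
            else f.part_suffix
        buckets.setdefault((f.name, part), []).append(f)
    return {k: v for k, v in buckets.items() if len(v) > 1}


def _disrupt_chance_repeats(
    seq: str, feats: list[GeneFeature], marks: list[Mark], rng: np.random.Generator
) -> str:
    """Substitute bases inside accidental dispersed repeats of the random
    background so that planted repeats are the only ones above threshold."""
    from mitocompare.repeats import find_dispersed_repeats

    planted = [m.interval for m in marks if m.kind in ("repeat", "ssr")]
    for group in _duplicate_feature_buckets(feats).values():
        planted.extend((f.start, f.end) for f in group)
    protected = [(f.start, f.end) for f in feats] + [m.interval for m in marks]

    def frac_overlap(iv, spans):
        ln = iv[1] - iv[0]
        best = 0
        for s, e in spans:
            best = max(best, max(0, min(iv[1], e) - max(iv[0], s)))
        return best / ln if ln else 0.0

    s = list(seq)
    for p in find_dispersed_repeats("".join(s), min_len=20):
        if frac_overlap(p.interval_1, planted) > 0.5 and \
           frac_overlap(p.interval_2, planted) > 0.5:
            continue
        # disrupt whichever arm is free of planted/protected sequence
        target = None
        for iv in (p.interval_2, p.interval_1):
            if frac_overlap(iv, protected) == 0.0:
                target = iv
                break
        if target is None:
            continue
        a, b = target
        n_sub = max(2, int(0.12 * (b - a)) + 1)
        for q in np.linspace(a + 1, b - 2, n_sub).astype(int):
            cur = s[q]
            s[q] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur] if cur in "ACGT" else "A"
    return "".join(s)


# ---------------------------------------------------------------------------
# cultivar variants
# ---------------------------------------------------------------------------

def _make_edit_presets(cultivar: str, reg: Registry, rng: np.random.Generator) -> dict:
    if cultivar == "A":
        presets = {
            "atp6": _preset_atp6_a(),
            "nad2": _preset_nad2_a(rng),
            "sdh3": _preset_sdh3_a(),
            "cox2": _preset_cox2_a(),
        }
        presets["nad2"].cms_indels = [(455, +90)]
        extras = [g for g in POLYMORPHIC_A if g not in CANDIDATE_GENES]
    else:
        presets = {
            "atp6": _preset_atp6_b(),
            "nad2": _preset_nad2_b(),
            "sdh3": _preset_sdh3_b(),
            "cox2": _preset_cox2_b(),
        }
        presets["nad2"].cms_indels = [(455, +3)]
        presets["cox2"].cms_indels = [(382, -33)]
        extras = [g for g in POLYMORPHIC_B if g not in CANDIDATE_GENES]
    presets["sdh3"].cms_indels = [(276, +15)] if cultivar == "A" else [(273, +3)]
    for g in extras:
        presets[g] = _preset_single_sub(g, reg.gene_concat[g], rng)
    for p in presets.values():
        if not hasattr(p, "cms_indels"):
            p.cms_indels = []
    return presets


def _split_parts(gene: str, concat: str, cms_indels: list) -> dict:
    """Split a (maintainer-version) concatenated CDS back into exon parts,
    shifting CMS-frame part boundaries across the preset's indels."""
    if gene not in GENE_PARTS:
        return {None: concat}
    bounds = [0]
    for plen in GENE_PARTS[gene].values():
        bounds.append(bounds[-1] + plen)

    def to_maint(cb: int) -> int:
        return cb + sum(d for (cp, d) in cms_indels if cp < cb)

    mbounds = [to_maint(cb) for cb in bounds]
    assert mbounds[-1] == len(concat), (gene, mbounds, len(concat))
    out = {}
    for i, part in enumerate(GENE_PARTS[gene]):
        out[part] = concat[mbounds[i] : mbounds[i + 1]]
    return out


def _gene_splices(state: GenomeState, gene: str, new_parts: dict) -> list:
    from mitocompare.genome_io import is_copy_label

    splices = []
    for f in state.features:
        if f.name != gene or is_copy_label(f.part_suffix):
            continue
        seq = new_parts[f.part_suffix]
        if f.strand != "+":
            raise ValueError(f"edited gene {gene} must be forward-strand")
        splices.append((f.start, f.end - f.start, seq))
    if not splices:
        raise ValueError(f"gene {gene} not found")
    return splices




def _gene_sub_positions(state: GenomeState, gene: str, diffs: list) -> list:
    """Genomic (pos, base) for CDS-index substitutions of a gene's primary
    copy (exon parts resolved; forward strand required)."""
    from mitocompare.genome_io import is_copy_label

    feats = {
        f.part_suffix: f
        for f in state.features
        if f.name == gene and not is_copy_label(f.part_suffix)
    }
    order = list(GENE_PARTS[gene]) if gene in GENE_PARTS else [None]
    out = []
    off = 0
    for part in order:
        f = feats[part]
        ln = f.end - f.start
        if f.strand != "+":
            raise ValueError(f"edited gene {gene} must be forward-strand")
        for idx, b in diffs:
            if off <= idx < off + ln:
                out.append((f.start + idx - off, b))
        off += ln
    return out



def _protected_points(state: GenomeState) -> list[tuple[int, int]]:
    pts = []
    for f in state.features:
        pts.append((f.start - 700, f.end + 700))
    for m in state.marks:
        margin = 700 if m.kind == "cluster" else 200
        pts.append((m.start - margin, m.end + margin))
    return pts


def _free_point(rng, L, protected, taken, margin_taken=3000, lo=5000) -> int:
    for _ in range(5000):
        p = int(rng.integers(lo, L - lo))
        if any(a <= p <= b for a, b in protected):
            continue
        if any(s - margin_taken <= p <= e + margin_taken for s, e in taken):
            continue
        return p
    raise RuntimeError("no free breakpoint found")


def _gene_copy_payload(gene: str, k: int, cds_genomic: str, rng, gc: float) -> InsertPayload:
    fl1 = _clean_ssrs(random_seq(rng, 150, gc), rng)
    fl2 = _clean_ssrs(random_seq(rng, 150, gc), rng)
    seq = fl1 + cds_genomic + fl2
    feat = GeneFeature(gene, 150, 150 + len(cds_genomic), "+", "protein", f"D{k}")
    return InsertPayload(f"{gene}-D{k}", "gene_copy", seq, [feat])


def maintainer_variant(
    base: GenomeState, reg: Registry, cfg: SimConfig, cultivar: str
) -> GenomeState:
    """Apply cultivar-specific maintainer features to the base scaffold:
    maintainer versions of the polymorphic genes, extra gene copies, and
    (cultivar B) intergenic background divergence plus a few SSR gains."""
    rng = np.random.default_rng([cfg.seed, 2 if cultivar == "A" else 3])
    presets = _make_edit_presets(cultivar, reg, rng) if cfg.include_genes else {}
    reg.maintainer_edits[cultivar] = presets
    plan = StructuralPlan()
    for gene, edit in presets.items():
        cms = reg.gene_concat[gene]
        maint = edit.to_maintainer(cms)
        if len(maint) == len(cms):
            diffs = [(i, maint[i]) for i in range(len(cms)) if maint[i] != cms[i]]
            plan.substitutions += _gene_sub_positions(base, gene, diffs)
        else:
            plan.splices += _gene_splices(
                base, gene, _split_parts(gene, maint, edit.cms_indels)
            )

    protected = _protected_points(base)
    taken: list[tuple[int, int]] = []
    col = 0 if cultivar == "A" else 2
    maint_cds = {}
    for gene, edit in presets.items():
        maint_cds[gene] = edit.to_maintainer(reg.gene_concat[gene])
    for gene, counts in (COPY_PLAN.items() if cfg.include_genes else []):
        for k in range(2, counts[col] + 1):
            cds = maint_cds.get(gene, reg.gene_concat.get(gene))
            p = _free_point(rng, len(base.seq), protected, taken)
            taken.append((p, p))
            plan.insertions.append((p, _gene_copy_payload(gene, k, cds, rng, cfg.gc)))
    # intergenic background divergence of this cultivar from the ancestor
    rate = cfg.divergence_rate if cultivar == "B" else cfg.divergence_rate_a
    free = np.ones(len(base.seq), bool)
    for a, b in [(f.start, f.end) for f in base.features] + \
                [m.interval for m in base.marks]:
        free[max(0, a - 5) : b + 5] = False
    free_idx = np.nonzero(free)[0]
    n_sub = rng.binomial(len(base.seq), rate)
    for p in rng.choice(free_idx, size=min(n_sub, free_idx.size), replace=False):
        cur = base.seq[p]
        alts = [b for b in "ACGT" if b != cur]
        plan.substitutions.append((int(p), alts[rng.integers(3)]))
    if cultivar == "B":
        for t in range(cfg.maintainer_b_ssr_gains):
            m = int(rng.integers(4, 7))
            lo_c, hi_c = _SSR_COPIES[m]
            p = _free_point(rng, len(base.seq), protected, taken)
            taken.append((p, p))
            plan.insertions.append(
                (p, _ssr_payload(f"ssrB{t}", _random_primitive_motif(rng, m),
                                 int(rng.integers(lo_c, hi_c + 1))))
            )
    state, _blocks = assemble(base, f"{cultivar}_maint", plan)
    state.seq = _disrupt_chance_repeats(state.seq, state.features, state.marks, rng)
    return state


def reference_variant(base: GenomeState, cfg: SimConfig) -> GenomeState:
    """An outgroup relative: the base scaffold plus intergenic SNPs."""
    rng = np.random.default_rng([cfg.seed, 9])
    free = np.ones(len(base.seq), bool)
    for a, b in [(f.start, f.end) for f in base.features] + \
                [m.interval for m in base.marks]:
        free[max(0, a - 5) : b + 5] = False
    free_idx = np.nonzero(free)[0]
    plan = StructuralPlan()
    n_sub = rng.binomial(len(base.seq), cfg.reference_divergence)
    for p in rng.choice(free_idx, size=min(n_sub, free_idx.size), replace=False):
        cur = base.seq[p]
        alts = [b for b in "ACGT" if b != cur]
        plan.substitutions.append((int(p), alts[rng.integers(3)]))
    state, _ = assemble(base, "REF", plan)
    return state


# ---------------------------------------------------------------------------
# shared CMS-specific payloads
# ---------------------------------------------------------------------------

def _orf_payload_seq(rng, aa: int, gc: float) -> str:
    return random_cds(rng, (aa + 1) * 3, gc)


def build_shared_payloads(cfg: SimConfig, reg: Registry) -> list[InsertPayload]:
    """The CMS-specific regions (identical in every CMS genome). Region 1
    carries the planted specific ORFs — three of them adjacent, echoing a
    chimeric-ORF cluster — plus its own repeat families; all regions are
    scrubbed of accidental ORFs so the specific-ORF inventory is exact."""
    rng = np.random.default_rng([cfg.seed, 6])
    payloads = []
    aa_list = list(SPECIFIC_ORF_AA[: cfg.n_specific_orfs])
    for idx, rl in enumerate(cfg.region_lengths):
        name = f"region{idx + 1}"
        if idx != 0:
            seq = _clean_ssrs(random_seq(rng, rl, cfg.gc), rng)
            seq = _clean_orfs(seq, rng)
            payloads.append(InsertPayload(name, "region", seq))
            continue
        placer = _Placer(rl, rng)
        arr = np.frombuffer(random_seq(rng, rl, cfg.gc).encode(), "S1").astype("U1")
        marks: list[Mark] = []
        # adjacent trio first (aa 100, 115, 115 -> orf100 / orf115 / orf115b)
        trio = aa_list[:3]
        rest = aa_list[3:]
        # each planted ORF is framed by an adjacent in-frame stop on its
        # upstream side, so no chance upstream ATG can extend it
        trio_seqs = [_orf_payload_seq(rng, aa, cfg.gc) for aa in trio]
        gaps = [int(rng.integers(150, 400)) for _ in trio]
        block_len = sum(len(s) + 3 for s in trio_seqs) + sum(gaps[:-1])
        pos = placer.free_spot(block_len, 300)
        cur = pos
        for t, (aa, s) in enumerate(zip(trio, trio_seqs)):
            framed = "TAA" + s
            arr[cur : cur + len(framed)] = list(framed)
            marks.append(Mark("orf", f"sorf{t}", cur + 3, cur + len(framed), "+",
                              {"aa": aa}))
            cur += len(framed)
            if t < len(trio) - 1:
                cur += gaps[t]
        for t, aa in enumerate(rest):
            s = _orf_payload_seq(rng, aa, cfg.gc)
            strand = "+" if t % 2 == 0 else "-"
            framed = "TAA" + s if strand == "+" else revcomp(s) + "TTA"
            p = placer.free_spot(len(framed), 250)
            arr[p : p + len(framed)] = list(framed)
            o0 = p + 3 if strand == "+" else p
            marks.append(Mark("orf", f"sorf{t + 3}", o0, o0 + len(s), strand,
                              {"aa": aa}))
        # region-internal repeat families (novel sequence)
        fam_specs = [("R1L0", 800, 2)] + [(f"R1S{i}", int(rng.integers(25, 45)), 2)
                                          for i in range(5)]
        for fam, armlen, ncopies in fam_specs:
            consensus = _clean_orfs(_clean_ssrs(random_seq(rng, armlen, cfg.gc), rng), rng)
            for c in range(ncopies):
                strand = "+" if c == 0 or rng.random() < 0.5 else "-"
                s = consensus if strand == "+" else revcomp(consensus)
                p = placer.free_spot(len(s), 250)
                arr[p : p + len(s)] = list(s)
                marks.append(Mark("repeat", f"{fam}.{c}", p, p + len(s), strand,
                                  {"family": fam}))
        seq = "".join(arr)
        prot = [m.interval for m in marks]
        seq = _clean_ssrs(seq, rng, prot)
        seq = _clean_orfs(seq, rng, prot)
        payloads.append(InsertPayload(name, "region", seq, marks=marks))
    reg.shared_payloads = payloads
    return payloads


# ---------------------------------------------------------------------------
# CMS derivation
# ---------------------------------------------------------------------------

def cms_variant(
    mstate: GenomeState, reg: Registry, cfg: SimConfig, cultivar: str
) -> tuple[GenomeState, list]:
    """Derive the CMS genome from its maintainer: rearrangements,
    insertions (shared regions, palindrome, amplified repeats, SSR and
    gene-copy gains), gene-copy losses, and the candidate-gene edits that
    restore the common CMS haplotype."""
    from mitocompare.genome_io import is_copy_label

    rng = np.random.default_rng([cfg.seed, 4 if cultivar == "A" else 5])
    L = len(mstate.seq)
    protected = _protected_points(mstate)
    plan = StructuralPlan()
    op_ivs: list[tuple[int, int]] = []

    def pick_interval(lo: int, hi: int) -> tuple[int, int]:
        for _ in range(5000):
            length = int(rng.integers(lo, hi))
            s = int(rng.integers(5000, L - length - 5000))
            e = s + length
            if any(a <= s <= b or a <= e <= b for a, b in protected):
                continue
            if any(s - 4000 < ie and e + 4000 > ib for ib, ie in op_ivs):
                continue
            op_ivs.append((s, e))
            return s, e
        raise RuntimeError("failed to place a rearrangement interval")

    for _ in range(cfg.n_inversions):
        plan.inversions.append(pick_interval(*cfg.inversion_len))
    for flip, count in ((False, cfg.n_translocations), (True, cfg.n_trans_inv)):
        for _ in range(count):
            s, e = pick_interval(*cfg.translocation_len)
            d = _free_point(rng, L, protected, op_ivs, margin_taken=4000)
            op_ivs.append((d, d))
            plan.translocations.append((s, e, d, flip))

    def anchor() -> int:
        p = _free_point(rng, L, protected, op_ivs, margin_taken=4000)
        op_ivs.append((p, p))
        return p

    for payload in reg.shared_payloads:
        plan.insertions.append((anchor(), payload))

    arm = cfg.palindrome_arms[cultivar]
    X = _clean_orfs(_clean_ssrs(random_seq(rng, arm, cfg.gc), rng), rng)
    pal = InsertPayload(
        f"pal_{cultivar}", "palindrome", X + revcomp(X),
        marks=[
            Mark("repeat", "pal.0", 0, arm, "+", {"family": f"pal{cultivar}"}),
            Mark("repeat", "pal.1", arm, 2 * arm, "-", {"family": f"pal{cultivar}"}),
        ],
    )
    plan.insertions.append((anchor(), pal))

    n_amp = cfg.amplified_families[cultivar]
    for i in range(n_amp):
        fam = f"I{i}" if cultivar == "A" else f"I{i + 10}"
        consensus, mu = reg.repeat_consensus[fam]
        s = _mutate(rng, consensus, mu)
        plan.insertions.append(
            (anchor(),
             InsertPayload(f"{fam}.amp", "repeat_copy", s,
                           marks=[Mark("repeat", f"{fam}.2", 0, len(s), "+",
                                       {"family": fam})]))
        )

    gains = cfg.cms_ssr_gains[cultivar]
    signature_motif = "CTTA" if cultivar == "A" else "CTCCAA"
    plan.insertions.append(
        (anchor(), _ssr_payload(f"ssr{cultivar}sig", signature_motif, 4))
    )
    for t in range(gains - 1):
        m = int(rng.integers(1, 7))
        lo_c, hi_c = _SSR_COPIES[m]
        plan.insertions.append(
            (anchor(), _ssr_payload(f"ssr{cultivar}g{t}", _random_primitive_motif(rng, m),
                                    int(rng.integers(lo_c, hi_c + 1))))
        )

    col_m, col_c = (0, 1) if cultivar == "A" else (2, 3)
    for gene, counts in (COPY_PLAN.items() if cfg.include_genes else []):
        for k in range(counts[col_c] + 1, counts[col_m] + 1):
            feat = next(
                f for f in mstate.features
                if f.name == gene and f.part_suffix == f"D{k}"
            )
            plan.splices.append((feat.start, feat.end - feat.start, ""))
            plan.feature_removals.append(_feature_key(feat))
        for k in range(counts[col_m] + 1, counts[col_c] + 1):
            cds = reg.gene_concat[gene]
            plan.insertions.append(
                (anchor(), _gene_copy_payload(gene, k, cds, rng, cfg.gc))
            )

    presets = reg.maintainer_edits[cultivar]
    for gene, edit in presets.items():
        cms = reg.gene_concat[gene]
        maint = edit.to_maintainer(cms)
        if len(maint) == len(cms):
            diffs = [(i, cms[i]) for i in range(len(cms)) if maint[i] != cms[i]]
            plan.substitutions += _gene_sub_positions(mstate, gene, diffs)
        else:
            cms_parts = (
                {p: reg.gene_cds[(gene, p)] for p in GENE_PARTS[gene]}
                if gene in GENE_PARTS
                else {None: cms}
            )
            plan.splices += _gene_splices(mstate, gene, cms_parts)

    state, blocks = assemble(mstate, f"{cultivar}_cms", plan)
    state.seq = _disrupt_chance_repeats(state.seq, state.features, state.marks, rng)
    return state, blocks


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class QuartetTruth:
    """Planted ground truth for a simulated quartet (plus outgroup)."""

    config: SimConfig
    states: dict[str, GenomeState]
    blocks: dict[str, list]              # cms id -> [(m_start, m_end, class)]
    gene_edits: dict[str, dict[str, list]]
    polymorphic: dict[str, list[str]]
    candidate_genes: list[str]
    cluster_signatures: list[tuple]
    pair_of: dict[str, str]              # cms id -> maintainer id

    def marks(self, genome_id: str, kind: str | None = None) -> list[Mark]:
        ms = self.states[genome_id].marks
        return [m for m in ms if kind is None or m.kind == kind]

    def repeat_pairs(self, genome_id: str):
        """Expected dispersed-repeat pairs: (iv1, iv2, orientation)."""
        from itertools import combinations

        groups: dict[str, list[Mark]] = {}
        for m in self.marks(genome_id, "repeat"):
            groups.setdefault(m.meta["family"], []).append(m)
        pairs = []
        for fam, ms in groups.items():
            for a, b in combinations(sorted(ms, key=lambda m: m.start), 2):
                orient = "DR" if a.strand == b.strand else "IR"
                pairs.append((a.interval, b.interval, orient))
        for group in _duplicate_feature_buckets(self.states[genome_id].features).values():
            group = sorted(group, key=lambda f: f.start)
            for a, b in combinations(group, 2):
                orient = "DR" if a.strand == b.strand else "IR"
                pairs.append(((a.start, a.end), (b.start, b.end), orient))
        return pairs

    def ssr_records(self, genome_id: str):
        from mitocompare.repeats import canonical_motif

        out = []
        for m in self.marks(genome_id, "ssr"):
            motif = m.meta["motif"]
            if m.strand == "-":
                motif = canonical_motif(revcomp(motif))
            out.append((motif, m.start, m.end))
        return out

    def specific_orfs(self, genome_id: str):
        return [(m.meta["aa"], m.start, m.end, m.strand)
                for m in self.marks(genome_id, "orf")]

    def regions(self, genome_id: str):
        return [(m.name, m.start, m.end) for m in self.marks(genome_id, "region")]

    def palindrome(self, genome_id: str):
        ms = self.marks(genome_id, "palindrome")
        return (ms[0].start, ms[0].end) if ms else None

    def cp_intervals(self, genome_id: str):
        return [m.interval for m in self.marks(genome_id, "cp")]

    def expansion(self, cms_id: str) -> int:
        return len(self.states[cms_id].seq) - len(self.states[self.pair_of[cms_id]].seq)


@dataclass
class Quartet:
    genomes: dict[str, CircularGenome]
    truth: QuartetTruth


def _cluster_signatures() -> list[tuple]:
    from mitocompare.clusters import canonical_signature, collapse_names

    sigs = []
    for plan in CLUSTER_PLAN:
        sigs.append(canonical_signature(collapse_names([g for g, _p, _k in plan])))
    return sigs


class Simulator:
    """Deterministic factory for one simulated quartet."""

    def __init__(self, config: SimConfig):
        self.cfg = config
        self.base, self.reg = build_base(config)
        build_shared_payloads(config, self.reg)
        self._maint: dict[str, GenomeState] = {}
        self._cms: dict[str, tuple[GenomeState, list]] = {}

    def maintainer(self, cultivar: str = "A") -> GenomeState:
        if cultivar not in self._maint:
            self._maint[cultivar] = maintainer_variant(
                self.base, self.reg, self.cfg, cultivar
            )
        return self._maint[cultivar]

    def cms(self, cultivar: str = "A") -> tuple[GenomeState, list]:
        if cultivar not in self._cms:
            self._cms[cultivar] = cms_variant(
                self.maintainer(cultivar), self.reg, self.cfg, cultivar
            )
        return self._cms[cultivar]

    def reference(self) -> GenomeState:
        return reference_variant(self.base, self.cfg)

    def quartet(self) -> Quartet:
        ma = self.maintainer("A")
        ca, blocks_a = self.cms("A")
        mb = self.maintainer("B")
        cb, blocks_b = self.cms("B")
        ref = self.reference()
        states = {s.id: s for s in (ma, ca, mb, cb, ref)}
        truth = QuartetTruth(
            config=self.cfg,
            states=states,
            blocks={"A_cms": blocks_a, "B_cms": blocks_b},
            gene_edits={
                cv: {g: e.expected_events for g, e in self.reg.maintainer_edits[cv].items()}
                for cv in ("A", "B")
            },
            polymorphic={"A": list(POLYMORPHIC_A), "B": list(POLYMORPHIC_B)},
            candidate_genes=list(CANDIDATE_GENES),
            cluster_signatures=_cluster_signatures(),
            pair_of={"A_cms": "A_maint", "B_cms": "B_maint"},
        )
        return Quartet(
            genomes={gid: st.to_genome() for gid, st in states.items()},
            truth=truth,
        )


def generate_quartet(config: SimConfig) -> Quartet:
    """Two maintainer/CMS pairs sharing one CMS haplotype, plus outgroup."""
    return Simulator(config).quartet()


def generate_maintainer(config: SimConfig, cultivar: str = "A"):
    """One maintainer genome with its generator (which holds the truth
    registry needed to derive the paired CMS genome)."""
    sim = Simulator(config)
    return sim.maintainer(cultivar).to_genome(), sim


def derive_cms(sim: Simulator, cultivar: str = "A"):
    """The CMS derivative of a generated maintainer, with truth blocks."""
    state, blocks = sim.cms(cultivar)
    return state.to_genome(), blocks
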