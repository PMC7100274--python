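"""Candidate-gene comparison between maintainer and CMS genomes.

Homologous protein-coding genes are paired by base name (multi-copy genes
by reciprocal best identity), their CDSs globally aligned, and every
difference reported with codon context: substitutions are placed at the
first nucleotide of the affected maintainer codon (1-based within the CDS)
with the changed bases uppercased, and classified as synonymous or
non-synonymous under the standard genetic code; indels are reported as
nucleotide ranges with lengths. Per-cultivar polymorphic gene sets are then
intersected to nominate CMS-associated candidates.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from mitocompare.genome_io import CircularGenome, GeneFeature, is_copy_label
from mitocompare.orfs import global_identity

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
INDEL = "indel"


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_substitution(codon_a: str, codon_b: str) -> str:
    """Synonymous iff both codons translate to the same amino acid.

    Raises ValueError for identical codons; returns "unclassified" when a
    codon contains an ambiguous base.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if codon_a == codon_b:
        raise ValueError("not a substitution: codons identical")
    if len(codon_a) != 3 or len(codon_b) != 3:
        raise ValueError("codons must be length 3")
    if set(codon_a + codon_b) - set("ACGT"):
        return "unclassified"
    return SYNONYMOUS if translate_codon(codon_a) == translate_codon(codon_b) else NONSYNONYMOUS


@dataclass
class PolymorphismEvent:
    """One difference between a maintainer CDS (a) and a CMS CDS (b)."""

    kind: str  # substitution | deletion | insertion
    position: int  # 1-based in the maintainer CDS (codon start for subs)
    end: int | None = None  # last deleted nt (deletions)
    length: int = 0  # indel length
    codon_before: str = ""
    codon_after: str = ""
    aa_before: str = ""
    aa_after: str = ""
    synonymy: str = ""
    seq: str = ""  # deleted / inserted bases

    def format_table(self) -> str:
        """Human-readable one-liner, Table-style."""
        if self.kind == "substitution":
            mark_b = "*" if self.synonymy == SYNONYMOUS else self.aa_before
            mark_a = "*" if self.synonymy == SYNONYMOUS else self.aa_after
            return (
                f"{self.position} {self.codon_before} ({mark_b}) -> "
                f"{self.position} {self.codon_after} ({mark_a})"
            )
        if self.kind == "deletion":
            return f"{self.position}-{self.end} -> - ({self.length})"
        return f"- ({self.length}) -> after {self.position}"


@dataclass
class PolymorphismRecord:
    gene: str
    cultivar: str = ""
    length_a: int = 0
    length_b: int = 0
    events: list[PolymorphismEvent] = field(default_factory=list)

    @property
    def polymorphic(self) -> bool:
        return bool(self.events)

    @property
    def net_indel(self) -> int:
        net = 0
        for e in self.events:
            if e.kind == "insertion":
                net += e.length
            elif e.kind == "deletion":
                net -= e.length
        return net


def _cds_aligner() -> Align.PairwiseAligner:
    # affine penalties keep biological indels contiguous instead of
    # fragmenting a long gap into cost-equivalent pieces
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1.5
    al.open_gap_score = -6
    al.extend_gap_score = -0.2
    return al


def _alignment_ops(seq_a: str, seq_b: str):
    """(count, op) runs of the global alignment; op in {'=','X','I','D'}.

    'D' consumes seq_a only (deletion in b); 'I' consumes seq_b only.
    """
    aln = _cds_aligner().align(seq_a, seq_b)[0]
    coords = aln.coordinates  # rows: a, b
    ops = []
    for t in range(coords.shape[1] - 1):
        da = int(coords[0, t + 1] - coords[0, t])
        db = int(coords[1, t + 1] - coords[1, t])
        if da and db:
            for u in range(da):
                ia, ib = int(coords[0, t]) + u, int(coords[1, t]) + u
                ops.append((1, "=" if seq_a[ia] == seq_b[ib] else "X"))
        elif da:
            ops.append((da, "D"))
        elif db:
            ops.append((db, "I"))
    # merge adjacent equal ops
    merged = []
    for num, op in ops:
        if merged and merged[-1][1] == op:
            merged[-1][0] += num
        else:
            merged.append([num, op])
    return [(n, o) for n, o in merged]


def _format_codon(codon: str, changed_offsets: set[int]) -> str:
    return "".join(
        c.upper() if i in changed_offsets else c.lower() for i, c in enumerate(codon)
    )


def compare_gene(
    seq_a: str,
    seq_b: str,
    gene: str = "",
    cultivar: str = "",
) -> PolymorphismRecord:
    """Globally align two CDSs and call events with codon context.

    ``seq_a`` is the maintainer CDS (codon 1 at position 1), ``seq_b`` the
    CMS CDS. Indels are left-normalized (shifted to the lowest equivalent
    maintainer position). Sequences whose length is not a multiple of three
    are still compared; codon-context fields are filled only where a full
    maintainer codon exists.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    rec = PolymorphismRecord(gene=gene, cultivar=cultivar,
                             length_a=len(seq_a), length_b=len(seq_b))
    if seq_a == seq_b:
        return rec
    a_pos = 0  # consumed of a
    b_pos = 0
    subs: list[tuple[int, str, str]] = []  # (a index 0-based, a base, b base)
    indels: list[PolymorphismEvent] = []
    for num, op in _alignment_ops(seq_a, seq_b):
        if op == "=":
            a_pos += num
            b_pos += num
        elif op == "X":
            for t in range(num):
                subs.append((a_pos + t, seq_a[a_pos + t], seq_b[b_pos + t]))
            a_pos += num
            b_pos += num
        elif op == "D":
            # gap in query (seq_b): bases of a absent from b -> deletion
            s = a_pos
            # left-normalize
            while s > 0 and seq_a[s - 1] == seq_a[s + num - 1]:
                s -= 1
            indels.append(
                PolymorphismEvent(
                    kind="deletion", position=s + 1, end=s + num, length=num,
                    seq=seq_a[s : s + num], synonymy=INDEL,
                )
            )
            a_pos += num
        else:  # I: insertion in b relative to a
            ins = seq_b[b_pos : b_pos + num]
            s = a_pos
            while s > 0 and seq_a[s - 1] == ins[-1]:
                ins = seq_a[s - 1] + ins[:-1]
                s -= 1
            indels.append(
                PolymorphismEvent(
                    kind="insertion", position=s, length=num, seq=ins,
                    synonymy=INDEL,
                )
            )
            b_pos += num
    # group substitutions by maintainer codon
    by_codon: dict[int, list[tuple[int, str, str]]] = defaultdict(list)
    for a_idx, a_base, b_base in subs:
        by_codon[a_idx // 3].append((a_idx, a_base, b_base))
    events: list[PolymorphismEvent] = []
    for codon_idx in sorted(by_codon):
        muts = by_codon[codon_idx]
        c_start = codon_idx * 3
        codon_a = seq_a[c_start : c_start + 3]
        if len(codon_a) < 3:
            for a_idx, a_base, b_base in muts:
                events.append(
                    PolymorphismEvent(
                        kind="substitution", position=a_idx + 1,
                        codon_before=a_base.lower(), codon_after=b_base.lower(),
                        synonymy="unclassified",
                    )
                )
            continue
        codon_b = list(codon_a)
        changed = set()
        for a_idx, _a_base, b_base in muts:
            off = a_idx - c_start
            codon_b[off] = b_base
            changed.add(off)
        codon_b = "".join(codon_b)
        syn = classify_substitution(codon_a, codon_b)
        aa_a = translate_codon(codon_a) if syn != "unclassified" else "?"
        aa_b = translate_codon(codon_b) if syn != "unclassified" else "?"
        events.append(
            PolymorphismEvent(
                kind="substitution", position=c_start + 1,
                codon_before=_format_codon(codon_a, changed),
                codon_after=_format_codon(codon_b, changed),
                aa_before=aa_a, aa_after=aa_b, synonymy=syn,
            )
        )
    rec.events = sorted(events + indels, key=lambda e: e.position)
    assert rec.length_b - rec.length_a == rec.net_indel
    return rec


# ---------------------------------------------------------------------------
# gene extraction / homolog pairing
# ---------------------------------------------------------------------------

def gene_copies(genome: CircularGenome, kinds=("protein",)) -> dict[str, list[tuple[str, str]]]:
    """Per base gene name, the list of (copy label, CDS sequence).

    Trans-spliced exon parts (suffixes a..e) of one copy are concatenated
    in suffix order; "D<k>" labels mark distinct copies. The primary copy
    is labelled "D1".
    """
    groups: dict[str, dict[str, list[GeneFeature]]] = defaultdict(lambda: defaultdict(list))
    for g in genome.genes:
        if g.kind not in kinds:
            continue
        suffix = g.part_suffix
        if suffix is None:
            copy, part = "D1", ""
        elif is_copy_label(suffix):
            copy, part = suffix, ""
        elif "-" in suffix:  # e.g. part "a" of copy "D2": "a-D2"
            part, copy = suffix.split("-", 1)
        else:
            copy, part = "D1", suffix
        groups[g.name][copy].append((part, g))
    out: dict[str, list[tuple[str, str]]] = {}
    for name, copies in groups.items():
        entries = []
        for copy_label in sorted(copies, key=lambda c: int(c[1:]) if c[1:].isdigit() else 0):
            parts = sorted(copies[copy_label], key=lambda t: t[0])
            seq = "".join(genome.feature_seq(f) for _p, f in parts)
            entries.append((copy_label, seq))
        out[name] = entries
    return out


@dataclass
class HomologPairs:
    pairs: list[tuple[str, str, str, str, str]] = field(default_factory=list)
    # (gene, label_a, label_b, seq_a, seq_b)
    only_a: list[tuple[str, str]] = field(default_factory=list)  # (gene, label)
    only_b: list[tuple[str, str]] = field(default_factory=list)
    ties: list[str] = field(default_factory=list)


def match_homologs(gA: CircularGenome, gB: CircularGenome) -> HomologPairs:
    """Pair protein-coding genes by base name; copies by reciprocal best
    identity; unpaired copies are reported as copy-number differences."""
    copies_a = gene_copies(gA)
    copies_b = gene_copies(gB)
    out = HomologPairs()
    for gene in sorted(set(copies_a) | set(copies_b)):
        ca = copies_a.get(gene, [])
        cb = copies_b.get(gene, [])
        if not cb:
            out.only_a.extend((gene, lab) for lab, _ in ca)
            continue
        if not ca:
            out.only_b.extend((gene, lab) for lab, _ in cb)
            continue
        if len(ca) == 1 and len(cb) == 1:
            out.pairs.append((gene, ca[0][0], cb[0][0], ca[0][1], cb[0][1]))
            continue
        # reciprocal best by identity, greedy on descending identity
        scored = []
        for i, (la, sa) in enumerate(ca):
            for j, (lb, sb) in enumerate(cb):
                scored.append((global_identity(sa, sb, both_strands=False), i, j))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        ident_of = {}
        for ident, i, j in scored:
            ident_of.setdefault((i, j), ident)
        used_a: set[int] = set()
        used_b: set[int] = set()
        top = scored[0][0] if scored else 0.0
        if len(scored) > 1 and scored[0][0] == scored[1][0] and top < 1.0:
            out.ties.append(gene)
        for ident, i, j in scored:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            out.pairs.append((gene, ca[i][0], cb[j][0], ca[i][1], cb[j][1]))
        out.only_a.extend((gene, ca[i][0]) for i in range(len(ca)) if i not in used_a)
        out.only_b.extend((gene, cb[j][0]) for j in range(len(cb)) if j not in used_b)
    return out


def call_polymorphisms(
    gA: CircularGenome, gB: CircularGenome, cultivar: str = ""
) -> list[PolymorphismRecord]:
    """compare_gene over every paired homolog of a maintainer/CMS pair."""
    out = []
    for gene, la, lb, sa, sb in match_homologs(gA, gB).pairs:
        out.append(compare_gene(sa, sb, gene=gene, cultivar=cultivar))
    return out


def copy_numbers(genomes: list[CircularGenome]) -> pd.DataFrame:
    """Per-gene copy counts across genomes (parts merged, D-labels split)."""
    data = {}
    for g in genomes:
        data[g.id] = {name: len(copies) for name, copies in gene_copies(g).items()}
    df = pd.DataFrame(data).fillna(0).astype(int)
    return df.sort_index()


def intersect_candidates(polymorphic_sets) -> list[str]:
    """Base gene names polymorphic in every cultivar.

    Accepts an iterable whose items are either iterables of gene names or
    lists of PolymorphismRecord (filtered to those with events).
    """
    sets = []
    for item in polymorphic_sets:
        if item and isinstance(next(iter(item), None), PolymorphismRecord):
            sets.append({r.gene for r in item if r.polymorphic})
        else:
            sets.append(set(item))
    if not sets:
        return []
    common = set.intersection(*sets)
    return sorted(common)
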