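"""Genome containers and standard-format I/O.

Coordinate contract used across the whole package: positions are 0-based,
half-open, on the forward strand. 1-based closed conventions (GenBank, GFF3)
are converted at the I/O boundary only.

Circular topology: features that span the replication origin in an ingested
record are eliminated by rotating the genome so that every feature is
contiguous; the applied offset is kept on the genome (``rotation_offset``)
so the original frame can be restored on output.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC_EXTRA = set("RYSWKMBDHV")

#: Base names of the mitochondrial gene inventory conserved across the
#: tobacco lines this package targets. Used only as a guard so that gene
#: names that happen to end in a lowercase letter (cob, trnM, ...) are never
#: mis-split into base + exon-part suffix.
GENE_INVENTORY = frozenset(
    [
        "atp1", "atp4", "atp6", "atp8", "atp9",
        "ccmB", "ccmC", "ccmFC", "ccmFN",
        "cob", "cox1", "cox2", "cox3",
        "mat-R", "mttB", "orfB",
        "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
        "rpl2", "rpl5", "rpl16",
        "rps1", "rps3", "rps4", "rps10", "rps12", "rps13", "rps14", "rps19",
        "sdh3", "sdh4",
        "rrn5", "rrn18", "rrn26",
    ]
)

_COPY_RE = re.compile(r"^(?P<base>.+?)-(?P<copy>D\d+)$")
_PART_RE = re.compile(r"^(?P<base>.*?(?:\d|[A-Z]))(?P<part>[a-e]{1,4})$")


def split_gene_name(name: str) -> tuple[str, str | None]:
    """Split an annotated gene label into (base name, part/copy suffix).

    Trailing lowercase letters a-e mark trans-spliced exon groups
    (``nad2a``, ``cox2ab``); ``-D<k>`` marks an additional gene copy
    (``nad3-D2``). Labels that are themselves inventory names (``cob``,
    ``trnM``) are never split.

    >>> split_gene_name("nad2ab")
    ('nad2', 'ab')
    >>> split_gene_name("cob")
    ('cob', None)
    >>> split_gene_name("nad3-D2")
    ('nad3', 'D2')
    """
    if name in GENE_INVENTORY or name.startswith("trn") or name.startswith("orf"):
        m = _COPY_RE.match(name)
        if m and m.group("base") in GENE_INVENTORY:
            return m.group("base"), m.group("copy")
        return name, None
    m = _COPY_RE.match(name)
    if m:
        base, copy = m.group("base"), m.group("copy")
        inner_base, part = split_gene_name(base)
        # "-D2" on a part-suffixed label is not expected; keep copy label.
        return inner_base, copy if part is None else part + "-" + copy
    m = _PART_RE.match(name)
    if m and (m.group("base") in GENE_INVENTORY or len(m.group("base")) >= 3):
        return m.group("base"), m.group("part")
    return name, None


def is_copy_label(suffix: str | None) -> bool:
    """True if a part_suffix denotes an extra gene copy rather than an exon."""
    return suffix is not None and re.fullmatch(r"D\d+", suffix) is not None


@dataclass
class GeneFeature:
    """A gene-level annotation on the forward coordinate frame.

    ``start``/``end`` are 0-based half-open. ``part_suffix`` holds a
    trans-spliced exon label ("a".."e" groups) or a "D<k>" copy label;
    comparisons across genomes are made on ``name`` (the base name).
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "protein"  # protein | tRNA | rRNA | orf
    part_suffix: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if self.part_suffix and self.name in self.part_suffix:
            raise ValueError("part_suffix must not contain the base name")
        if self.start >= self.end:
            raise ValueError(f"empty/inverted feature interval for {self.name}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def full_name(self) -> str:
        if self.part_suffix is None:
            return self.name
        if is_copy_label(self.part_suffix):
            return f"{self.name}-{self.part_suffix}"
        return f"{self.name}{self.part_suffix}"

    @property
    def length(self) -> int:
        return self.end - self.start


def _clean_seq(seq: str, label: str) -> str:
    s = seq.upper()
    bad = set(s) - _DNA
    if bad:
        if bad <= _IUPAC_EXTRA:
            warnings.warn(
                f"record {label}: ambiguity codes {sorted(bad)} converted to N"
            )
            s = re.sub("[" + "".join(sorted(_IUPAC_EXTRA)) + "]", "N", s)
        else:
            raise ValueError(
                f"record {label}: non-DNA characters {sorted(bad - _IUPAC_EXTRA)}"
            )
    return s


@dataclass
class CircularGenome:
    """A (usually circular) DNA sequence with attached gene annotations."""

    id: str
    seq: str
    circular: bool = True
    genes: list[GeneFeature] = field(default_factory=list)
    rotation_offset: int = 0  # bp the ingested record was rotated by on read

    def __post_init__(self) -> None:
        self.seq = _clean_seq(self.seq, self.id)
        if len(self.seq) == 0:
            raise ValueError(f"genome {self.id} has empty sequence")
        for g in self.genes:
            if not (0 <= g.start < g.end <= len(self.seq)):
                raise ValueError(
                    f"feature {g.full_name} outside genome {self.id} bounds"
                )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def feature_seq(self, feat: GeneFeature) -> str:
        s = self.seq[feat.start : feat.end]
        return revcomp(s) if feat.strand == "-" else s


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(genome_or_seq: CircularGenome | str) -> float:
    """(G+C)/(A+C+G+T); N is excluded from the denominator.

    Raises ValueError on an all-N sequence (undefined).
    """
    seq = genome_or_seq.seq if isinstance(genome_or_seq, CircularGenome) else genome_or_seq
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / denom


def rotate(genome: CircularGenome, new_origin: int) -> CircularGenome:
    """Return the genome re-linearized to start at ``new_origin``.

    Feature coordinates are remapped; a feature that would span the new
    origin keeps its contiguity because rotation is only applied at points
    outside every feature — if a feature would be cut, ValueError is raised.
    """
    if not genome.circular:
        raise ValueError("cannot rotate a linear genome")
    n = genome.length
    if not 0 <= new_origin < n:
        raise ValueError("new_origin out of range")
    if new_origin == 0:
        return genome
    for g in genome.genes:
        if g.start < new_origin < g.end:
            raise ValueError(
                f"rotation point {new_origin} cuts feature {g.full_name}"
            )
    seq = genome.seq[new_origin:] + genome.seq[:new_origin]
    genes = [
        replace(
            g,
            start=(g.start - new_origin) % n,
            end=(g.end - new_origin - 1) % n + 1,
        )
        for g in genome.genes
    ]
    return CircularGenome(
        id=genome.id,
        seq=seq,
        circular=True,
        genes=sorted(genes, key=lambda g: g.start),
        rotation_offset=(genome.rotation_offset + new_origin) % n,
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, circular: bool = True) -> list[CircularGenome]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    return [CircularGenome(id=r.id, seq=str(r.seq), circular=circular) for r in records]


def write_fasta(genomes: list[CircularGenome] | CircularGenome, path, width: int = 70) -> None:
    if isinstance(genomes, CircularGenome):
        genomes = [genomes]
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GB_KIND = {"CDS": "protein", "gene": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path) -> CircularGenome:
    """Read one annotated GenBank flat record.

    Gene features are taken from CDS/tRNA/rRNA entries (falling back to
    ``gene`` entries not covered by one of those). An origin-spanning
    (compound, wrap-around) feature triggers a rotation of the whole genome
    so that every feature becomes contiguous.
    """
    record = SeqIO.read(str(path), "genbank")
    if len(record.seq) == 0:
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence")
    circular = record.annotations.get("topology", "linear") == "circular"
    n = len(record.seq)

    wrap_rotation = None
    feats = []
    for f in record.features:
        if f.type not in _GB_KIND:
            continue
        name = (
            f.qualifiers.get("gene", [None])[0]
            or f.qualifiers.get("locus_tag", [None])[0]
            or f.qualifiers.get("product", ["unknown"])[0]
        )
        parts = f.location.parts
        span = sum(len(p) for p in parts)
        start, end = int(f.location.start), int(f.location.end)
        wrap_start = None
        if len(parts) > 1 and end - start > span:
            # compound location running across the origin
            if not circular:
                raise ValueError(f"{path}: feature {name} outside sequence bounds")
            wrap_start = int(parts[0].start)
            if wrap_rotation is None:
                wrap_rotation = wrap_start
        elif not (0 <= start < end <= n):
            raise ValueError(f"{path}: feature {name} outside sequence bounds")
        strand = "-" if f.location.strand == -1 else "+"
        kind = _GB_KIND[f.type]
        if name.startswith(("trn", "tRNA")):
            kind = "tRNA"
        elif name.startswith(("rrn", "rRNA")):
            kind = "rRNA"
        elif name.startswith("orf"):
            kind = "orf"
        feats.append((name, start, end, strand, kind, span, wrap_start))

    genome = CircularGenome(id=record.id or record.name, seq=str(record.seq), circular=circular)
    rot = wrap_rotation or 0
    if rot:
        genome = CircularGenome(
            id=genome.id,
            seq=genome.seq[rot:] + genome.seq[:rot],
            circular=True,
            rotation_offset=rot,
        )
    genes = []
    for name, start, end, strand, kind, span, wrap_start in feats:
        base, part = split_gene_name(name)
        if wrap_start is not None:
            new_start = (wrap_start - rot) % n
            if new_start + span > n:
                raise ValueError(
                    f"{path}: cannot linearize several origin-spanning features"
                )
            genes.append(GeneFeature(base, new_start, new_start + span, strand, kind, part))
        else:
            genes.append(
                GeneFeature(
                    base,
                    (start - rot) % n,
                    (end - rot - 1) % n + 1,
                    strand,
                    kind,
                    part,
                )
            )
    # de-duplicate gene/CDS double annotation of the same locus
    seen: set[tuple] = set()
    uniq = []
    for g in sorted(genes, key=lambda g: (g.start, g.end)):
        key = (g.name, g.part_suffix, g.start, g.end, g.strand)
        if key not in seen:
            seen.add(key)
            uniq.append(g)
    genome.genes = uniq
    return genome


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

_GFF_TYPE = {"protein": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "orf": "ORF"}
_GFF_KIND = {v: k for k, v in _GFF_TYPE.items()}


def write_gff3(genome: CircularGenome, path) -> None:
    """Write gene annotations as GFF3 (1-based closed at the boundary)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for g in sorted(genome.genes, key=lambda g: g.start):
            attrs = f"ID={g.full_name};Name={g.name}"
            if g.part_suffix:
                attrs += f";part={g.part_suffix}"
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "mitocompare",
                        _GFF_TYPE[g.kind],
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            _, _, ftype, start, end, _, strand, _, attrs = cols
            attrd = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            ident = attrd.get("ID") or attrd.get("Name", "unknown")
            base, part = split_gene_name(ident)
            if "Name" in attrd:
                base = attrd["Name"]
            if "part" in attrd:
                part = attrd["part"]
            feats.append(
                GeneFeature(
                    name=base,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    kind=_GFF_KIND.get(ftype, "protein"),
                    part_suffix=part,
                )
            )
    return feats


def attach_gff3(genome: CircularGenome, path) -> CircularGenome:
    genome.genes = sorted(read_gff3(path), key=lambda g: g.start)
    # re-validate bounds
    return CircularGenome(
        id=genome.id,
        seq=genome.seq,
        circular=genome.circular,
        genes=genome.genes,
        rotation_offset=genome.rotation_offset,
    )


def write_bed(intervals, path, genome_id: str | None = None) -> None:
    """Write (chrom, start, end, name[, score, strand]) rows as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
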