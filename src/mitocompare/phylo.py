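"""Character matrices and tree inference.

Two matrix sources mirror the two comparisons the pipeline makes:
whole-genome SNP columns called against a reference through synteny-block
alignments (concatenated in reference order), and concatenated candidate
genes. Trees are inferred by Fitch maximum parsimony (exhaustive topology
search up to a cap, NNI hill-climbing beyond) and by p-distance
neighbor-joining; node supports come from nonparametric bootstrap over
matrix columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from mitocompare.genome_io import CircularGenome
from mitocompare.synteny import build_synteny_blocks

_STATE = {"A": 1, "C": 2, "G": 4, "T": 8, "-": 15, "?": 15, "N": 15}


@dataclass
class CharacterMatrix:
    """Aligned per-taxon character strings over {A,C,G,T,-,?}."""

    taxa: list[str]
    rows: dict[str, str]
    source: str = "snp_concat"  # snp_concat | gene_concat

    def __post_init__(self) -> None:
        lens = {len(self.rows[t]) for t in self.taxa}
        if len(lens) > 1:
            raise ValueError("rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.taxa[0]]) if self.taxa else 0

    def state_array(self) -> np.ndarray:
        """(n_taxa, n_columns) Fitch state-set array (uint8 bitmasks)."""
        arr = np.empty((len(self.taxa), self.n_columns), np.uint8)
        for i, t in enumerate(self.taxa):
            arr[i] = [_STATE.get(c, 15) for c in self.rows[t]]
        return arr

    def subsample_columns(self, idx: np.ndarray) -> "CharacterMatrix":
        rows = {t: "".join(self.rows[t][j] for j in idx) for t in self.taxa}
        return CharacterMatrix(list(self.taxa), rows, self.source)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """An unrooted tree over a taxon set.

    ``topology`` is a nested-tuple encoding rooted at the first taxon's
    pendant edge: (0, R) where R recursively is a leaf index or a pair.
    ``supports`` maps bipartitions — frozensets of taxon names on the side
    away from the first taxon — to bootstrap percentages.
    """

    taxa: list[str]
    topology: tuple | None = None
    newick: str = ""
    supports: dict[frozenset, float] = field(default_factory=dict)
    branch_lengths: bool = False
    score: float | None = None
    ties: list[tuple] = field(default_factory=list)

    def splits(self) -> set[frozenset]:
        if self.topology is None:
            raise ValueError("no topology stored")
        out: set[frozenset] = set()

        def leafset(node):
            if isinstance(node, int):
                return {node}
            s = set()
            for ch in node:
                s |= leafset(ch)
            return s

        def walk(node):
            if isinstance(node, int):
                return
            for ch in node:
                ls = leafset(ch)
                if 1 < len(ls) < len(self.taxa) - 1:
                    out.add(frozenset(self.taxa[i] for i in ls))
                walk(ch)

        walk(self.topology[1])
        return out

    def separates(self, group) -> bool:
        """True if the tree contains the bipartition group | rest."""
        g = frozenset(group)
        comp = frozenset(self.taxa) - g
        if len(g) < 2 or len(comp) < 2:
            return True  # trivial split, always present
        first = self.taxa[0]
        side = comp if first in g else g
        return side in self.splits()

    def to_newick(self, with_supports: bool = False) -> str:
        if self.topology is None:
            return self.newick

        def leafset(node):
            if isinstance(node, int):
                return {node}
            return leafset(node[0]) | leafset(node[1])

        def nwk(node):
            if isinstance(node, int):
                return self.taxa[node]
            s = f"({nwk(node[0])},{nwk(node[1])})"
            if with_supports:
                ls = leafset(node)
                key = frozenset(self.taxa[i] for i in ls)
                if key in self.supports:
                    s += f"{self.supports[key]:.0f}"
            return s
        r = self.topology[1]
        if isinstance(r, int):
            return f"({self.taxa[0]},{self.taxa[r]});"
        return f"({self.taxa[0]},{nwk(r[0])},{nwk(r[1])});"


def _canonical(node):
    if isinstance(node, int):
        return node
    a = _canonical(node[0])
    b = _canonical(node[1])
    return (a, b) if str(a) <= str(b) else (b, a)


def enumerate_rooted(taxa: list[int]):
    """All rooted binary tree shapes over the taxon indices (tuples)."""
    if len(taxa) == 1:
        yield taxa[0]
        return
    for sub in enumerate_rooted(taxa[:-1]):
        yield from _insert_everywhere(sub, taxa[-1])


def _insert_everywhere(tree, x):
    yield (tree, x)
    if not isinstance(tree, int):
        l, r = tree
        for nl in _insert_everywhere(l, x):
            yield (nl, r)
        for nr in _insert_everywhere(r, x):
            yield (l, nr)


def _collapse_columns(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique column patterns and their multiplicities."""
    cols = arr.T.copy()
    uniq, counts = np.unique(cols, axis=0, return_counts=True)
    return uniq.T.copy(), counts


def _fitch_changes(topology, arr: np.ndarray, weights: np.ndarray) -> int:
    """Weighted Fitch small-parsimony count over all columns at once."""
    changes = np.zeros(arr.shape[1], np.int64)

    def down(node) -> np.ndarray:
        if isinstance(node, int):
            return arr[node]
        s1 = down(node[0])
        s2 = down(node[1])
        inter = s1 & s2
        empty = inter == 0
        changes[empty] += 1
        return np.where(empty, s1 | s2, inter)

    root_child = down(topology[1]) if not isinstance(topology[1], int) else arr[topology[1]]
    s0 = arr[topology[0]]
    inter = s0 & root_child
    changes[inter == 0] += 1
    return int((changes * weights).sum())


def parsimony_score(tree: Tree | tuple, matrix: CharacterMatrix) -> int:
    """Sum over columns of Fitch state changes; '-'/'?' are missing."""
    topology = tree.topology if isinstance(tree, Tree) else tree
    if topology is None:
        raise ValueError("tree has no explicit topology")
    if isinstance(tree, Tree) and set(tree.taxa) != set(matrix.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    if isinstance(tree, Tree) and tree.taxa != matrix.taxa:
        # re-index the topology onto the matrix taxon order
        remap = {i: matrix.taxa.index(t) for i, t in enumerate(tree.taxa)}

        def rm(node):
            return remap[node] if isinstance(node, int) else (rm(node[0]), rm(node[1]))

        topology = (rm(topology[0]), rm(topology[1]))
    arr, weights = _collapse_columns(matrix.state_array())
    return _fitch_changes(topology, arr, weights)


def _all_topologies(n: int):
    for shape in enumerate_rooted(list(range(1, n))):
        yield (0, shape)


def build_mp_tree(matrix: CharacterMatrix, exhaustive_cap: int = 9) -> Tree:
    """Maximum-parsimony tree (exhaustive search up to ``exhaustive_cap``
    taxa, NNI hill-climbing from the NJ topology beyond). Ties are all
    recorded; the canonically first topology is returned as primary."""
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    arr, weights = _collapse_columns(matrix.state_array())
    if n <= exhaustive_cap:
        best_score = None
        best: list[tuple] = []
        for topo in _all_topologies(n):
            s = _fitch_changes(topo, arr, weights)
            if best_score is None or s < best_score:
                best_score = s
                best = [topo]
            elif s == best_score:
                best.append(topo)
        canon = sorted(best, key=lambda t: str(_canonical(t)))
        primary = canon[0]
        return Tree(
            taxa=list(matrix.taxa), topology=primary,
            score=best_score, ties=canon[1:],
        )
    # NNI hill-climb from the NJ topology
    current = nj_tree(matrix).topology
    if current is None:
        raise RuntimeError("NJ starting topology unavailable")
    cur_score = _fitch_changes(current, arr, weights)
    improved = True
    while improved:
        improved = False
        for nb in _nni_neighbors(current):
            s = _fitch_changes(nb, arr, weights)
            if s < cur_score:
                current, cur_score = nb, s
                improved = True
                break
    return Tree(taxa=list(matrix.taxa), topology=current, score=cur_score)


def _nni_neighbors(topology):
    """Nearest-neighbor interchanges of a (leaf0-rooted) topology."""
    def rebuild(node, path, repl):
        if not path:
            return repl
        l, r = node
        if path[0] == 0:
            return (rebuild(l, path[1:], repl), r)
        return (l, rebuild(r, path[1:], repl))

    out = []
    root = topology[1]

    def rebuild_root(path, repl):
        return (0, rebuild(root, path, repl))

    def walk(node, path):
        if isinstance(node, int):
            return
        l, r = node
        # each non-leaf child defines an internal edge; swap one grandchild
        # across it with the sibling subtree
        if not isinstance(l, int):
            a, b = l
            out.append(rebuild_root(path, ((a, r), b)))
            out.append(rebuild_root(path, ((b, r), a)))
        if not isinstance(r, int):
            a, b = r
            out.append(rebuild_root(path, (b, (a, l))))
            out.append(rebuild_root(path, (a, (b, l))))
        walk(l, path + [0])
        walk(r, path + [1])

    if isinstance(root, int):
        return []
    walk(root, [])
    return out


def p_distance(matrix: CharacterMatrix) -> np.ndarray:
    """Pairwise mismatch fraction over comparable (unambiguous) sites."""
    arr = matrix.state_array()
    n = len(matrix.taxa)
    good = (arr != 15) & (arr != 0)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = good[i] & good[j]
        nb = int(both.sum())
        if nb == 0:
            raise ValueError(
                f"taxa {matrix.taxa[i]}/{matrix.taxa[j]}: no comparable sites"
            )
        mism = int((arr[i][both] != arr[j][both]).sum())
        d[i, j] = d[j, i] = mism / nb
    return d


def nj_tree(matrix: CharacterMatrix) -> Tree:
    """p-distance neighbor-joining (deterministic; negative branch
    lengths clamped to zero)."""
    if len(matrix.taxa) < 3:
        raise ValueError("need >= 3 taxa")
    dm = DistanceMatrix(p_distance(matrix), ids=matrix.taxa)
    t = _skbio_nj(dm)
    clamped = False
    for node in t.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0")
    topo = _skbio_to_topology(t, matrix.taxa)
    return Tree(
        taxa=list(matrix.taxa), topology=topo, newick=str(t).strip(),
        branch_lengths=True,
    )


def _skbio_to_topology(t, taxa: list[str]):
    """Convert an skbio TreeNode to the leaf0-rooted nested-tuple form."""
    index = {name: i for i, name in enumerate(taxa)}
    t = t.copy()
    # root at the first taxon's pendant edge
    first = t.find(taxa[0])
    t = t.root_at(first.parent) if first.parent is not None else t

    def conv(node):
        if node.is_tip():
            return index[node.name]
        kids = [conv(c) for c in node.children]
        cur = kids[0]
        for k in kids[1:]:
            cur = (cur, k)
        return cur

    # children of root excluding the first taxon
    others = [c for c in t.children if not (c.is_tip() and c.name == taxa[0])]
    sub = [conv(c) for c in others]
    cur = sub[0]
    for k in sub[1:]:
        cur = (cur, k)
    return (index[taxa[0]], cur)


def bootstrap_support(
    matrix: CharacterMatrix,
    method: str = "mp",
    n_reps: int = 1000,
    seed: int = 0,
) -> Tree:
    """Column bootstrap; supports = % of replicate trees containing each
    internal bipartition of the primary tree."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if method not in ("mp", "nj"):
        raise ValueError("method must be 'mp' or 'nj'")
    build = build_mp_tree if method == "mp" else nj_tree
    primary = build(matrix)
    target_splits = primary.splits()
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    ncol = matrix.n_columns
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rep = build(matrix.subsample_columns(idx))
        rep_splits = rep.splits()
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
    primary.supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return primary


# ---------------------------------------------------------------------------
# SNP matrix from synteny alignments
# ---------------------------------------------------------------------------

def _fill_alleles(sample: CircularGenome, reference: CircularGenome, blocks) -> np.ndarray:
    from mitocompare._sw import OP_D, OP_EQ, OP_I, OP_X
    from mitocompare.genome_io import revcomp

    L = reference.length
    alleles = np.full(L, "?", dtype="U1")
    bseq = sample.seq
    for blk in blocks:
        # a reference-only gap between consecutive block segments is a
        # deletion in the sample (too long for the banded aligner to bridge)
        segs = sorted(blk.segments, key=lambda s: s.q_start)
        for prev, nxt in zip(segs, segs[1:]):
            ref_gap = nxt.q_start - prev.q_end
            if prev.orientation == "forward":
                s_gap = nxt.s_start - prev.s_end
            else:
                s_gap = prev.s_start - nxt.s_end
            if ref_gap > 0 and s_gap <= 5:
                alleles[prev.q_end : nxt.q_start] = "-"
        for seg in blk.segments:
            if seg.ops is None:
                continue
            rp = seg.q_start
            if seg.orientation == "forward":
                walk = bseq[seg.s_start : seg.s_end]
            else:
                walk = revcomp(bseq[seg.s_start : seg.s_end])
            sp = 0
            for op in seg.ops:
                if op == OP_EQ or op == OP_X:
                    alleles[rp] = walk[sp]
                    rp += 1
                    sp += 1
                elif op == OP_D:
                    alleles[rp] = "-"
                    rp += 1
                else:  # OP_I
                    sp += 1
    return alleles


def snp_matrix(
    samples: list[CircularGenome],
    reference: CircularGenome,
    min_align_frac: float = 0.10,
    blocks_by_sample: dict | None = None,
    **block_kwargs,
) -> CharacterMatrix:
    """Whole-genome SNP columns versus a reference, concatenated in
    reference order; sample deletions appear as '-'.

    A column is emitted for every reference position covered in all
    retained samples where at least one state differs; the reference is
    included as a taxon. Samples aligning over less than
    ``min_align_frac`` of the reference are excluded with a warning.
    """
    kept = []
    allele_rows = []
    for s in samples:
        if blocks_by_sample is not None and s.id in blocks_by_sample:
            blocks = blocks_by_sample[s.id]
        else:
            blocks = build_synteny_blocks(reference, s, **block_kwargs)
        alleles = _fill_alleles(s, reference, blocks)
        frac = float((alleles != "?").mean())
        if frac < min_align_frac:
            warnings.warn(f"sample {s.id}: only {frac:.1%} alignable; excluded")
            continue
        kept.append(s.id)
        allele_rows.append(alleles)
    if not kept:
        raise ValueError("no sample passed the alignable-fraction filter")
    A = np.vstack(allele_rows)
    ref_arr = np.frombuffer(reference.seq.encode(), dtype="S1").astype("U1")
    covered = (A != "?").all(axis=0)
    differs = (A != ref_arr[None, :]).any(axis=0)
    cols = np.nonzero(covered & differs)[0]
    rows = {gid: "".join(A[i, cols]) for i, gid in enumerate(kept)}
    rows[reference.id] = "".join(ref_arr[cols])
    return CharacterMatrix(
        taxa=kept + [reference.id], rows=rows, source="snp_concat"
    )


def gene_concat_matrix(
    sequences_per_taxon: dict[str, dict[str, str]],
    genes: list[str] | None = None,
) -> CharacterMatrix:
    """Concatenated per-gene alignment across taxa (MAFFT-free: genes are
    pairwise-anchored on the first taxon via global alignment columns).

    ``sequences_per_taxon``: taxon -> {gene -> CDS}. Genes missing in any
    taxon are skipped. Indel columns carry '-' states.
    """
    from mitocompare.genes import _alignment_ops

    taxa = list(sequences_per_taxon)
    if genes is None:
        genes = sorted(set.intersection(*(set(v) for v in sequences_per_taxon.values())))
    rows = {t: [] for t in taxa}
    anchor_taxon = taxa[0]
    for gene in genes:
        anchor = sequences_per_taxon[anchor_taxon][gene]
        # per-taxon alignment to the anchor, then projected on anchor columns
        per_taxon_cols = {}
        max_ins_after = [0] * (len(anchor) + 1)
        aligned = {}
        for t in taxa:
            seq = sequences_per_taxon[t][gene]
            cols = []  # (anchor_pos or -1, char)
            ap = 0
            bp = 0
            ins_run = {}
            for num, op in _alignment_ops(anchor, seq):
                if op in ("=", "X"):
                    for u in range(num):
                        cols.append((ap, seq[bp]))
                        ap += 1
                        bp += 1
                elif op == "D":
                    for u in range(num):
                        cols.append((ap, "-"))
                        ap += 1
                else:
                    ins_run[ap] = seq[bp : bp + num]
                    bp += num
            aligned[t] = (cols, ins_run)
            for pos, insseq in ins_run.items():
                max_ins_after[pos] = max(max_ins_after[pos], len(insseq))
        for t in taxa:
            cols, ins_run = aligned[t]
            out = []
            byp = {p: c for p, c in cols}
            for p in range(len(anchor) + 1):
                ins = ins_run.get(p, "")
                out.append(ins + "-" * (max_ins_after[p] - len(ins)))
                if p < len(anchor):
                    out.append(byp.get(p, "-"))
            rows[t].append("".join(out))
    return CharacterMatrix(
        taxa=taxa, rows={t: "".join(v) for t, v in rows.items()},
        source="gene_concat",
    )
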