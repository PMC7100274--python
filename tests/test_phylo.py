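from itertools import product

import numpy as np
import pytest

from mitocompare.phylo import (
    CharacterMatrix,
    Tree,
    bootstrap_support,
    build_mp_tree,
    enumerate_rooted,
    gene_concat_matrix,
    nj_tree,
    p_distance,
    parsimony_score,
    snp_matrix,
)
from mitocompare.genome_io import CircularGenome
from tests.conftest import random_dna


def exhaustive_parsimony(topology, taxa_states):
    """Independent oracle: minimize changes over all ancestral labelings."""
    nodes = []

    def collect(n):
        if isinstance(n, int):
            return n
        l = collect(n[0])
        r = collect(n[1])
        nodes.append((len(nodes), l, r))
        return ("i", len(nodes) - 1)

    root_child = collect(topology[1])
    best = None
    states = "ACGT"
    for assign in product(states, repeat=len(nodes)):
        def val(ref):
            if isinstance(ref, int):
                return taxa_states[ref]
            return assign[ref[1]]

        cost = 0
        for i, l, r in nodes:
            for ch in (l, r):
                v = val(ch)
                if v not in ("-", "?") and v != assign[i]:
                    cost += 1
        top = val(root_child)
        leaf0 = taxa_states[topology[0]]
        if leaf0 not in ("-", "?") and top not in ("-", "?") and leaf0 != top:
            cost += 1
        if isinstance(root_child, int) and leaf0 not in ("-", "?"):
            cost = 0 if leaf0 == top or top in ("-", "?") else 1
        if best is None or cost < best:
            best = cost
    return best


class TestParsimonyScore:
    def test_hand_checked_quartet_columns(self):
        mat = CharacterMatrix(["a1", "a2", "c1", "c2"],
                              {"a1": "A", "a2": "A", "c1": "C", "c2": "C"})
        good = Tree(["a1", "a2", "c1", "c2"], topology=(0, (1, (2, 3))))
        bad = Tree(["a1", "c1", "a2", "c2"], topology=(0, (1, (2, 3))))
        assert parsimony_score(good, mat) == 1
        assert parsimony_score(bad, mat) == 2

    def test_constant_column_contributes_zero(self):
        mat = CharacterMatrix(list("abcd"), {t: "G" for t in "abcd"})
        t = Tree(list("abcd"), topology=(0, (1, (2, 3))))
        assert parsimony_score(t, mat) == 0

    def test_missing_states_free(self):
        mat = CharacterMatrix(list("abcd"), {"a": "A", "b": "?", "c": "-", "d": "C"})
        t = Tree(list("abcd"), topology=(0, (1, (2, 3))))
        assert parsimony_score(t, mat) == 1

    def test_matches_exhaustive_enumeration_on_small_trees(self):
        rng = np.random.default_rng(3)
        for n in (4, 5, 6):
            taxa = [f"t{i}" for i in range(n)]
            shapes = list(enumerate_rooted(list(range(1, n))))
            for _ in range(8):
                topo = (0, shapes[rng.integers(len(shapes))])
                col = "".join(rng.choice(list("ACGT-?"), n))
                mat = CharacterMatrix(taxa, dict(zip(taxa, col)))
                assert parsimony_score(Tree(taxa, topology=topo), mat) == \
                    exhaustive_parsimony(topo, col)

    def test_taxa_mismatch_rejected(self):
        mat = CharacterMatrix(list("abc"), {t: "A" for t in "abc"})
        with pytest.raises(ValueError):
            parsimony_score(Tree(list("abd"), topology=(0, (1, 2))), mat)


class TestBuildMpTree:
    def test_single_informative_split(self):
        mat = CharacterMatrix(["A1", "A2", "C1", "C2"],
                              {"A1": "AAA", "A2": "AAA", "C1": "CCC", "C2": "CCC"})
        t = build_mp_tree(mat)
        assert t.separates({"C1", "C2"}) and t.score == 3

    def test_majority_signal_wins(self):
        rows = {"a": "AAAC", "b": "AAAA", "c": "CCCA", "d": "CCCC"}
        t = build_mp_tree(CharacterMatrix(list("abcd"), rows))
        assert t.separates({"a", "b"})  # 3 columns vs 1

    def test_is_globally_optimal_at_six_taxa(self):
        rng = np.random.default_rng(9)
        taxa = [f"t{i}" for i in range(6)]
        rows = {t: "".join(rng.choice(list("ACGT"), 30)) for t in taxa}
        mat = CharacterMatrix(taxa, rows)
        best = build_mp_tree(mat)
        for shape in enumerate_rooted(list(range(1, 6))):
            alt = Tree(taxa, topology=(0, shape))
            assert best.score <= parsimony_score(alt, mat)

    def test_recovers_generating_topology(self):
        rng = np.random.default_rng(0)
        taxa = ["a1", "a2", "b1", "b2", "c1", "c2"]
        groups = [{0, 1}, {2, 3}, {4, 5}]
        rows = {t: "" for t in taxa}
        for _ in range(200):
            grp = groups[rng.integers(3)]
            for i, t in enumerate(taxa):
                rows[t] += "C" if i in grp else "A"
        t = build_mp_tree(CharacterMatrix(taxa, rows))
        assert t.separates({"a1", "a2"}) and t.separates({"b1", "b2"}) \
            and t.separates({"c1", "c2"})


class TestNjTree:
    def test_additive_quartet_recovered(self):
        # characters engineered so p-distances are additive on ((a,b),(c,d))
        rows = {
            "a": "AAAAAAAAAA" + "GG",
            "b": "AAAAAAAAAC" + "GG",
            "c": "CCCCCAAAAA" + "TT",
            "d": "CCCCCAAAAC" + "TT",
        }
        t = nj_tree(CharacterMatrix(list("abcd"), rows))
        assert t.separates({"c", "d"})

    def test_label_permutation_invariance(self):
        rows = {"a": "AAAA", "b": "AAAC", "c": "CCCA", "d": "CCCC"}
        t1 = nj_tree(CharacterMatrix(list("abcd"), rows))
        order = ["c", "a", "d", "b"]
        t2 = nj_tree(CharacterMatrix(order, rows))
        def norm(tree):
            return {frozenset(s) if "a" not in s else frozenset(set(rows) - s)
                    for s in tree.splits()}
        assert norm(t1) == norm(t2)

    def test_zero_comparable_sites_error(self):
        rows = {"a": "A?", "b": "?C", "c": "AC"}
        with pytest.raises(ValueError):
            p_distance(CharacterMatrix(list("abc"), rows))


class TestBootstrap:
    def test_perfect_split_full_support(self):
        mat = CharacterMatrix(["A1", "A2", "C1", "C2"],
                              {"A1": "AAAA", "A2": "AAAA", "C1": "CCCC", "C2": "CCCC"})
        t = bootstrap_support(mat, "mp", n_reps=100, seed=1)
        assert list(t.supports.values()) == [100.0]

    def test_balanced_conflict_near_fifty(self):
        rows = {"a": "A" * 20 + "A" * 20, "b": "A" * 20 + "C" * 20,
                "c": "C" * 20 + "A" * 20, "d": "C" * 20 + "C" * 20}
        t = bootstrap_support(CharacterMatrix(list("abcd"), rows), "mp",
                              n_reps=1000, seed=2)
        (sup,) = t.supports.values()
        assert 40 <= sup <= 60  # binomial tolerance around 50

    def test_invalid_args(self):
        mat = CharacterMatrix(list("abc"), {t: "A" for t in "abc"})
        with pytest.raises(ValueError):
            bootstrap_support(mat, "mp", n_reps=0)
        with pytest.raises(ValueError):
            bootstrap_support(mat, "ml")


class TestSnpMatrix:
    def _ref_and_samples(self, rng):
        ref = CircularGenome(id="REF", seq=random_dna(rng, 20_000))
        s = ref.seq
        pos = sorted(rng.choice(np.arange(1000, 19_000), 50, replace=False))
        def mutate(positions):
            x = list(s)
            for p in positions:
                x[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[x[p]]
            return "".join(x)
        a = CircularGenome(id="a", seq=mutate(pos[:30]))
        b = CircularGenome(id="b", seq=mutate(pos[20:]))
        return ref, a, b, pos

    def test_identical_samples_zero_columns(self, rng):
        ref = CircularGenome(id="REF", seq=random_dna(rng, 20_000))
        a = CircularGenome(id="a", seq=ref.seq)
        mat = snp_matrix([a], ref)
        assert mat.n_columns == 0

    def test_planted_snp_union(self, rng):
        ref, a, b, pos = self._ref_and_samples(rng)
        mat = snp_matrix([a, b], ref)
        assert mat.n_columns == len(pos)  # union of variant positions
        assert mat.taxa == ["a", "b", "REF"]

    def test_deletion_becomes_gap_state(self, rng):
        ref = CircularGenome(id="REF", seq=random_dna(rng, 20_000))
        a = CircularGenome(id="a", seq=ref.seq[:5_000] + ref.seq[5_100:])
        mat = snp_matrix([a], ref)
        assert "-" in mat.rows["a"]


def test_gene_concat_matrix_alignment_columns(rng):
    # one substitution + one 3 nt deletion across three taxa
    base = random_dna(rng, 300)
    seqs = {
        "m1": {"g": base},
        "c1": {"g": base[:100] + ("A" if base[100] != "A" else "C") + base[101:]},
        "c2": {"g": base[:200] + base[203:]},
    }
    mat = gene_concat_matrix(seqs, ["g"])
    assert mat.n_columns == 300
    col100 = {t: mat.rows[t][100] for t in mat.taxa}
    assert col100["m1"] != col100["c1"]
    assert mat.rows["c2"].count("-") == 3
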