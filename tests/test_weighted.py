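import numpy as np
import pytest

from corgias import (
    asa_correct,
    asa_counts,
    asa_decompose,
    cwa_counts,
    naive_counts,
    parse_newick,
    rle_counts,
)
from corgias.ancestral_parsimony import acctran_matrix, fitch_matrix
from corgias.phylo_io import UNCERTAIN
from corgias.weighted_methods import contingency_test, joint_code

from .conftest import random_binary_tree


def brute_force_tally(v1, v2):
    cells = {"11": 0, "10": 0, "01": 0, "00": 0}
    for a, b in zip(v1, v2):
        cells[f"{a}{b}"] += 1
    return cells["11"], cells["10"], cells["01"], cells["00"]


class TestNaive:
    def test_identical_profiles(self):
        assert naive_counts([1, 1, 0, 0], [1, 1, 0, 0]) == (2, 0, 0, 2)

    def test_complementary_profiles(self):
        assert naive_counts([1, 0, 1, 0], [0, 1, 0, 1]) == (0, 2, 2, 0)

    def test_random_pair_matches_loop_tally(self):
        rng = np.random.default_rng(3)
        v1 = rng.integers(0, 2, 50)
        v2 = rng.integers(0, 2, 50)
        assert naive_counts(v1, v2) == brute_force_tally(v1, v2)

    def test_cells_sum_to_genome_count(self):
        rng = np.random.default_rng(4)
        v1, v2 = rng.integers(0, 2, 37), rng.integers(0, 2, 37)
        assert sum(naive_counts(v1, v2)) == 37


class TestRLE:
    def test_hand_run_count(self):
        # ordered joint states [11, 11, 00, 00, 11]
        tree = parse_newick("((((A:1,B:1):1,C:1):1,D:1):1,E:1);")
        s = {"A": 1, "B": 1, "C": 0, "D": 0, "E": 1}
        assert rle_counts(tree, s, s) == (2, 0, 0, 1)

    def test_all_identical_one_run(self, quartet):
        s = {"A": 1, "B": 1, "C": 1, "D": 1}
        assert rle_counts(quartet, s, s) == (1, 0, 0, 0)

    def test_rotation_changes_counts_on_witness(self, six_leaf_witness):
        """Two '11' clades adjacent vs separated give different run counts."""
        s1 = {"A": 1, "B": 1, "C": 0, "D": 0, "E": 1, "F": 1}
        s2 = dict(s1)
        before = rle_counts(six_leaf_witness, s1, s2)
        rotated = six_leaf_witness.copy().rotate("N3")  # swap (C,D) / (E,F)
        after = rle_counts(rotated, s1, s2)
        assert before == (2, 0, 0, 1)
        assert after == (1, 0, 0, 1)
        assert before != after


class TestCWA:
    def test_hand_evaluation(self, quartet):
        s1 = {"A": 1, "B": 1, "C": 1, "D": 0}
        s2 = {"A": 1, "B": 1, "C": 0, "D": 0}
        assert cwa_counts(quartet, s1, s2) == (1, 1, 0, 1)

    def test_whole_tree_constant(self, quartet):
        s = {"A": 1, "B": 1, "C": 1, "D": 1}
        assert cwa_counts(quartet, s, s) == (1, 0, 0, 0)

    def test_paraphyletic_groups_not_merged(self, quartet):
        # A and D share 11 but straddle the root: two separate blocks
        s1 = {"A": 1, "B": 0, "C": 0, "D": 1}
        s2 = {"A": 1, "B": 0, "C": 0, "D": 1}
        assert cwa_counts(quartet, s1, s2) == (2, 0, 0, 2)

    def test_rotation_invariant(self):
        rng = np.random.default_rng(19)
        tree = random_binary_tree(rng, 20)
        v1 = {n.id: int(rng.integers(2)) for n in tree.leaves()}
        v2 = {n.id: int(rng.integers(2)) for n in tree.leaves()}
        baseline = cwa_counts(tree, v1, v2)
        work = tree.copy()
        internals = [n.id for n in work.internal_nodes()]
        for _ in range(30):
            work.rotate(str(rng.choice(internals)))
            assert cwa_counts(work, v1, v2) == baseline

    def test_compression_never_increases_cells(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            tree = random_binary_tree(rng, 15)
            v1 = {n.id: int(rng.integers(2)) for n in tree.leaves()}
            v2 = {n.id: int(rng.integers(2)) for n in tree.leaves()}
            names = tree.leaf_names()
            naive = naive_counts([v1[n] for n in names], [v2[n] for n in names])
            cwa = cwa_counts(tree, v1, v2)
            assert all(c <= n for c, n in zip(cwa, naive))


def _acctran_states(tree, profile_cols):
    arr = tree.arrays()
    cols = np.array([[profile_cols[0][n], profile_cols[1][n]] for n in arr.leaf_ids])
    masks, _ = fitch_matrix(arr, cols.astype(np.int8))
    states = acctran_matrix(arr, masks)
    s1 = {arr.node_ids[i]: int(states[i, 0]) for i in range(arr.n_nodes)}
    s2 = {arr.node_ids[i]: int(states[i, 1]) for i in range(arr.n_nodes)}
    return s1, s2


class TestASADecompose:
    def test_constant_tree_single_block(self, quartet):
        s = {n.id: 1 for n in quartet.postorder()}
        blocks = asa_decompose(quartet, s, s)
        assert len(blocks) == 1
        assert blocks[0].root_id == quartet.root.id
        assert sorted(blocks[0].leaves) == ["A", "B", "C", "D"]

    def test_uncertain_root_splits_in_two(self, quartet):
        s1 = {"A": 1, "B": 1, "L": 1, "C": 0, "D": 0, "R": 0}
        s1[quartet.root.id] = UNCERTAIN
        blocks = asa_decompose(quartet, s1, s1)
        sizes = sorted(b.M for b in blocks)
        assert sizes == [2, 2]
        assert {b.joint for b in blocks} == {"11", "00"}

    def test_divergent_leaf_is_singleton(self, quartet):
        s1 = {"A": 1, "B": 0, "L": 1, "C": 1, "D": 1, "R": 1}
        s1[quartet.root.id] = 1
        blocks = asa_decompose(quartet, s1, s1)
        by_leafset = {frozenset(b.leaves): b for b in blocks}
        singleton = by_leafset[frozenset({"B"})]
        assert singleton.M == 1
        assert asa_correct(singleton, quartet) == pytest.approx(1.0)

    def test_blocks_partition_leaves(self):
        rng = np.random.default_rng(47)
        for _ in range(10):
            tree = random_binary_tree(rng, 12)
            v1 = {n.id: int(rng.integers(2)) for n in tree.leaves()}
            v2 = {n.id: int(rng.integers(2)) for n in tree.leaves()}
            s1, s2 = _acctran_states(tree, (v1, v2))
            blocks = asa_decompose(tree, s1, s2)
            covered = [leaf for b in blocks for leaf in b.leaves]
            assert sorted(covered) == sorted(n.id for n in tree.leaves())
            assert sum(b.M for b in blocks) == 12


class TestASACorrect:
    def test_cherry_zero_stem(self):
        tree = parse_newick("((A:1,B:1)X:0,C:5);")
        s = {"A": 1, "B": 1, "X": 1, "C": 0}
        s[tree.root.id] = 0
        block = [b for b in asa_decompose(tree, s, s) if b.M == 2][0]
        assert asa_correct(block, tree) == pytest.approx(2.0)

    def test_cherry_unit_stem(self):
        tree = parse_newick("((A:1,B:1)X:1,C:5);")
        s = {"A": 1, "B": 1, "X": 1, "C": 0}
        s[tree.root.id] = 0
        block = [b for b in asa_decompose(tree, s, s) if b.M == 2][0]
        # Mc = 2 * (1+1+1) / (1*2 + 1 + 1) = 1.5
        assert asa_correct(block, tree) == pytest.approx(1.5)

    def test_stem_exclusion_flag(self):
        tree = parse_newick("((A:1,B:1)X:1,C:5);")
        s = {"A": 1, "B": 1, "X": 1, "C": 0}
        s[tree.root.id] = 0
        block = [b for b in asa_decompose(tree, s, s) if b.M == 2][0]
        assert asa_correct(block, tree, include_stem=False) == pytest.approx(2.0)

    def test_zero_length_block_falls_back_with_warning(self):
        tree = parse_newick("((A:0,B:0)X:0,C:5);")
        s = {"A": 1, "B": 1, "X": 1, "C": 0}
        s[tree.root.id] = 0
        block = [b for b in asa_decompose(tree, s, s) if b.M == 2][0]
        with pytest.warns(UserWarning, match="zero total branch length"):
            assert asa_correct(block, tree) == 2.0

    def test_scaling_internal_branches_decreases_mc(self):
        rng = np.random.default_rng(53)
        tree = random_binary_tree(rng, 10)
        s = {n.id: 1 for n in tree.postorder()}
        block = asa_decompose(tree, s, s)[0]
        base = asa_correct(block, tree)
        scaled = tree.copy()
        for node in scaled.postorder():
            if not node.is_leaf:
                node.length *= 3.0
        assert asa_correct(block, scaled) < base

    def test_uniform_scaling_leaves_mc_unchanged(self):
        rng = np.random.default_rng(59)
        tree = random_binary_tree(rng, 10)
        s = {n.id: 1 for n in tree.postorder()}
        block = asa_decompose(tree, s, s)[0]
        base = asa_correct(block, tree)
        scaled = tree.copy()
        for node in scaled.postorder():
            node.length *= 7.5
        assert asa_correct(block, scaled) == pytest.approx(base, rel=1e-12)


class TestASACounts:
    def test_ceiling_rule_arithmetic(self):
        # blocks summing to {11: 3.3, 10: 0.2, 00: 5.5} -> (4, 1, 0, 6)
        assert int(np.ceil(3.3)) == 4  # documents the rule the cells follow
        tree = parse_newick(
            "(((A:1,B:1)P:1,(C:1,D:1)Q:3)X:1,((E:1,F:2)R:2,(G:1,H:1)S:1)Y:1);"
        )
        # engineered states: two 11 blocks, one 00 block, one 10 singleton
        s1 = {n: 1 for n in ["A", "B", "P", "C", "D", "Q", "X"]}
        s1.update({n: 0 for n in ["E", "F", "R", "G", "H", "S", "Y"]})
        s1[tree.root.id] = UNCERTAIN
        s2 = dict(s1)
        s2.update({"G": 0})
        cells = asa_counts(tree, s1, s2)
        blocks = asa_decompose(tree, s1, s2)
        sums = {"11": 0.0, "10": 0.0, "01": 0.0, "00": 0.0}
        for b in blocks:
            sums[b.joint] += asa_correct(b, tree)
        expect = tuple(
            int(np.ceil(sums[j] - 1e-9)) if sums[j] > 0 else 0
            for j in ("11", "10", "01", "00")
        )
        assert cells == expect

    def test_star_tree_equals_naive(self):
        rng = np.random.default_rng(61)
        leaves = ",".join(f"L{i}:{rng.uniform(0.5, 2):.3f}" for i in range(12))
        tree = parse_newick(f"({leaves});")
        v1 = {f"L{i}": int(rng.integers(2)) for i in range(12)}
        v2 = {f"L{i}": int(rng.integers(2)) for i in range(12)}
        s1 = dict(v1)
        s2 = dict(v2)
        s1[tree.root.id] = int(rng.integers(2))
        s2[tree.root.id] = int(rng.integers(2))
        names = [f"L{i}" for i in range(12)]
        naive = naive_counts([v1[n] for n in names], [v2[n] for n in names])
        assert asa_counts(tree, s1, s2) == naive

    def test_unweighted_counts_blocks(self, quartet):
        s1 = {"A": 1, "B": 1, "L": 1, "C": 0, "D": 0, "R": 0}
        s1[quartet.root.id] = UNCERTAIN
        assert asa_counts(quartet, s1, s1, weighted=False) == (1, 0, 0, 1)

    def test_fast_route_equals_per_block_composition(self):
        rng = np.random.default_rng(67)
        for _ in range(10):
            tree = random_binary_tree(rng, 14)
            v1 = {n.id: int(rng.integers(2)) for n in tree.leaves()}
            v2 = {n.id: int(rng.integers(2)) for n in tree.leaves()}
            s1, s2 = _acctran_states(tree, (v1, v2))
            cells = asa_counts(tree, s1, s2)
            sums = {"11": 0.0, "10": 0.0, "01": 0.0, "00": 0.0}
            for b in asa_decompose(tree, s1, s2):
                sums[b.joint] += asa_correct(b, tree)
            expect = tuple(
                int(np.ceil(sums[j] - 1e-9)) if sums[j] > 0 else 0
                for j in ("11", "10", "01", "00")
            )
            assert cells == expect

    def test_weighted_cells_not_above_naive(self):
        rng = np.random.default_rng(71)
        for _ in range(10):
            tree = random_binary_tree(rng, 16)
            v1 = {n.id: int(rng.integers(2)) for n in tree.leaves()}
            v2 = {n.id: int(rng.integers(2)) for n in tree.leaves()}
            s1, s2 = _acctran_states(tree, (v1, v2))
            names = tree.leaf_names()
            naive = naive_counts([v1[n] for n in names], [v2[n] for n in names])
            asa = asa_counts(tree, s1, s2)
            assert all(a <= nv for a, nv in zip(asa, naive))


class TestContingencyTest:
    def test_direction_sign(self):
        p, sign = contingency_test(10, 1, 1, 10)
        assert sign == 1 and p < 0.01
        _, sign = contingency_test(1, 10, 10, 1)
        assert sign == -1
        _, sign = contingency_test(2, 2, 2, 2)
        assert sign == 0

    def test_joint_code_uncertain_propagates(self):
        codes = joint_code([1, 0, UNCERTAIN], [1, UNCERTAIN, 0])
        assert codes[0] == 3
        assert codes[1] == UNCERTAIN and codes[2] == UNCERTAIN
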