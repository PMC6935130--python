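"""Sankoff engine vs independent oracles (enumeration, Fitch)."""

import random

import pytest

from oracles import enumeration_min_and_sets, fitch_length, random_case

from charoptim.engine import (
    EngineError,
    StepMatrix,
    character_length,
    max_steps,
    min_steps,
    mpr_sets,
    sankoff_down_pass,
)
from charoptim.matrix import MISSING
from charoptim.trees import PhyloTree
from conftest import build_matrix


class TestStepMatrix:
    def test_unordered_costs(self):
        s = StepMatrix.unordered(3)
        assert s(0, 0) == 0 and s(0, 1) == 1 and s(2, 1) == 1

    def test_ordered_costs(self):
        s = StepMatrix.ordered_linear(4)
        assert s(0, 3) == 3 and s(2, 1) == 1 and s(1, 1) == 0

    @pytest.mark.parametrize("kind", ["unordered", "ordered_linear"])
    def test_symmetry_and_triangle(self, kind):
        s = getattr(StepMatrix, kind)(5)
        k = s.n_states
        for i in range(k):
            for j in range(k):
                assert s(i, j) == s(j, i)
                for l in range(k):
                    assert s(i, j) <= s(i, l) + s(l, j)

    def test_negative_cost_rejected(self):
        with pytest.raises(EngineError):
            StepMatrix([[0, -1], [1, 0]])


class TestCharacterLength:
    def test_invariant_character(self, balanced_quartet):
        m = build_matrix("ABCD", [[0, 0, 0, 0]])
        assert character_length(balanced_quartet, m, 0) == 0

    def test_single_origin(self, balanced_quartet):
        m = build_matrix("ABCD", [[0, 0, 1, 1]])
        assert character_length(balanced_quartet, m, 0) == 1

    def test_ordered_two_tips(self):
        t = PhyloTree.parse("(A,B);")
        m = build_matrix("AB", [[0, 3]], ordered=[0])
        assert character_length(t, m, 0) == 3

    def test_extra_matrix_taxa_ignored(self, balanced_quartet):
        m = build_matrix("ABCDE", [[0, 0, 1, 1, 1]])
        assert character_length(balanced_quartet, m, 0) == 1

    def test_all_missing_on_tree_is_zero(self, balanced_quartet):
        m = build_matrix("ABCD", [["?", "?", "?", "?"]])
        assert character_length(balanced_quartet, m, 0) == 0

    def test_tree_tip_absent_from_matrix_raises(self, balanced_quartet):
        m = build_matrix("ABC", [[0, 0, 1]])
        with pytest.raises(EngineError, match="D"):
            character_length(balanced_quartet, m, 0)


class TestDownPass:
    def test_polymorphic_tip_row(self, balanced_quartet):
        m = build_matrix("ABCD", [[{0, 1}, 0, 1, 1]])
        cost = sankoff_down_pass(balanced_quartet, m, 0)
        tip_a = balanced_quartet.tip_node("A")
        assert cost[tip_a] == [0, 0]

    def test_missing_tip_row_all_zero(self, balanced_quartet):
        m = build_matrix("ABCD", [["?", 0, 1, 1]])
        tip_a = balanced_quartet.tip_node("A")
        assert sankoff_down_pass(balanced_quartet, m, 0)[tip_a] == [0, 0]

    def test_root_row_hand_example(self, balanced_quartet):
        m = build_matrix("ABCD", [[0, 0, 1, 1]])
        cost = sankoff_down_pass(balanced_quartet, m, 0)
        assert cost[balanced_quartet.root] == [1, 1]


class TestMPRSets:
    def test_balanced_case(self, balanced_quartet):
        m = build_matrix("ABCD", [[0, 0, 1, 1]])
        step = StepMatrix.unordered(2)
        cost = sankoff_down_pass(balanced_quartet, m, 0, step)
        mpr = mpr_sets(balanced_quartet, cost, step)
        assert mpr[balanced_quartet.root] == frozenset([0, 1])
        ab = balanced_quartet.mrca(["A", "B"])
        cd = balanced_quartet.mrca(["C", "D"])
        assert mpr[ab] == frozenset([0])
        assert mpr[cd] == frozenset([1])

    def test_pectinate_ambiguous_ancestor(self, pectinate_quartet):
        m = build_matrix("ABCD", [[1, 0, 1, 0]])
        step = StepMatrix.unordered(2)
        cost = sankoff_down_pass(pectinate_quartet, m, 0, step)
        mpr = mpr_sets(pectinate_quartet, cost, step)
        ab = pectinate_quartet.mrca(["A", "B"])
        assert mpr[ab] == frozenset([0, 1])

    def test_invariant_character_singleton_everywhere(self, balanced_quartet):
        m = build_matrix("ABCD", [[1, 1, 1, 1]])
        step = StepMatrix.unordered(2)
        cost = sankoff_down_pass(balanced_quartet, m, 0, step)
        mpr = mpr_sets(balanced_quartet, cost, step)
        assert all(s == frozenset([1]) for s in mpr.values())


class TestMinSteps:
    def test_unordered_three_states(self):
        m = build_matrix("ABC", [[0, 1, 2]])
        assert min_steps(m, 0) == 2

    def test_ordered_range(self):
        m = build_matrix("AB", [[0, 3]], ordered=[0])
        assert min_steps(m, 0) == 3

    def test_polymorphism_resolved_favourably(self):
        m = build_matrix("ABC", [[{0, 1}, 0, 0]])
        assert min_steps(m, 0) == 0

    def test_disjoint_polymorphic_sets(self):
        # no single state covers both cells; two states do
        m = build_matrix("AB", [[{0, 1}, {2, 3}]], n_states=[4])
        assert min_steps(m, 0) == 1

    def test_all_missing(self):
        m = build_matrix("AB", [["?", "?"]])
        assert min_steps(m, 0) == 0


class TestMaxSteps:
    def test_unordered_binary_counts(self):
        m = build_matrix("ABCDE", [[0, 0, 0, 1, 1]])
        assert max_steps(m, 0, list("ABCDE")) == 2

    def test_ordered_three_states(self):
        m = build_matrix("ABC", [[0, 1, 2]], ordered=[0])
        assert max_steps(m, 0, list("ABC")) == 2

    def test_invariant(self):
        m = build_matrix("ABC", [[1, 1, 1]])
        assert max_steps(m, 0, list("ABC")) == 0 == min_steps(m, 0)

    def test_restricted_to_tree_tips(self):
        m = build_matrix("ABCDE", [[0, 0, 0, 1, 1]])
        assert max_steps(m, 0, list("ABC")) == 0


class TestAgainstEnumeration:
    """Exact agreement with brute force on small random instances."""

    N_CASES = 300

    def test_lengths_and_mpr_sets_match_enumeration(self):
        rng = random.Random(20260927)
        for case in range(self.N_CASES):
            tree, matrix, k, ordered = random_case(rng)
            step = StepMatrix.for_character(matrix.characters[0])
            cells = matrix.column(0)
            want_len, want_sets = enumeration_min_and_sets(tree, cells, k, step)
            got_len = character_length(tree, matrix, 0)
            assert got_len == want_len, f"case {case}: length mismatch"
            cost = sankoff_down_pass(tree, matrix, 0, step)
            got_sets = mpr_sets(tree, cost, step)
            for node in tree.postorder():
                assert got_sets[node] == want_sets[node], (
                    f"case {case}: MPR mismatch at {tree.node_label(node)}"
                )

    def test_sankoff_equals_fitch_on_binary_trees(self):
        rng = random.Random(4711)
        for case in range(1000):
            tree, matrix, k, _ = random_case(rng, binary_only=True)
            # force unordered scoring for the Fitch comparison
            m = matrix.with_ordering([])
            assert character_length(tree, m, 0) == fitch_length(tree, m.column(0), k), (
                f"case {case}"
            )

    def test_m_le_s_le_g(self):
        rng = random.Random(99)
        for _ in range(200):
            tree, matrix, k, _ = random_case(rng)
            tips = tree.tip_names
            m = min_steps(matrix, 0, taxa=tips)
            s = character_length(tree, matrix, 0)
            g = max_steps(matrix, 0, tips)
            assert m <= s <= g

    def test_min_steps_is_tree_free_lower_bound(self):
        """m from polymorphism brute force equals the analytic computation."""
        rng = random.Random(5)
        from itertools import product as iproduct

        from charoptim.matrix import is_scored

        for _ in range(150):
            tree, matrix, k, ordered = random_case(rng, max_tips=5)
            step = StepMatrix.for_character(matrix.characters[0])
            cells = [c for c in matrix.column(0).values() if is_scored(c)]
            if not cells:
                continue
            best = None
            for combo in iproduct(*[sorted(c) for c in cells]):
                states = set(combo)
                if ordered:
                    cost = max(states) - min(states)
                else:
                    cost = len(states) - 1
                best = cost if best is None else min(best, cost)
            assert min_steps(matrix, 0) == best


class TestInvariances:
    def test_child_order_irrelevant(self):
        a = PhyloTree.parse("((A,B),(C,D));")
        b = PhyloTree.parse("((D,C),(B,A));")
        m = build_matrix("ABCD", [[0, {0, 1}, "?", 2]], n_states=[3])
        assert character_length(a, m, 0) == character_length(b, m, 0)

    def test_reroot_preserves_length(self):
        rng = random.Random(17)
        for _ in range(50):
            tree, matrix, k, _ = random_case(rng, binary_only=True,
                                             allow_uncertainty=False)
            base = character_length(tree, matrix, 0)
            for tip in tree.tip_names[:3]:
                ingroup = [t for t in tree.tip_names if t != tip]
                rerooted = tree.root_by_outgroup([tip])
                assert character_length(rerooted, matrix, 0) == base

    def test_missing_only_taxon_removable(self):
        t = PhyloTree.parse("((A,B),(C,(D,E)));")
        m = build_matrix("ABCDE", [[0, 1, 1, 0, "?"], [2, "?", 0, 1, "?"]],
                         n_states=[2, 3])
        pruned = t.prune("E")
        for j in range(2):
            assert character_length(t, m, j) == character_length(pruned, m, j)
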