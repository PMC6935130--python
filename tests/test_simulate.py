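"""Synthetic-data generator: determinism, truth bookkeeping, distributions."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from charoptim.engine import StepMatrix, character_length, mpr_sets, sankoff_down_pass
from charoptim.indices import ensemble_fit
from charoptim.matrix import MISSING
from charoptim.resolve import DELTRAN, enumerate_changes, resolve
from charoptim.simulate import (
    SimConfig,
    SimulationError,
    inject_missing,
    make_random_tree,
    simulate_matrix,
)
from charoptim.trees import PhyloTree
from conftest import build_matrix


class TestMakeRandomTree:
    def test_minimum_size(self):
        t = make_random_tree(3, seed=1)
        assert t.n_tips == 3
        with pytest.raises(SimulationError):
            make_random_tree(2, seed=1)

    def test_binary_internal_count(self):
        t = make_random_tree(27, seed=5)
        internals = sum(1 for n in t.postorder() if not n.is_leaf())
        assert internals == 26
        assert all(len(n.child_nodes()) == 2 for n in t.postorder() if not n.is_leaf())

    def test_seeds_give_distinct_topologies(self):
        sigs = {make_random_tree(10, seed=s).topology_signature() for s in range(6)}
        assert len(sigs) >= 5  # collisions vanishingly rare over labelled shapes

    def test_unit_branch_lengths(self):
        t = make_random_tree(8, seed=2)
        assert all(c.edge.length == 1.0 for _, c in t.edges())


class TestSimulateMatrix:
    def _config(self, **kw):
        tree = kw.pop("tree", make_random_tree(10, seed=11))
        base = dict(tree=tree, n_chars=30, rate=0.05,
                    missing_fraction=0.0, seed=42)
        base.update(kw)
        return SimConfig(**base)

    def test_deterministic_under_seed(self):
        a = simulate_matrix(self._config())
        b = simulate_matrix(self._config())
        assert a.matrix == b.matrix

        def flat(sim):
            tree = sim.config.tree
            return [
                [(tree.node_label(n), x, y) for n, x, y in h]
                for h in sim.true_histories
            ]

        assert flat(a) == flat(b)

    def test_rate_zero_limit_invariant(self):
        sim = simulate_matrix(self._config(rate=1e-9))
        assert all(len(h) == 0 for h in sim.true_histories)
        for j in range(sim.matrix.n_characters):
            assert len(sim.matrix.observed_states(j)) == 1

    def test_replaying_history_reproduces_tips(self):
        sim = simulate_matrix(self._config(rate=0.4, seed=3))
        tree = sim.config.tree
        for j, events in enumerate(sim.true_histories):
            states = {tree.root: sim.true_node_states[j][tree.root]}
            by_branch = {}
            for child, a, b in events:
                by_branch.setdefault(child, []).append((a, b))
            for parent, child in tree.edges():
                s = states[parent]
                for a, b in by_branch.get(child, []):
                    assert a == s
                    s = b
                states[child] = s
            for name in tree.tip_names:
                assert sim.matrix.cell(name, j) == frozenset(
                    [states[tree.tip_node(name)]]
                )

    def test_parsimony_lower_bounds_true_events(self):
        sim = simulate_matrix(self._config(rate=0.5, n_chars=100, seed=9))
        tree = sim.config.tree
        for j in range(100):
            assert character_length(tree, sim.matrix, j) <= len(sim.true_histories[j])

    def test_ordered_moves_are_single_steps(self):
        sim = simulate_matrix(self._config(rate=0.8, n_chars=60,
                                           ordered_count=60, seed=21,
                                           max_states=5))
        for h in sim.true_histories:
            for _, a, b in h:
                assert abs(a - b) == 1

    def test_invalid_config_names_each_field(self):
        tree = make_random_tree(5, seed=0)
        with pytest.raises(SimulationError) as err:
            SimConfig(tree=tree, n_chars=0, rate=-1.0,
                      missing_fraction=1.5, seed=1).validate()
        msg = str(err.value)
        assert "n_chars" in msg and "rate" in msg and "missing_fraction" in msg

    def test_tip_pattern_frequencies_match_markov_oracle(self):
        """Observed quartet tip patterns vs exact CTMC probabilities."""
        tree = PhyloTree.parse("((A:1,B:1):1,(C:1,D:1):1);")
        rate = 0.3
        n = 10_000
        sim = simulate_matrix(
            SimConfig(tree=tree, n_chars=n, min_states=2, max_states=2,
                      ordered_fraction=0.0, rate=rate,
                      missing_fraction=0.0, seed=0)
        )
        Q = np.array([[-rate, rate], [rate, -rate]])
        P = expm(Q)  # unit branch
        expected = {}
        for pat in range(16):
            a, b, c, d = (pat >> 3) & 1, (pat >> 2) & 1, (pat >> 1) & 1, pat & 1
            p = 0.0
            for r in (0, 1):
                for e in (0, 1):
                    for f in (0, 1):
                        p += (0.5 * P[r, e] * P[r, f]
                              * P[e, a] * P[e, b] * P[f, c] * P[f, d])
            expected[(a, b, c, d)] = p
        counts = {}
        for j in range(n):
            pat = tuple(next(iter(sim.matrix.cell(t, j))) for t in "ABCD")
            counts[pat] = counts.get(pat, 0) + 1
        assert abs(sum(expected.values()) - 1.0) < 1e-12
        for pat, p in expected.items():
            se = math.sqrt(p * (1 - p) / n)
            obs = counts.get(pat, 0) / n
            assert abs(obs - p) <= 3 * se + 1e-9, (pat, obs, p)


class TestInjectMissing:
    def test_zero_fraction_identity(self):
        m = build_matrix("ABCD", [[0, 0, 1, 1], [0, 1, 0, 1]])
        assert inject_missing(m, 0.0, seed=1) == m

    def test_unknown_taxon_rejected(self):
        m = build_matrix("ABCD", [[0, 0, 1, 1]])
        with pytest.raises(SimulationError, match="Z"):
            inject_missing(m, 0.1, all_missing_taxa=["Z"], seed=1)

    def test_binomial_cell_count(self):
        taxa = [f"t{i}" for i in range(100)]
        cols = [[i % 2 for i in range(100)] for _ in range(40)]
        m = build_matrix(taxa, cols)
        out = inject_missing(m, 0.3, seed=123)
        n_missing = sum(
            1 for row in out.rows for c in row if c is MISSING
        )
        mean, sd = 0.3 * 4000, math.sqrt(4000 * 0.3 * 0.7)
        assert abs(n_missing - mean) <= 4 * sd

    def test_all_missing_taxon_equivalent_to_absent(self):
        tree = make_random_tree(8, seed=4)
        sim = simulate_matrix(SimConfig(tree=tree, n_chars=25, rate=0.3,
                                        missing_fraction=0.0, seed=4))
        blanked = inject_missing(sim.matrix, 0.0,
                                 all_missing_taxa=[tree.tip_names[0]], seed=0)
        pruned_tree = tree.prune(tree.tip_names[0])
        a = ensemble_fit(tree, blanked)
        b = ensemble_fit(pruned_tree, sim.matrix.drop_taxa([tree.tip_names[0]]))
        assert a.tree_length == b.tree_length
        assert a.CI == b.CI and a.RI == b.RI


class TestParameterRecovery:
    def test_low_rate_reconstruction_matches_truth(self):
        """Expected ~0.1 changes/character: DELTRAN changes equal the true
        history for at least 95% of characters."""
        tree = make_random_tree(27, seed=13)
        n_edges = sum(1 for _ in tree.edges())
        rate = 0.1 / n_edges
        sim = simulate_matrix(SimConfig(tree=tree, n_chars=500, rate=rate,
                                        missing_fraction=0.0, seed=13))
        hits = 0
        for j in range(500):
            step = StepMatrix.for_character(sim.matrix.characters[j])
            cost = sankoff_down_pass(tree, sim.matrix, j, step)
            mpr = mpr_sets(tree, cost, step)
            res = resolve(tree, mpr, cost, step, DELTRAN, char_index=j)
            got = sorted(
                (id(c.child), c.from_state, c.to_state)
                for c in enumerate_changes(res)
            )
            want = sorted((id(n), a, b) for n, a, b in sim.true_histories[j])
            hits += got == want
        assert hits / 500 >= 0.95
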