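"""Independent oracles for the parsimony engine tests.

These deliberately share no code with the package's DP implementation:
lengths and MPR sets come from exhaustive enumeration of all internal
state assignments, and unordered lengths on binary trees additionally from
a classic two-pass Fitch count.
"""

from __future__ import annotations

import random
from itertools import product

from charoptim.matrix import CharacterDef, CharacterMatrix, MISSING, is_scored
from charoptim.trees import PhyloTree

BIG = 10 ** 9


def enumeration_min_and_sets(tree: PhyloTree, cells: dict, k: int, step) -> tuple:
    """Brute-force minimum cost and per-node optimal state sets.

    ``cells`` maps tip name -> frozenset of states / MISSING.  Every node
    (tips with uncertainty included) is enumerated over its allowed states;
    the cost of an assignment is the sum of step costs over all edges.
    Returns (min_cost, {node: frozenset(states in >=1 optimal assignment)}).
    """
    nodes = list(tree.postorder())
    choices = []
    for node in nodes:
        if node.is_leaf():
            cell = cells[node.taxon.label]
            allowed = sorted(cell) if is_scored(cell) else list(range(k))
        else:
            allowed = list(range(k))
        choices.append(allowed)

    edges = [(nodes.index(p), nodes.index(c)) for p, c in tree.edges()]
    best = BIG
    opt_states: list = [set() for _ in nodes]
    for assignment in product(*choices):
        cost = sum(step(assignment[i], assignment[j]) for i, j in edges)
        if cost < best:
            best = cost
            opt_states = [set() for _ in nodes]
        if cost == best:
            for i, s in enumerate(assignment):
                opt_states[i].add(s)
    return best, {nodes[i]: frozenset(opt_states[i]) for i in range(len(nodes))}


def fitch_length(tree: PhyloTree, cells: dict, k: int) -> int:
    """Two-pass Fitch count (unordered characters, binary trees only)."""
    sets: dict = {}
    length = 0
    for node in tree.postorder():
        kids = node.child_nodes()
        if not kids:
            cell = cells[node.taxon.label]
            sets[node] = set(cell) if is_scored(cell) else set(range(k))
            continue
        assert len(kids) == 2, "Fitch oracle requires a binary tree"
        a, b = sets[kids[0]], sets[kids[1]]
        inter = a & b
        if inter:
            sets[node] = inter
        else:
            sets[node] = a | b
            length += 1
    return length


def random_case(rng: random.Random, max_tips: int = 6, max_states: int = 4,
                binary_only: bool = False, allow_uncertainty: bool = True):
    """One random (tree, matrix) instance small enough to enumerate.

    Returns (PhyloTree, CharacterMatrix with one character, k, ordered).
    """
    n_tips = rng.randint(4, max_tips)
    k = rng.randint(2, max_states)
    ordered = rng.random() < 0.5
    names = [f"T{i}" for i in range(n_tips)]

    # random topology by sequential joins; occasionally leave a polytomy
    groups = list(names)
    while len(groups) > 1:
        take = 2
        if not binary_only and len(groups) >= 3 and rng.random() < 0.15:
            take = 3
        picked = rng.sample(range(len(groups)), take)
        merged = "(" + ",".join(groups[i] for i in picked) + ")"
        groups = [g for i, g in enumerate(groups) if i not in picked]
        groups.append(merged)
    tree = PhyloTree.parse(groups[0] + ";")

    cells = []
    scored = False
    for _ in range(n_tips):
        r = rng.random()
        if allow_uncertainty and r < 0.10:
            cells.append(MISSING)
        elif allow_uncertainty and r < 0.22:
            size = rng.randint(2, k) if k > 1 else 1
            cells.append(frozenset(rng.sample(range(k), size)))
            scored = True
        else:
            cells.append(frozenset([rng.randrange(k)]))
            scored = True
    if not scored:
        cells[0] = frozenset([rng.randrange(k)])
    matrix = CharacterMatrix(
        taxa=names,
        characters=[CharacterDef(index=0, n_states=k, ordered=ordered)],
        rows=[[c] for c in cells],
    )
    return tree, matrix, k, ordered
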