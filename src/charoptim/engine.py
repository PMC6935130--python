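"""Generalized (Sankoff) parsimony on a fixed rooted tree.

For one character with k states and a step matrix ``step``, the down-pass
computes, for every node v and state i, the minimal cost of the subtree
rooted at v given that v is in state i:

    tips:      S_v(i) = 0 if i is an observed state (any state when the
               cell is missing/inapplicable), infinity otherwise;
    internal:  S_v(i) = sum over children c of min_s [ S_c(s) + step(i, s) ]

Polytomies are treated as hard: the recurrence simply sums over all
children.  The character's length on the tree is ``min_i S_root(i)``.

The up-pass computes, per node, the full cost of the best reconstruction
that places the node in each state, from which the MPR set — the states a
node takes in at least one most-parsimonious reconstruction — is read off.

All costs are exact integers for the built-in step kinds (unordered:
0/1; ordered linear morphocline: ``|i - j|``); weights enter only at the
ensemble level.
"""

from __future__ import annotations

from itertools import combinations

from .matrix import CharacterMatrix, is_scored
from .trees import PhyloTree

#: Effectively-infinite integer cost (never overflows exact int arithmetic).
INF = 10 ** 12


class EngineError(ValueError):
    pass


class StepMatrix:
    """A k x k non-negative integer cost table with zero diagonal."""

    __slots__ = ("costs", "n_states", "kind")

    def __init__(self, costs, kind: str = "custom"):
        self.costs = tuple(tuple(int(c) for c in row) for row in costs)
        self.n_states = len(self.costs)
        self.kind = kind
        for i, row in enumerate(self.costs):
            if len(row) != self.n_states:
                raise EngineError("step matrix must be square")
            if row[i] != 0:
                raise EngineError("step matrix diagonal must be zero")
            if any(c < 0 for c in row):
                raise EngineError("step costs must be non-negative")

    @classmethod
    def unordered(cls, n_states: int) -> "StepMatrix":
        """Fitch costs: 0 on the diagonal, 1 elsewhere."""
        return cls(
            [[0 if i == j else 1 for j in range(n_states)] for i in range(n_states)],
            kind="unordered",
        )

    @classmethod
    def ordered_linear(cls, n_states: int) -> "StepMatrix":
        """Wagner costs for a linear morphocline: ``|i - j|``."""
        return cls(
            [[abs(i - j) for j in range(n_states)] for i in range(n_states)],
            kind="ordered",
        )

    @classmethod
    def for_character(cls, chardef) -> "StepMatrix":
        if chardef.ordered:
            return cls.ordered_linear(chardef.n_states)
        return cls.unordered(chardef.n_states)

    def __call__(self, i: int, j: int) -> int:
        return self.costs[i][j]

    def __eq__(self, other):
        return isinstance(other, StepMatrix) and self.costs == other.costs

    def __repr__(self):
        return f"StepMatrix({self.kind}, k={self.n_states})"


def _tip_cells(tree: PhyloTree, matrix: CharacterMatrix, char_index: int) -> dict:
    names = tree.tip_names
    absent = set(names) - set(matrix.taxa)
    if absent:
        raise EngineError(
            f"tree tips missing from the character matrix: {sorted(absent)}"
        )
    if not names:
        raise EngineError("tree has no tips")
    return matrix.column(char_index, taxa=names)


def tip_cost_row(cell, n_states: int) -> list:
    """Down-pass cost row for a tip: 0 for attainable states, INF otherwise.

    Polymorphic cells are uncertainty (zero cost for each listed state);
    missing and inapplicable cells cost zero in every state.
    """
    if is_scored(cell):
        return [0 if s in cell else INF for s in range(n_states)]
    return [0] * n_states


def sankoff_down_pass(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    char_index: int,
    step: StepMatrix | None = None,
) -> dict:
    """Postorder DP table: ``{node: [cost of subtree | node in state i]}``."""
    chardef = matrix.characters[char_index]
    if step is None:
        step = StepMatrix.for_character(chardef)
    k = step.n_states
    cells = _tip_cells(tree, matrix, char_index)
    table: dict = {}
    for node in tree.postorder():
        if node.is_leaf():
            table[node] = tip_cost_row(cells[node.taxon.label], k)
            continue
        row = [0] * k
        for child in node.child_nodes():
            crow = table[child]
            for i in range(k):
                best = INF
                srow = step.costs[i]
                for s in range(k):
                    v = crow[s] + srow[s]
                    if v < best:
                        best = v
                row[i] = min(row[i] + best, INF)
        table[node] = row
    return table


def character_length(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    char_index: int,
    step: StepMatrix | None = None,
) -> int:
    """Minimum number of (weighted-by-step) changes for one character.

    Matrix taxa absent from the tree are ignored; a character with no
    scored state on the tree's tips has length 0.
    """
    table = sankoff_down_pass(tree, matrix, char_index, step)
    length = min(table[tree.root])
    if length >= INF:
        raise EngineError(
            f"character {char_index + 1}: no state assignment has finite cost"
        )
    return length


def mpr_sets(
    tree: PhyloTree, cost: dict, step: StepMatrix
) -> dict:
    """States attainable at each node in at least one MPR.

    ``cost`` is the table from :func:`sankoff_down_pass`.  The up-pass
    computes F_v(i), the total tree cost of the best reconstruction with v
    in state i; the MPR set at v is ``{i : F_v(i) = tree length}``.
    """
    k = step.n_states
    root = tree.root
    length = min(cost[root])
    full: dict = {root: list(cost[root])}
    for node in tree.preorder():
        if node is root:
            continue
        parent = node.parent_node
        frow = full[parent]
        srow_node = cost[node]
        # parent's down-pass contribution from this child, per parent state
        contrib = []
        for j in range(k):
            best = INF
            srow = step.costs[j]
            for s in range(k):
                v = srow_node[s] + srow[s]
                if v < best:
                    best = v
            contrib.append(best)
        out = []
        for i in range(k):
            best = INF
            for j in range(k):
                base = frow[j] - contrib[j]
                v = base + srow_node[i] + step.costs[j][i]
                if v < best:
                    best = v
            out.append(best)
        full[node] = out
    return {
        node: frozenset(i for i in range(k) if row[i] == length)
        for node, row in full.items()
    }


# ---------------------------------------------------------------------------
# tree-independent bounds


def min_steps(
    matrix: CharacterMatrix, char_index: int, taxa=None
) -> int:
    """Minimum steps attainable on *any* tree (the CI numerator, m).

    Unordered: one fewer than the minimum number of distinct states needed
    to cover every scored cell, resolving polymorphic cells favourably.
    Ordered: the smallest spanned range over polymorphism resolutions.
    """
    chardef = matrix.characters[char_index]
    cells = [
        c for c in matrix.column(char_index, taxa).values() if is_scored(c)
    ]
    if not cells:
        return 0
    if chardef.ordered:
        lo = max(min(c) for c in cells)   # every cell reaches down to its min
        hi = min(max(c) for c in cells)
        return max(0, lo - hi)
    forced = set()
    polys = []
    for c in cells:
        if len(c) == 1:
            forced |= c
        else:
            polys.append(c)
    uncovered = [p for p in polys if not (p & forced)]
    extra = 0
    if uncovered:
        universe = sorted(set().union(*uncovered))
        for size in range(1, len(universe) + 1):
            if any(
                all(set(combo) & p for p in uncovered)
                for combo in combinations(universe, size)
            ):
                extra = size
                break
    n_needed = len(forced) + extra
    return max(0, n_needed - 1)


def max_steps(
    matrix: CharacterMatrix, char_index: int, tree_tips
) -> int:
    """Maximum parsimony length over all trees (the RI bound, g).

    Equals the length on the star tree over the given tips: the best
    single "center" state pays, for every scored cell, the cheapest step
    from the center into the cell.
    """
    chardef = matrix.characters[char_index]
    step = StepMatrix.for_character(chardef)
    cells = [
        c for c in matrix.column(char_index, tree_tips).values() if is_scored(c)
    ]
    if not cells:
        return 0
    best = INF
    for center in range(step.n_states):
        total = sum(min(step(center, s) for s in c) for c in cells)
        best = min(best, total)
    return best
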