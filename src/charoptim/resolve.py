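"""ACCTRAN/DELTRAN resolution of MPR ambiguity and change classification.

Parsimony fixes the number of changes but often not their placement.  The
two classical resolutions assign a single state to every node, never adding
steps beyond the Sankoff minimum:

* **ACCTRAN** (accelerated transformation) pushes changes as close to the
  root as possible, favouring an early gain followed by reversal;
* **DELTRAN** (delayed transformation) pushes changes toward the tips,
  favouring independent parallel gains.

Both are computed by a preorder sweep over the outgroup-rooted tree.  The
root takes the lowest-coded state among those achieving the minimum; each
child then chooses among the states that preserve global optimality given
its parent's state — ACCTRAN the state *farthest* from the parent (largest
step cost), DELTRAN the *nearest* — with remaining ties broken by lowest
state code.  Resolutions are undefined on unrooted trees; the API requires
a rooted :class:`~charoptim.trees.PhyloTree`.

A change whose (branch, from, to) triple differs between the two
resolutions is *ambiguous* (optimisation-dependent).  A change is *unique
and unreversed* when its character has ci = 1.0 and the derived state
arises exactly once with no later change away from it.  For multistate
characters the per-character ci criterion is primary; a per-transition
check (derived state arising once, never left) is computed alongside so
the two notions can be distinguished when they disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engine import StepMatrix
from .trees import PhyloTree

ACCTRAN = "acctran"
DELTRAN = "deltran"


class ResolveError(ValueError):
    pass


@dataclass
class Change:
    """One state change on one branch for one character (0-based index)."""

    char_index: int
    parent: object
    child: object
    parent_label: str
    child_label: str
    from_state: int
    to_state: int
    steps: int = 1
    on_internal_branch: bool = False
    ambiguous: bool | None = None
    unique_unreversed: bool | None = None

    def key(self):
        return (self.char_index, id(self.child), self.from_state, self.to_state)

    def describe(self) -> str:
        arrow = "-->" if self.ambiguous else "==>"
        return (
            f"char {self.char_index + 1}: {self.from_state} {arrow} "
            f"{self.to_state} on {self.parent_label} -> {self.child_label}"
        )


@dataclass
class Resolution:
    """A single-state-per-node assignment for one character."""

    mode: str
    char_index: int
    states: dict  # node -> state
    tree: PhyloTree
    step: StepMatrix

    def length(self) -> int:
        total = 0
        for parent, child in self.tree.edges():
            total += self.step(self.states[parent], self.states[child])
        return total


def resolve(
    tree: PhyloTree,
    mpr: dict,
    cost: dict,
    step: StepMatrix,
    mode: str,
    char_index: int = 0,
) -> Resolution:
    """Assign one state per node under ACCTRAN or DELTRAN.

    ``mpr`` and ``cost`` come from :func:`~charoptim.engine.mpr_sets` and
    :func:`~charoptim.engine.sankoff_down_pass`.  Every assigned state lies
    in the node's MPR set and the implied length equals the Sankoff
    minimum.
    """
    if mode not in (ACCTRAN, DELTRAN):
        raise ResolveError(f"unknown resolution mode {mode!r}")
    k = step.n_states
    root = tree.root
    root_min = min(cost[root])
    states: dict = {}
    states[root] = min(i for i in range(k) if cost[root][i] == root_min)
    for node in tree.preorder():
        if node is root:
            continue
        p_state = states[node.parent_node]
        srow = cost[node]
        best = min(srow[i] + step(p_state, i) for i in range(k))
        cands = [i for i in range(k) if srow[i] + step(p_state, i) == best]
        if mode == ACCTRAN:
            # farthest from the parent: place the change on this rootward edge
            dist = max(step(p_state, i) for i in cands)
        else:
            # nearest to the parent: delay the change toward the tips
            dist = min(step(p_state, i) for i in cands)
        states[node] = min(i for i in cands if step(p_state, i) == dist)
    return Resolution(mode=mode, char_index=char_index, states=states,
                      tree=tree, step=step)


def enumerate_changes(resolution: Resolution) -> list:
    """One :class:`Change` per branch whose endpoint states differ.

    A multi-step ordered change on a single branch is emitted as one
    transition (e.g. ``0 --> 3``) whose ``steps`` is the step-matrix cost.
    Branches are visited in preorder.
    """
    tree = resolution.tree
    states = resolution.states
    out = []
    for parent, child in tree.edges():
        a, b = states[parent], states[child]
        if a == b:
            continue
        out.append(
            Change(
                char_index=resolution.char_index,
                parent=parent,
                child=child,
                parent_label=tree.node_label(parent),
                child_label=tree.node_label(child),
                from_state=a,
                to_state=b,
                steps=resolution.step(a, b),
                on_internal_branch=not child.is_leaf(),
            )
        )
    return out


def _flag_unique_unreversed(changes: list, ci_by_char: dict) -> None:
    by_char: dict = {}
    for c in changes:
        by_char.setdefault(c.char_index, []).append(c)
    for j, chs in by_char.items():
        ci = ci_by_char.get(j)
        char_ci_one = ci is not None and ci == 1
        derived_counts: dict = {}
        left_states = set()
        for c in chs:
            derived_counts[c.to_state] = derived_counts.get(c.to_state, 0) + 1
            left_states.add(c.from_state)
        for c in chs:
            transition_unique = (
                derived_counts[c.to_state] == 1 and c.to_state not in left_states
            )
            c.unique_unreversed = bool(char_ci_one and transition_unique)


def classify_changes(
    acctran_changes: list, deltran_changes: list, ci_by_char: dict
) -> tuple:
    """Annotate both change lists with ambiguity and apomorphy flags.

    A change is unambiguous only when the identical (branch, from, to)
    triple occurs in both resolutions.  Both lists must come from the same
    matrix x tree analysis (same tree object); mismatched inputs raise.
    """
    acc_chars = {c.char_index for c in acctran_changes}
    del_chars = {c.char_index for c in deltran_changes}
    if acc_chars != del_chars:
        raise ResolveError(
            "ACCTRAN and DELTRAN change lists cover different characters: "
            f"{sorted(acc_chars ^ del_chars)}"
        )
    acc_keys = {c.key() for c in acctran_changes}
    del_keys = {c.key() for c in deltran_changes}
    shared = acc_keys & del_keys
    for c in acctran_changes:
        c.ambiguous = c.key() not in shared
    for c in deltran_changes:
        c.ambiguous = c.key() not in shared
    _flag_unique_unreversed(acctran_changes, ci_by_char)
    _flag_unique_unreversed(deltran_changes, ci_by_char)
    return acctran_changes, deltran_changes


def apomorphies_for_clade(changes: list, clade) -> list:
    """Changes on the stem branch of a clade (the edge into its MRCA node)."""
    return [c for c in changes if c.child is clade]
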