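"""Synthetic morphological matrices with known evolutionary histories.

Characters evolve independently on a known tree by a continuous-time
Markov process:

* unordered characters follow the equal-rates Mk model: from state i the
  total leaving rate is ``rate`` split evenly over the other k-1 states;
* ordered characters follow a nearest-neighbour stepping chain (moves of
  one morphocline step only): each permitted +/-1 move fires at rate
  ``rate / 2``, so interior states leave at ``rate`` and boundary states at
  ``rate / 2`` — the process whose cost structure matches the ordered step
  matrix.

The root state is drawn uniformly.  Every change event is recorded, so
parsimony reconstructions can be compared against the true history.  A
missing-data mask is applied *after* evolution, optionally blanking whole
taxa — mimicking fossil taxa scoreable for almost nothing.

The generator's defaults emulate a palaeognath-style morphological data
set: 27 taxa, 42 characters with 2-5 states, 18 of them ordered
morphoclines, with substantial missing data.

A single integer seed drives tree shape, histories and masking through
independently spawned substreams, so each component is reproducible on
its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .matrix import CharacterDef, CharacterMatrix, MISSING
from .trees import PhyloTree


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters for one simulated matrix.

    ``rate`` is the expected number of changes per unit branch length for
    an interior state; ``ordered_count`` fixes how many characters are
    ordered (overriding ``ordered_fraction`` when given).
    """

    tree: PhyloTree = None
    n_chars: int = 42
    min_states: int = 2
    max_states: int = 5
    ordered_fraction: float = 18 / 42
    ordered_count: int | None = None
    rate: float = 0.05
    missing_fraction: float = 0.25
    all_missing_taxa: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.tree is None:
            errors.append("tree: required")
        if self.n_chars < 1:
            errors.append(f"n_chars: must be >= 1, got {self.n_chars}")
        if not 2 <= self.min_states <= self.max_states:
            errors.append(
                f"min_states/max_states: need 2 <= {self.min_states} "
                f"<= {self.max_states}"
            )
        if not 0.0 <= self.ordered_fraction <= 1.0:
            errors.append(
                f"ordered_fraction: must be in [0, 1], got {self.ordered_fraction}"
            )
        if self.rate <= 0:
            errors.append(f"rate: must be > 0, got {self.rate}")
        if not 0.0 <= self.missing_fraction < 1.0:
            errors.append(
                f"missing_fraction: must be in [0, 1), got {self.missing_fraction}"
            )
        if self.tree is not None:
            tips = set(self.tree.tip_names)
            for t in self.all_missing_taxa:
                if t not in tips:
                    errors.append(f"all_missing_taxa: unknown taxon {t!r}")
            for _, child in self.tree.edges():
                if child.edge.length is None or child.edge.length <= 0:
                    errors.append("tree: all branch lengths must be positive")
                    break
        if errors:
            raise SimulationError("; ".join(errors))


@dataclass
class SimResult:
    matrix: CharacterMatrix
    #: per character: list of (child_node, from_state, to_state) in event order
    true_histories: list = field(default_factory=list)
    #: per character: {node: state} at the moment of speciation
    true_node_states: list = field(default_factory=list)
    config: SimConfig = None

    def n_events(self, char_index: int) -> int:
        return len(self.true_histories[char_index])


def make_random_tree(n_tips: int, seed: int) -> PhyloTree:
    """Random binary rooted tree by uniform coalescent-style joins.

    Tips are named ``t01..tNN``; every branch has unit length.
    """
    if n_tips < 3:
        raise SimulationError(f"n_tips must be >= 3, got {n_tips}")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    width = max(2, len(str(n_tips)))
    nodes = []
    for i in range(n_tips):
        node = dendropy.Node(taxon=tns.require_taxon(f"t{i + 1:0{width}d}"))
        node.edge.length = 1.0
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = 1.0
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    return PhyloTree(tree)


def _evolve_branch(state: int, length: float, k: int, ordered: bool,
                   rate: float, rng) -> tuple:
    """Gillespie simulation along one branch; returns (end state, events)."""
    events = []
    t = 0.0
    while True:
        if ordered:
            moves = [s for s in (state - 1, state + 1) if 0 <= s < k]
            leave = rate / 2.0 * len(moves)
        else:
            moves = [s for s in range(k) if s != state]
            leave = rate
        if leave <= 0:
            break
        t += rng.exponential(1.0 / leave)
        if t >= length:
            break
        new_state = moves[rng.integers(len(moves))]
        events.append((state, new_state))
        state = new_state
    return state, events


def simulate_matrix(config: SimConfig) -> SimResult:
    """Evolve a matrix on ``config.tree``, recording the true history."""
    config.validate()
    root_seq = np.random.SeedSequence(config.seed)
    ss_chars, ss_types, ss_mask = root_seq.spawn(3)
    type_rng = np.random.default_rng(ss_types)

    n = config.n_chars
    if config.ordered_count is not None:
        n_ordered = config.ordered_count
        if not 0 <= n_ordered <= n:
            raise SimulationError(f"ordered_count: out of range 0..{n}")
    else:
        n_ordered = round(config.ordered_fraction * n)
    ordered_idx = set(type_rng.choice(n, size=n_ordered, replace=False).tolist())
    k_per_char = type_rng.integers(
        config.min_states, config.max_states + 1, size=n
    ).tolist()

    tree = config.tree
    taxa = tree.tip_names
    characters = []
    columns = []
    histories = []
    node_states_all = []
    char_seeds = ss_chars.spawn(n)
    for j in range(n):
        rng = np.random.default_rng(char_seeds[j])
        k = k_per_char[j]
        ordered = j in ordered_idx
        characters.append(
            CharacterDef(index=j, n_states=k, ordered=ordered)
        )
        states = {tree.root: int(rng.integers(k))}
        events = []
        for parent, child in tree.edges():
            end, branch_events = _evolve_branch(
                states[parent], child.edge.length, k, ordered, config.rate, rng
            )
            states[child] = end
            for a, b in branch_events:
                events.append((child, a, b))
        histories.append(events)
        node_states_all.append(states)
        columns.append(
            {t: frozenset([states[tree.tip_node(t)]]) for t in taxa}
        )

    rows = [[columns[j][t] for j in range(n)] for t in taxa]
    matrix = CharacterMatrix(taxa=list(taxa), characters=characters, rows=rows)
    mask_seed = int(np.random.default_rng(ss_mask).integers(2 ** 31))
    if config.missing_fraction > 0 or config.all_missing_taxa:
        matrix = inject_missing(
            matrix,
            config.missing_fraction,
            all_missing_taxa=config.all_missing_taxa,
            seed=mask_seed,
        )
    return SimResult(
        matrix=matrix,
        true_histories=histories,
        true_node_states=node_states_all,
        config=config,
    )


def inject_missing(
    matrix: CharacterMatrix,
    fraction: float,
    all_missing_taxa=(),
    seed: int = 0,
) -> CharacterMatrix:
    """Blank a random fraction of cells, plus every cell of listed taxa."""
    if not 0.0 <= fraction < 1.0:
        raise SimulationError(f"fraction must be in [0, 1), got {fraction}")
    unknown = set(all_missing_taxa) - set(matrix.taxa)
    if unknown:
        raise SimulationError(f"unknown taxa: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    blank_rows = set(all_missing_taxa)
    for i, taxon in enumerate(out.taxa):
        for j in range(out.n_characters):
            if taxon in blank_rows or (
                fraction > 0 and rng.random() < fraction
            ):
                out.rows[i][j] = MISSING
    return out
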