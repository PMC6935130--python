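"""Discrete character matrices for morphological parsimony analysis.

A :class:`CharacterMatrix` is a taxa x characters table of discrete state
sets.  Each cell is one of

* a ``frozenset`` of integer state codes — a single observed state or a
  polymorphic/uncertain set of several states,
* :data:`MISSING` — the character could not be scored for the taxon,
* :data:`INAPPLICABLE` — the character does not apply to the taxon (coded
  with the gap symbol in NEXUS files).

For optimisation purposes inapplicable cells behave exactly like missing
cells; the distinction is preserved only so files round-trip faithfully.
Polymorphic sets are treated as uncertainty: a reconstruction pays the
minimum cost over the listed states, it is not required to visit them all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


#: Cell value for an unscored (missing) observation.
MISSING = _Sentinel("MISSING")
#: Cell value for an inapplicable observation (NEXUS gap).
INAPPLICABLE = _Sentinel("INAPPLICABLE")

Cell = "frozenset[int] | _Sentinel"


def is_scored(cell) -> bool:
    """True if the cell carries at least one observed state."""
    return isinstance(cell, frozenset)


@dataclass(frozen=True)
class CharacterDef:
    """Metadata for one character column.

    Parameters
    ----------
    index : int
        0-based position of the character in the matrix.  File formats and
        the command line use the 1-based NEXUS convention; the conversion
        happens at the I/O boundary.
    label : str
        Free-text character name.
    n_states : int
        Size of the state space (state codes run 0..n_states-1).
    ordered : bool
        If True the character is a linear morphocline and a change from
        state i to j costs ``|i - j|``; otherwise every change costs 1.
    weight : float
        Multiplier for the character's contribution to ensemble sums.
    state_labels : tuple of str, optional
        Names for the individual states.
    """

    index: int
    label: str = ""
    n_states: int = 2
    ordered: bool = False
    weight: float = 1.0
    state_labels: tuple = None

    def __post_init__(self):
        if self.n_states < 2:
            raise ValueError(
                f"character {self.index}: n_states must be >= 2, got {self.n_states}"
            )
        if self.weight < 0:
            raise ValueError(f"character {self.index}: weight must be non-negative")


@dataclass
class CharacterMatrix:
    """Taxa x characters table of discrete state sets.

    ``rows[i][j]`` is the cell for taxon ``taxa[i]`` and character
    ``characters[j]``.
    """

    taxa: list
    characters: list
    rows: list = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon names: {dupes}")
        nchar = len(self.characters)
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != nchar:
                raise ValueError(
                    f"taxon {taxon!r}: row has {len(row)} cells, expected {nchar}"
                )
        for j, char in enumerate(self.characters):
            space = range(char.n_states)
            for taxon, row in zip(self.taxa, self.rows):
                cell = row[j]
                if is_scored(cell):
                    if not cell:
                        raise ValueError(
                            f"taxon {taxon!r}, character {j + 1}: empty state set"
                        )
                    bad = [s for s in cell if s not in space]
                    if bad:
                        raise ValueError(
                            f"taxon {taxon!r}, character {j + 1}: state(s) {bad} "
                            f"outside 0..{char.n_states - 1}"
                        )

    # -- basic accessors -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def row(self, taxon: str) -> list:
        return self.rows[self.taxa.index(taxon)]

    def cell(self, taxon: str, char_index: int):
        return self.rows[self.taxa.index(taxon)][char_index]

    def column(self, char_index: int, taxa: Sequence[str] | None = None) -> dict:
        """Cells of one character, keyed by taxon.

        ``taxa`` restricts (and does not reorder) the result to taxa present
        in the matrix; taxa named there but absent from the matrix are
        ignored, mirroring how optimisation ignores matrix taxa absent from
        the tree.
        """
        if taxa is None:
            wanted = self.taxa
        else:
            want = set(taxa)
            wanted = [t for t in self.taxa if t in want]
        idx = {t: i for i, t in enumerate(self.taxa)}
        return {t: self.rows[idx[t]][char_index] for t in wanted}

    def observed_states(self, char_index: int, taxa: Sequence[str] | None = None) -> set:
        """Union of states appearing in any scored cell of the character."""
        out: set = set()
        for cell in self.column(char_index, taxa).values():
            if is_scored(cell):
                out |= cell
        return out

    # -- derived matrices ------------------------------------------------

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            taxa=list(self.taxa),
            characters=list(self.characters),
            rows=[list(r) for r in self.rows],
        )

    def subset_characters(self, keep: Iterable[int]) -> "CharacterMatrix":
        """New matrix with the character columns in ``keep`` (0-based), in order."""
        keep = list(keep)
        for j in keep:
            if not 0 <= j < self.n_characters:
                raise IndexError(f"character index {j} out of range")
        chars = [replace(self.characters[j], index=k) for k, j in enumerate(keep)]
        rows = [[row[j] for j in keep] for row in self.rows]
        return CharacterMatrix(taxa=list(self.taxa), characters=chars, rows=rows)

    def drop_taxa(self, names: Iterable[str]) -> "CharacterMatrix":
        drop = set(names)
        unknown = drop - set(self.taxa)
        if unknown:
            raise KeyError(f"unknown taxa: {sorted(unknown)}")
        keep = [i for i, t in enumerate(self.taxa) if t not in drop]
        return CharacterMatrix(
            taxa=[self.taxa[i] for i in keep],
            characters=list(self.characters),
            rows=[list(self.rows[i]) for i in keep],
        )

    def with_ordering(self, ordered_indices: Iterable[int]) -> "CharacterMatrix":
        """New matrix with exactly the given characters (0-based) flagged ordered."""
        ordered = set(ordered_indices)
        for j in ordered:
            if not 0 <= j < self.n_characters:
                raise IndexError(f"character index {j} out of range")
        chars = [
            replace(c, ordered=(j in ordered)) for j, c in enumerate(self.characters)
        ]
        return CharacterMatrix(taxa=list(self.taxa), characters=chars, rows=self.rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and [(c.n_states, c.ordered, c.weight) for c in self.characters]
            == [(c.n_states, c.ordered, c.weight) for c in other.characters]
            and self.rows == other.rows
        )
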