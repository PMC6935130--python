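"""Per-character and ensemble homoplasy indices.

For a character with minimum conceivable steps m (on any tree), observed
steps s (on the given tree) and maximum steps g (star tree):

    ci = m / s          consistency index (undefined when s = 0)
    ri = (g - s)/(g - m)  retention index (undefined when g = m)
    hi = 1 - ci         homoplasy index

The ensemble indices are ratio-of-sums, not means of ratios:

    CI = sum(w*m) / sum(w*s),   RI = (sum(w*g) - sum(w*s)) / (sum(w*g) - sum(w*m))

AC counts the unique-and-unreversed apomorphic characters: characters with
per-character ci = 1.0 whose change lies on an internal (synapomorphy-
bearing) branch.  A flag widens this to all ci = 1 characters including
tip autapomorphies.

All ratios are exact :class:`fractions.Fraction` values; rounding happens
only at display time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .engine import (
    StepMatrix,
    character_length,
    max_steps,
    min_steps,
    mpr_sets,
    sankoff_down_pass,
)
from .matrix import CharacterMatrix
from .resolve import (
    ACCTRAN,
    DELTRAN,
    classify_changes,
    enumerate_changes,
    resolve,
)
from .trees import PhyloTree


@dataclass(frozen=True)
class CharacterFit:
    """m, s, g and the derived ci/ri for one character on one tree."""

    index: int
    m: int
    s: int
    g: int
    weight: float = 1.0
    ordered: bool = False

    @property
    def ci(self) -> Fraction | None:
        if self.s == 0:
            return None
        return Fraction(self.m, self.s)

    @property
    def ri(self) -> Fraction | None:
        if self.g == self.m:
            return None
        return Fraction(self.g - self.s, self.g - self.m)

    @property
    def informative(self) -> bool:
        """False when every tree yields the same length (m = g)."""
        return self.g > self.m

    def to_dict(self) -> dict:
        return {
            "char": self.index + 1,
            "ordered": self.ordered,
            "weight": self.weight,
            "m": self.m,
            "s": self.s,
            "g": self.g,
            "ci": None if self.ci is None else float(self.ci),
            "ri": None if self.ri is None else float(self.ri),
        }


@dataclass
class FitReport:
    """The ensemble row for one matrix x topology pair, plus per-character detail."""

    topology: str
    tree_length: int
    CI: Fraction | None
    RI: Fraction | None
    AC: int
    character_fits: list
    acctran_changes: list = field(default_factory=list)
    deltran_changes: list = field(default_factory=list)
    excluded_uninformative: int = 0

    @property
    def HI(self) -> Fraction | None:
        return None if self.CI is None else 1 - self.CI

    def changes(self, mode: str = DELTRAN) -> list:
        if mode == DELTRAN:
            return self.deltran_changes
        if mode == ACCTRAN:
            return self.acctran_changes
        raise ValueError(f"unknown mode {mode!r}")

    def to_dict(self, include_changes: bool = True) -> dict:
        d = {
            "topology": self.topology,
            "tree_length": self.tree_length,
            "CI": None if self.CI is None else float(self.CI),
            "HI": None if self.HI is None else float(self.HI),
            "RI": None if self.RI is None else float(self.RI),
            "AC": self.AC,
            "characters": [f.to_dict() for f in self.character_fits],
        }
        if include_changes:
            for mode in (ACCTRAN, DELTRAN):
                d[f"{mode}_changes"] = [
                    {
                        "char": c.char_index + 1,
                        "branch": f"{c.parent_label} -> {c.child_label}",
                        "from": c.from_state,
                        "to": c.to_state,
                        "steps": c.steps,
                        "internal": c.on_internal_branch,
                        "ambiguous": c.ambiguous,
                        "unique_unreversed": c.unique_unreversed,
                    }
                    for c in self.changes(mode)
                ]
        return d


def character_fit(
    tree: PhyloTree, matrix: CharacterMatrix, char_index: int
) -> CharacterFit:
    """Compute m, s, g for one character restricted to the tree's tips."""
    chardef = matrix.characters[char_index]
    tips = tree.tip_names
    return CharacterFit(
        index=char_index,
        m=min_steps(matrix, char_index, taxa=tips),
        s=character_length(tree, matrix, char_index),
        g=max_steps(matrix, char_index, tree_tips=tips),
        weight=chardef.weight,
        ordered=chardef.ordered,
    )


def _weighted_sum(fits, attr: str):
    total = 0
    for f in fits:
        w = f.weight
        v = getattr(f, attr) * w
        total = total + (int(v) if float(v).is_integer() else v)
    return total


def ensemble_fit(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    topology_name: str = "topology",
    *,
    exclude_uninformative: bool = False,
    count_autapomorphies: bool = False,
    include_characters=None,
) -> FitReport:
    """Optimise every character on one topology and assemble the report.

    ``exclude_uninformative`` drops parsimony-uninformative characters
    (m = g) from the CI/RI sums; tree length always sums all characters.
    ``include_characters`` (0-based indices) restricts the CI/RI sums for
    cross-topology comparability; it does not affect tree length either.
    """
    fits = [character_fit(tree, matrix, j) for j in range(matrix.n_characters)]
    tree_length = _weighted_sum(fits, "s")

    index_fits = fits
    if include_characters is not None:
        keep = set(include_characters)
        index_fits = [f for f in index_fits if f.index in keep]
    n_before = len(index_fits)
    if exclude_uninformative:
        index_fits = [f for f in index_fits if f.informative]
    excluded = n_before - len(index_fits)

    sum_m = _weighted_sum(index_fits, "m")
    sum_s = _weighted_sum(index_fits, "s")
    sum_g = _weighted_sum(index_fits, "g")
    CI = None if sum_s == 0 else Fraction(sum_m) / Fraction(sum_s)
    RI = (
        None
        if sum_g == sum_m
        else Fraction(sum_g - sum_s) / Fraction(sum_g - sum_m)
    )

    acc_all: list = []
    del_all: list = []
    ci_by_char: dict = {}
    for f in fits:
        ci_by_char[f.index] = f.ci
        if f.s == 0:
            continue
        chardef = matrix.characters[f.index]
        step = StepMatrix.for_character(chardef)
        cost = sankoff_down_pass(tree, matrix, f.index, step)
        mpr = mpr_sets(tree, cost, step)
        for mode, bucket in ((ACCTRAN, acc_all), (DELTRAN, del_all)):
            res = resolve(tree, mpr, cost, step, mode, char_index=f.index)
            bucket.extend(enumerate_changes(res))
    classify_changes(acc_all, del_all, ci_by_char)

    ac_chars = set()
    for c in del_all:
        ci = ci_by_char.get(c.char_index)
        if ci is None or ci != 1:
            continue
        if count_autapomorphies or c.on_internal_branch:
            ac_chars.add(c.char_index)

    return FitReport(
        topology=topology_name,
        tree_length=tree_length,
        CI=CI,
        RI=RI,
        AC=len(ac_chars),
        character_fits=fits,
        acctran_changes=acc_all,
        deltran_changes=del_all,
        excluded_uninformative=excluded,
    )


def compare_topologies(
    matrix: CharacterMatrix,
    trees: dict,
    *,
    exclude_uninformative: bool = False,
    count_autapomorphies: bool = False,
) -> tuple:
    """One :class:`FitReport` per named topology, plus a ranking.

    Character inclusion is held identical across trees: with
    ``exclude_uninformative`` a character enters the CI/RI sums only when
    it is informative on *every* topology.  Returns ``(reports, ranking)``
    where ranking is the topology names sorted best-first by tree length,
    then CI, then RI.
    """
    if len(trees) < 2:
        raise ValueError("compare_topologies needs at least two trees")
    names = list(trees)
    tipsets = {n: set(trees[n].tip_names) for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if len(tipsets[a] & tipsets[b]) < 2:
                raise ValueError(
                    f"topologies {a!r} and {b!r} share fewer than two taxa"
                )

    include = None
    if exclude_uninformative:
        include = set(range(matrix.n_characters))
        for name in names:
            fits = [
                character_fit(trees[name], matrix, j)
                for j in range(matrix.n_characters)
            ]
            include &= {f.index for f in fits if f.informative}

    reports = [
        ensemble_fit(
            trees[name],
            matrix,
            topology_name=name,
            count_autapomorphies=count_autapomorphies,
            include_characters=include,
        )
        for name in names
    ]

    def _rank_key(r: FitReport):
        return (
            r.tree_length,
            -(r.CI if r.CI is not None else 0),
            -(r.RI if r.RI is not None else 0),
        )

    ranking = [r.topology for r in sorted(reports, key=_rank_key)]
    return reports, ranking
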