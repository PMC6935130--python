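"""Model/Results interface for character optimisation.

:class:`CharacterOptimization` pairs a character matrix with one fixed,
rooted topology; :meth:`~CharacterOptimization.fit` runs the Sankoff
optimisation for every character under both ACCTRAN and DELTRAN and
returns an :class:`OptimizationResults` carrying the ensemble indices
(tree length, CI, HI, RI, AC), the per-character m/s/g table, the
classified change lists, and a printable summary.

:func:`compare_topologies` fits the same matrix against several competing
topologies and ranks them.
"""

from __future__ import annotations

from fractions import Fraction

import pandas as pd

from . import indices
from .indices import FitReport
from .matrix import CharacterMatrix
from .nexus import parse_assumptions, parse_nexus_matrix
from .resolve import ACCTRAN, DELTRAN, apomorphies_for_clade
from .trees import PhyloTree, parse_tree


def _parse_char_selection(spec, n_chars: int) -> set:
    """1-based NEXUS-style charset ("1-42 45") or iterable of 1-based ints."""
    if spec is None:
        return set()
    if isinstance(spec, str):
        out = set()
        for tok in spec.replace(",", " ").split():
            if "-" in tok:
                lo, hi = tok.split("-", 1)
                lo = int(lo)
                hi = n_chars if hi in (".", "") else int(hi)
            else:
                lo = hi = int(tok)
            if not 1 <= lo <= hi <= n_chars:
                raise ValueError(f"character selection {tok!r} outside 1..{n_chars}")
            out |= set(range(lo - 1, hi))
        return out
    out = {int(j) - 1 for j in spec}
    bad = [j + 1 for j in out if not 0 <= j < n_chars]
    if bad:
        raise ValueError(f"character selection {bad} outside 1..{n_chars}")
    return out


class CharacterOptimization:
    """Parsimony optimisation of a discrete character matrix on one topology.

    Parameters
    ----------
    matrix : CharacterMatrix
        The characters; ordering flags and weights are honoured.
    tree : PhyloTree
        Rooted topology whose tips are all present in ``matrix``.
    topology_name : str
        Label used in reports.
    include_chars, exclude_chars : str or iterable of int, optional
        1-based character selections (NEXUS charset syntax, e.g.
        ``"1-42"``); exclusion wins over inclusion.
    outgroup : iterable of str, optional
        If given, the tree is (re)rooted by these taxa before fitting.
    exclude_uninformative : bool
        Drop parsimony-uninformative characters from the CI/RI sums.
    count_autapomorphies : bool
        Count ci = 1 characters changing on terminal branches toward AC.
    """

    def __init__(
        self,
        matrix: CharacterMatrix,
        tree: PhyloTree,
        *,
        topology_name: str = "topology",
        include_chars=None,
        exclude_chars=None,
        outgroup=None,
        exclude_uninformative: bool = False,
        count_autapomorphies: bool = False,
    ):
        n = matrix.n_characters
        include = _parse_char_selection(include_chars, n) or set(range(n))
        include -= _parse_char_selection(exclude_chars, n)
        if not include:
            raise ValueError("character selection is empty")
        self.selected_chars = sorted(include)
        self.matrix = matrix.subset_characters(self.selected_chars)
        if outgroup is not None:
            tree = tree.root_by_outgroup(list(outgroup))
        self.tree = tree
        self.topology_name = topology_name
        self.exclude_uninformative = exclude_uninformative
        self.count_autapomorphies = count_autapomorphies

    @classmethod
    def from_files(
        cls,
        matrix_path: str,
        tree_path: str,
        *,
        assumptions_path: str | None = None,
        **kwargs,
    ) -> "CharacterOptimization":
        """Build from a NEXUS matrix file and a newick/NEXUS tree file."""
        with open(matrix_path) as fh:
            matrix = parse_nexus_matrix(fh.read())
        if assumptions_path is not None:
            with open(assumptions_path) as fh:
                matrix = parse_assumptions(fh.read(), matrix)
        with open(tree_path) as fh:
            tree = parse_tree(fh.read())
        return cls(matrix, tree, **kwargs)

    def fit(self) -> "OptimizationResults":
        report = indices.ensemble_fit(
            self.tree,
            self.matrix,
            topology_name=self.topology_name,
            exclude_uninformative=self.exclude_uninformative,
            count_autapomorphies=self.count_autapomorphies,
        )
        return OptimizationResults(self, report)


class OptimizationResults:
    """Fitted ensemble indices and classified change lists."""

    def __init__(self, model: CharacterOptimization, report: FitReport):
        self.model = model
        self.report = report

    # -- headline numbers ------------------------------------------------

    @property
    def tree_length(self) -> int:
        return self.report.tree_length

    @property
    def ci(self) -> float | None:
        return None if self.report.CI is None else float(self.report.CI)

    @property
    def hi(self) -> float | None:
        return None if self.report.HI is None else float(self.report.HI)

    @property
    def ri(self) -> float | None:
        return None if self.report.RI is None else float(self.report.RI)

    @property
    def ac(self) -> int:
        return self.report.AC

    # -- tables ----------------------------------------------------------

    def character_fits(self) -> pd.DataFrame:
        """Per-character m, s, g, ci, ri (1-based character numbers)."""
        return pd.DataFrame([f.to_dict() for f in self.report.character_fits])

    def changes(self, mode: str = DELTRAN, min_ci: float | None = None) -> pd.DataFrame:
        """Classified changes for one resolution mode.

        ``min_ci`` filters to characters at or above a consistency-index
        threshold (a report filter only — e.g. 0.5 to show the well-fitting
        characters), leaving the computation untouched.
        """
        ci_by_char = {f.index: f.ci for f in self.report.character_fits}
        rows = []
        for c in self.report.changes(mode):
            ci = ci_by_char.get(c.char_index)
            if min_ci is not None and (ci is None or ci < min_ci):
                continue
            rows.append(
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
            )
        return pd.DataFrame(
            rows,
            columns=[
                "char", "branch", "from", "to", "steps",
                "internal", "ambiguous", "unique_unreversed",
            ],
        )

    def apomorphies(self, clade_tips, mode: str = DELTRAN) -> list:
        """Changes on the stem branch of the clade spanned by ``clade_tips``.

        A single tip name gives that tip's autapomorphies.
        """
        if isinstance(clade_tips, str):
            node = self.model.tree.tip_node(clade_tips)
        else:
            node = self.model.tree.mrca(clade_tips)
        return apomorphies_for_clade(self.report.changes(mode), node)

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        r = self.report

        def fmt(x):
            return "   n/a" if x is None else f"{float(x):.4f}"

        lines = [
            "Character optimisation results",
            "=" * 62,
            f"Topology:            {r.topology}",
            f"Taxa on tree:        {self.model.tree.n_tips}",
            f"Characters:          {self.model.matrix.n_characters}"
            + (
                f"  ({r.excluded_uninformative} uninformative excluded from CI/RI)"
                if r.excluded_uninformative
                else ""
            ),
            f"Ordered characters:  "
            f"{sum(1 for c in self.model.matrix.characters if c.ordered)}",
            "-" * 62,
            f"Tree length (L):     {r.tree_length}",
            f"Consistency (CI):    {fmt(r.CI)}",
            f"Homoplasy (HI):      {fmt(r.HI)}",
            f"Retention (RI):      {fmt(r.RI)}",
            f"Apomorphic (AC):     {r.AC}   (unique-and-unreversed, ci = 1.0)",
            "-" * 62,
            f"Changes (DELTRAN):   {len(r.deltran_changes)}"
            f"   ambiguous: {sum(1 for c in r.deltran_changes if c.ambiguous)}",
            f"Changes (ACCTRAN):   {len(r.acctran_changes)}"
            f"   ambiguous: {sum(1 for c in r.acctran_changes if c.ambiguous)}",
            "=" * 62,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return self.report.to_dict()


class TopologyComparison:
    """Fit of one matrix against several topologies, ranked best-first."""

    def __init__(self, results: list, ranking: list):
        self.results = results
        self.ranking = ranking

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, name: str) -> OptimizationResults:
        for r in self.results:
            if r.report.topology == name:
                return r
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "Topology": r.report.topology,
                    "TreeLength": r.tree_length,
                    "CI": r.ci,
                    "HI": r.hi,
                    "RI": r.ri,
                    "AC": r.ac,
                    "Rank": self.ranking.index(r.report.topology) + 1,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame().copy()
        for col in ("CI", "HI", "RI"):
            df[col] = df[col].map(lambda v: "n/a" if v is None else f"{v:.4f}")
        header = "Topology comparison (best first by L, then CI, RI)"
        return (
            header
            + "\n"
            + "=" * len(header)
            + "\n"
            + df.to_string(index=False)
            + "\n"
            + f"Preferred topology: {self.ranking[0]}"
        )


def compare_topologies(
    matrix: CharacterMatrix,
    trees: dict,
    *,
    include_chars=None,
    exclude_chars=None,
    outgroup=None,
    exclude_uninformative: bool = False,
    count_autapomorphies: bool = False,
) -> TopologyComparison:
    """Fit a matrix against >=2 named topologies and rank them."""
    models = {
        name: CharacterOptimization(
            matrix,
            tree,
            topology_name=name,
            include_chars=include_chars,
            exclude_chars=exclude_chars,
            outgroup=outgroup,
            count_autapomorphies=count_autapomorphies,
        )
        for name, tree in trees.items()
    }
    some = next(iter(models.values()))
    reports, ranking = indices.compare_topologies(
        some.matrix,
        {name: m.tree for name, m in models.items()},
        exclude_uninformative=exclude_uninformative,
        count_autapomorphies=count_autapomorphies,
    )
    results = [
        OptimizationResults(models[rep.topology], rep) for rep in reports
    ]
    return TopologyComparison(results, ranking)
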