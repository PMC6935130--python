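"""Rooted phylogenies and topology manipulation.

:class:`PhyloTree` is a thin wrapper around a rooted :class:`dendropy.Tree`
(cladogram semantics: branch lengths are carried but never required —
parsimony optimisation is length-free).  Polytomies are preserved as given;
no arbitrary resolution is ever performed.

The module also provides the topology-construction steps used to build
competing hypotheses for character optimisation: outgroup rooting, grafting
taxa that lack data onto a backbone, and rearranging major clades to
conform to a named hypothesis expressed as :class:`CladeConstraint` s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy


class TreeError(ValueError):
    pass


class CladeConstraintError(TreeError):
    """Contradictory or unsatisfiable clade constraints."""


@dataclass(frozen=True)
class CladeConstraint:
    """Required placement of one clade relative to the rest of the tree.

    Exactly one of ``sister`` / ``basal_within`` must be given.  ``tips``
    (and targets given as tip sets) must be monophyletic on the input tree;
    within-clade structure is never altered.
    """

    name: str
    tips: frozenset
    sister: "frozenset | str | None" = None
    basal_within: "frozenset | str | None" = None

    def __post_init__(self):
        if (self.sister is None) == (self.basal_within is None):
            raise CladeConstraintError(
                f"constraint {self.name!r}: give exactly one of sister / basal_within"
            )


class PhyloTree:
    """A rooted tree with named tips; polytomies allowed."""

    def __init__(self, dtree: dendropy.Tree):
        dtree.is_rooted = True
        self._tree = dtree
        names = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")

    # -- construction ----------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "PhyloTree":
        """Parse a newick string or the first tree of a NEXUS TREES block."""
        schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
        try:
            dtree = dendropy.Tree.get(data=text, schema=schema)
        except dendropy.utility.error.DataParseError as exc:
            raise TreeError(f"cannot parse tree: {exc}") from exc
        return cls(dtree)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return cls.parse(text)

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- inspection ------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self):
        return self._tree.seed_node

    @property
    def tip_names(self) -> list:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def postorder(self):
        return self._tree.postorder_node_iter()

    def preorder(self):
        return self._tree.preorder_node_iter()

    def edges(self):
        """(parent, child) pairs in preorder (root edge excluded)."""
        for node in self._tree.preorder_node_iter():
            for child in node.child_nodes():
                yield node, child

    def tipsets(self) -> dict:
        """Map every node to the frozenset of tip names below it."""
        out: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                out[node] = frozenset([node.taxon.label])
            else:
                acc = frozenset()
                for child in node.child_nodes():
                    acc |= out[child]
                out[node] = acc
        return out

    def tip_node(self, name: str):
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label == name:
                return leaf
        raise TreeError(f"tip {name!r} not in tree")

    def mrca(self, tip_names: Iterable[str]):
        """Most recent common ancestor of the named tips."""
        want = frozenset(tip_names)
        missing = want - set(self.tip_names)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        tipsets = self.tipsets()
        best = None
        for node in self._tree.postorder_node_iter():
            if want <= tipsets[node]:
                best = node
                break  # postorder: first container is the MRCA
        return best

    def node_label(self, node) -> str:
        """Stable human-readable label for a node (tip name or clade tag)."""
        if node.is_leaf():
            return node.taxon.label
        tips = sorted(self.tipsets()[node])
        if len(tips) <= 3:
            return "MRCA(" + "+".join(tips) + ")"
        return f"MRCA({tips[0]}+{len(tips) - 1} others)"

    def topology_signature(self) -> frozenset:
        """Set of non-trivial tip bipartition clades; equal iff same topology."""
        tipsets = self.tipsets()
        all_tips = tipsets[self.root]
        return frozenset(
            ts for ts in tipsets.values() if 1 < len(ts) < len(all_tips)
        )

    def write_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=False
        )
        return s.strip()

    # -- rooting ---------------------------------------------------------

    def root_by_outgroup(self, outgroup: Sequence[str]) -> "PhyloTree":
        """Root so that the outgroup is monophyletic and sister to the ingroup.

        The input rooting is treated as arbitrary.  Raises if the outgroup
        does not form a connected cluster on the unrooted tree, or if it
        equals the full tip set.
        """
        og = frozenset(outgroup)
        tips = frozenset(self.tip_names)
        unknown = og - tips
        if unknown:
            raise TreeError(f"outgroup taxa not in tree: {sorted(unknown)}")
        if og == tips:
            raise TreeError("outgroup cannot contain every tip")
        if not og:
            raise TreeError("outgroup is empty")
        ingroup = tips - og

        new = self.clone()
        tipsets = new.tipsets()
        children = new.root.child_nodes()
        if len(children) == 2 and any(tipsets[c] == og for c in children):
            return new  # already rooted as requested (idempotent)

        target = None
        for node in new._tree.postorder_node_iter():
            if node is new.root:
                continue
            if tipsets[node] == og or tipsets[node] == ingroup:
                target = node
                break
        if target is None:
            raise TreeError(
                "outgroup is not monophyletic on the unrooted tree: "
                f"{sorted(og)}"
            )
        new._tree.reroot_at_edge(target.edge)
        new._tree.suppress_unifurcations()
        return PhyloTree(new._tree)

    # -- grafting and pruning -------------------------------------------

    def _resolve_position(self, position):
        if isinstance(position, dendropy.Node):
            return position
        if isinstance(position, str):
            return self.tip_node(position)
        names = frozenset(position)
        node = self.mrca(names)
        return node

    def graft(self, taxon: str, position, mode: str = "sister") -> "PhyloTree":
        """Attach a new tip next to ``position``.

        ``mode='sister'`` with a tip position makes the new tip that tip's
        sister.  ``mode='basal'`` with a clade position (a set of tip names)
        attaches the new tip as sister to the entire clade — on a clade of
        one tip this degenerates to ``sister``.  Both subdivide the stem
        branch above the position node.
        """
        if mode not in ("sister", "basal"):
            raise TreeError(f"unknown graft mode {mode!r}")
        if taxon in self.tip_names:
            raise TreeError(f"taxon {taxon!r} already in tree")
        new = self.clone()
        if isinstance(position, dendropy.Node):
            # caller's node belongs to the original tree; map by tip set
            tipsets = self.tipsets()
            position = frozenset(tipsets[position])
        anchor = new._resolve_position(position)

        tns = new._tree.taxon_namespace
        tip = dendropy.Node(taxon=tns.require_taxon(label=taxon))
        tip.edge.length = 0.0
        joint = dendropy.Node()
        joint.edge.length = 0.0
        parent = anchor.parent_node
        if parent is None:  # grafting basal to the whole tree: new root
            joint.add_child(anchor)
            joint.add_child(tip)
            new._tree.seed_node = joint
        else:
            parent.remove_child(anchor)
            joint.add_child(anchor)
            joint.add_child(tip)
            parent.add_child(joint)
        return PhyloTree(new._tree)

    def prune(self, taxon: str) -> "PhyloTree":
        """Remove one tip, suppressing the unifurcation it leaves behind."""
        new = self.clone()
        leaf = new.tip_node(taxon)
        parent = leaf.parent_node
        if parent is None:
            raise TreeError("cannot prune the only node of the tree")
        parent.remove_child(leaf)
        new._tree.suppress_unifurcations()
        # a root left with a single child is also collapsed
        while len(new.root.child_nodes()) == 1:
            new._tree.seed_node = new.root.child_nodes()[0]
            new._tree.seed_node.parent_node = None
        return PhyloTree(new._tree)

    # -- hypothesis rearrangement ---------------------------------------

    def rearrange(self, constraints: Sequence[CladeConstraint]) -> "PhyloTree":
        """Re-arrange major clades to conform to a hypothesis.

        Each constraint detaches its (monophyletic) clade and re-attaches
        it: as sister to the target clade, or as the basal (first-diverging)
        lineage within a named scope.  Within-clade structure is preserved;
        the tip set never changes.
        """
        by_name = {c.name: c for c in constraints}
        for i, a in enumerate(constraints):
            for b in constraints[i + 1:]:
                if a.tips == b.tips and (
                    a.sister != b.sister or a.basal_within != b.basal_within
                ):
                    raise CladeConstraintError(
                        f"contradictory constraints {a.name!r} and {b.name!r}: "
                        "same clade, different required placements"
                    )

        def _target_tips(ref) -> frozenset:
            if isinstance(ref, str):
                if ref not in by_name:
                    raise CladeConstraintError(
                        f"constraint target {ref!r} names no other constraint"
                    )
                return by_name[ref].tips
            return frozenset(ref)

        new = self.clone()
        all_tips = frozenset(new.tip_names)
        for con in constraints:
            if not con.tips <= all_tips:
                raise CladeConstraintError(
                    f"constraint {con.name!r}: tips not in tree: "
                    f"{sorted(con.tips - all_tips)}"
                )
            tipsets = new.tipsets()
            subject = new.mrca(con.tips)
            if tipsets[subject] != con.tips:
                raise CladeConstraintError(
                    f"constraint {con.name!r}: tips are not monophyletic "
                    "on the current tree"
                )
            if con.sister is not None:
                target_tips = _target_tips(con.sister)
            else:
                scope = _target_tips(con.basal_within)
                if not con.tips < scope:
                    raise CladeConstraintError(
                        f"constraint {con.name!r}: clade is not inside its "
                        "basal_within scope"
                    )
                target_tips = scope - con.tips
            if target_tips & con.tips:
                raise CladeConstraintError(
                    f"constraint {con.name!r}: target overlaps the clade itself"
                )

            # detach subject
            parent = subject.parent_node
            if parent is None:
                raise CladeConstraintError(
                    f"constraint {con.name!r}: cannot move the whole tree"
                )
            parent.remove_child(subject)
            new._tree.suppress_unifurcations()
            while len(new.root.child_nodes()) == 1:
                new._tree.seed_node = new.root.child_nodes()[0]
                new._tree.seed_node.parent_node = None

            # re-attach as sister to the target clade
            tipsets = new.tipsets()
            anchor = new.mrca(target_tips)
            if tipsets[anchor] != frozenset(target_tips):
                raise CladeConstraintError(
                    f"constraint {con.name!r}: target clade is not "
                    "monophyletic after detaching"
                )
            joint = dendropy.Node()
            joint.edge.length = 0.0
            aparent = anchor.parent_node
            if aparent is None:
                joint.add_child(anchor)
                joint.add_child(subject)
                new._tree.seed_node = joint
            else:
                aparent.remove_child(anchor)
                joint.add_child(anchor)
                joint.add_child(subject)
                aparent.add_child(joint)
        result = PhyloTree(new._tree)
        if frozenset(result.tip_names) != all_tips:
            raise CladeConstraintError("rearrangement altered the tip set")
        return result


def parse_tree(text: str) -> PhyloTree:
    """Parse a newick string or NEXUS trees block into a rooted tree."""
    return PhyloTree.parse(text)
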