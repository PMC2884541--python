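"""Orthogroup delineation on prokaryote-rooted gene trees.

An orthogroup is a eukaryote-only clade containing members from both
Archaeplastida (R) and Opisthokonta (O) that most likely descends from a
single gene of the first eukaryotic common ancestor.  Delineation works on
the maximal eukaryote-only clades (MECs) of a rooted tree:

* a MEC whose sister subtree contains only prokaryotic leaves is a **type I**
  orthogroup (it has a direct prokaryotic outgroup);
* a MEC whose sister mixes eukaryotic and prokaryotic leaves is resolved at
  its basal split: if both basal children themselves contain R and O members,
  each child becomes a separate **type II** orthogroup (two sister
  orthogroups whose joint ancestor is delimited by a prokaryote-outgrouped
  neighbourhood); otherwise the whole MEC is a single type II orthogroup.

The basal split that separates two sister type II orthogroups is consumed by
the split itself and is not a duplication candidate; deeper splits inside any
orthogroup are, and are handled by :mod:`paleodup.duplications`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import AnalysisInputError
from .taxa import Group, TaxonMap
from .trees import GeneTree, Node

__all__ = ["Orthogroup", "find_mecs", "delineate_orthogroups"]


@dataclass(frozen=True)
class Orthogroup:
    """A delineated orthogroup: a clade of the source tree.

    ``split_root_consumed`` marks orthogroups created by splitting a MEC into
    two sister type II orthogroups; duplication scanning then still visits
    every internal node of the orthogroup clade itself.
    """

    tree_id: Optional[str]
    orthogroup_id: str
    root: Node
    og_type: str  # "I" or "II"
    sister_context: str  # "prokaryote-pure" or "mixed"
    n_R: int
    n_O: int

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    @property
    def size(self) -> int:
        return len(self.root.leaves())


def find_mecs(tree: GeneTree, taxa: TaxonMap) -> list[Node]:
    """Maximal eukaryote-only clades, in deterministic preorder.

    A MEC is a clade whose leaves are all eukaryotic and whose parent clade
    (if any) contains at least one non-eukaryotic leaf.  Traversal stops at
    each MEC, so returned clades are pairwise disjoint.
    """
    mecs: list[Node] = []

    def walk(node: Node) -> None:
        # single eukaryotic leaves hanging in a mixed context are degenerate
        # MECs; they can never become orthogroups but keeping them makes the
        # maximality property uniform.
        if all(taxa.is_eukaryote(l.label) for l in node.leaves()):
            mecs.append(node)
            return
        for child in node.children:
            walk(child)

    walk(tree.root)
    return mecs


def _has_R_and_O(node: Node, taxa: TaxonMap) -> tuple[int, int]:
    n_r = n_o = 0
    for leaf in node.leaves():
        g = taxa.group_of(leaf.label)
        if g is Group.R:
            n_r += 1
        elif g is Group.O:
            n_o += 1
    return n_r, n_o


def _sister_context(mec: Node, taxa: TaxonMap) -> str:
    """Lineage composition of everything under the MEC's parent except the
    MEC itself."""
    parent = mec.parent
    sister_leaves = [
        leaf
        for child in parent.children
        if child is not mec
        for leaf in child.leaves()
    ]
    if all(taxa.is_prokaryote(l.label) for l in sister_leaves):
        return "prokaryote-pure"
    return "mixed"


def delineate_orthogroups(tree: GeneTree, taxa: TaxonMap) -> list[Orthogroup]:
    """Delineate type I / type II orthogroups from a rooted tree.

    The tree must be rooted (normally by
    :func:`paleodup.trees.root_by_prokaryotes`).  MECs lacking either an R or
    an O member yield no orthogroup.  Output order is deterministic
    (preorder; a split MEC contributes its two children in serialization
    order).
    """
    if not tree.rooted:
        raise AnalysisInputError("orthogroup delineation requires a rooted tree")

    orthogroups: list[Orthogroup] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        prefix = tree.name or "tree"
        return f"{prefix}.og{counter}"

    for mec in find_mecs(tree, taxa):
        n_r, n_o = _has_R_and_O(mec, taxa)
        if n_r < 1 or n_o < 1:
            continue
        if mec.parent is None:
            # whole tree eukaryotic: no prokaryotic context exists, so no
            # orthogroup can be delimited (analysis II handles such trees).
            continue
        context = _sister_context(mec, taxa)
        if context == "prokaryote-pure":
            orthogroups.append(
                Orthogroup(tree.name, next_id(), mec, "I", context, n_r, n_o)
            )
        else:
            children = mec.children
            competent = []
            if len(children) == 2:
                for child in children:
                    c_r, c_o = _has_R_and_O(child, taxa)
                    if c_r >= 1 and c_o >= 1:
                        competent.append((child, c_r, c_o))
            if len(children) == 2 and len(competent) == 2:
                # one split into two sister type II orthogroups; the split
                # node itself is not a duplication candidate for either.
                for child, c_r, c_o in competent:
                    orthogroups.append(
                        Orthogroup(tree.name, next_id(), child, "II", context, c_r, c_o)
                    )
            else:
                orthogroups.append(
                    Orthogroup(tree.name, next_id(), mec, "II", context, n_r, n_o)
                )
    return orthogroups
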