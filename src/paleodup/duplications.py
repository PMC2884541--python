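"""Inference of duplications predating the Archaeplastida/Opisthokonta split.

Two detection routes:

* :func:`detect_duplications` — node scan inside an orthogroup (families with
  a prokaryotic outgroup).  A node is a *relaxed* duplication candidate when
  it subtends two or more eukaryote-containing child clades of which at least
  one contains both R and O members.  The *stringent* criterion additionally
  requires at least one species with genes on both sides of the split, which
  guards against long-branch attraction: a misplaced fast-evolving gene
  creates an apparent basal split but cannot put the same species on both
  sides unless a genuine duplicate exists.
* :func:`detect_bipartition_duplication` — edge scan on eukaryote-only trees
  (no outgroup, so no root): any internal edge with R and O members on both
  sides witnesses a duplication regardless of root position.

Support gating: a node call is gated on the minimum support over its non-leaf
child clades (a leaf child carries no topological uncertainty; a node whose
children are all leaves gates on its own support); an edge call is gated on
the support of the edge itself.  An unknown support fails every threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

from .errors import AnalysisInputError
from .orthogroups import Orthogroup
from .taxa import Group, TaxonMap
from .trees import GeneTree, Node

__all__ = [
    "DuplicationCall",
    "detect_duplications",
    "scan_duplication_nodes",
    "detect_bipartition_duplication",
    "classify_pattern",
    "classify_protist_placement",
    "PATTERNS",
    "PLACEMENTS",
]

PATTERNS = ("RO_RO", "RO_R", "RO_O", "OTHER")
PLACEMENTS = (
    "PROTIST_IN_PARALOG_CLADE",
    "NO_RESOLUTION",
    "NO_PROTIST_HOMOLOG",
    "DUPLICATION_AFTER_PROTIST",
)


@dataclass(frozen=True)
class SideSummary:
    species: frozenset[str]
    has_R: bool
    has_O: bool


@dataclass(frozen=True)
class DuplicationCall:
    """One inferred duplication at a node (or edge) of a gene tree."""

    tree_id: Optional[str]
    orthogroup_id: Optional[str]
    node_leaves: frozenset[str]  # leaves under the call node / one edge side
    gate: Optional[float]  # gating support, None = unknown
    side1: SideSummary
    side2: SideSummary
    shared_species: frozenset[str]
    method: str = ""
    node: Optional[Node] = None

    @property
    def stringent_ok(self) -> bool:
        return bool(self.shared_species)


def _side_summary(leaves: Sequence[str], taxa: TaxonMap) -> SideSummary:
    groups = {taxa.group_of(l) for l in leaves}
    return SideSummary(
        species=taxa.species_set(leaves),
        has_R=Group.R in groups,
        has_O=Group.O in groups,
    )


def _gate_of(node: Node) -> Optional[float]:
    internal_children = [c for c in node.children if not c.is_leaf]
    if not internal_children:
        return node.support
    supports = [c.support for c in internal_children]
    if any(s is None for s in supports):
        return None
    return min(supports)


def _best_pair(node: Node, taxa: TaxonMap) -> Optional[tuple[list[str], list[str]]]:
    """Pick the pair of child clades that best satisfies the duplication
    criteria of a (possibly multifurcating) node: prefer pairs where at least
    one side has both R and O, then pairs maximizing the number of shared
    species; ties broken by child order.  Returns None when fewer than two
    children contain eukaryotic leaves."""
    euk_children = []
    for child in node.children:
        leaves = [l.label for l in child.leaves() if taxa.is_eukaryote(l.label)]
        if leaves:
            euk_children.append(leaves)
    if len(euk_children) < 2:
        return None
    best = None
    best_score = None
    for a, b in combinations(range(len(euk_children)), 2):
        la, lb = euk_children[a], euk_children[b]
        sa, sb = _side_summary(la, taxa), _side_summary(lb, taxa)
        pair_ro = (sa.has_R and sa.has_O) or (sb.has_R and sb.has_O)
        shared = sa.species & sb.species
        score = (pair_ro, len(shared) > 0, len(shared))
        if best_score is None or score > best_score:
            best_score = score
            best = (la, lb)
    return best


def _relaxed_candidate(node: Node, taxa: TaxonMap) -> bool:
    n_euk_children = 0
    any_ro_child = False
    for child in node.children:
        groups = {taxa.group_of(l.label) for l in child.leaves()}
        if groups - {Group.PROK}:
            n_euk_children += 1
        if Group.R in groups and Group.O in groups:
            any_ro_child = True
    return n_euk_children >= 2 and any_ro_child


def scan_duplication_nodes(
    root: Node,
    taxa: TaxonMap,
    threshold: float,
    stringent: bool,
    tree_id: Optional[str] = None,
    orthogroup_id: Optional[str] = None,
    method: str = "",
) -> list[DuplicationCall]:
    """Scan every internal node of a clade for accepted duplication calls.

    A call is accepted when the node satisfies the relaxed criterion, its
    gating support is known and ≥ ``threshold``, and — if ``stringent`` —
    its shared-species set is non-empty.  Preorder output.
    """
    calls: list[DuplicationCall] = []
    for node in root.preorder():
        if node.is_leaf or not _relaxed_candidate(node, taxa):
            continue
        gate = _gate_of(node)
        if gate is None or gate < threshold:
            continue
        pair = _best_pair(node, taxa)
        if pair is None:
            continue
        side1 = _side_summary(pair[0], taxa)
        side2 = _side_summary(pair[1], taxa)
        shared = side1.species & side2.species
        if stringent and not shared:
            continue
        calls.append(
            DuplicationCall(
                tree_id=tree_id,
                orthogroup_id=orthogroup_id,
                node_leaves=node.leaf_labels(),
                gate=gate,
                side1=side1,
                side2=side2,
                shared_species=shared,
                method=method,
                node=node,
            )
        )
    return calls


def detect_duplications(
    og: Orthogroup,
    taxa: TaxonMap,
    threshold: float,
    stringent: bool = False,
    method: str = "",
) -> list[DuplicationCall]:
    """Accepted duplication calls inside one orthogroup (analyses I/III)."""
    return scan_duplication_nodes(
        og.root,
        taxa,
        threshold,
        stringent,
        tree_id=og.tree_id,
        orthogroup_id=og.orthogroup_id,
        method=method,
    )


def detect_bipartition_duplication(
    tree: GeneTree,
    taxa: TaxonMap,
    threshold: float,
    stringent: bool = False,
    method: str = "",
) -> list[DuplicationCall]:
    """Edge scan on a eukaryote-only tree (analysis II).

    Every internal edge of the unrooted tree with R and O members on both
    sides is a duplication witness; the call is gated on the edge's support.
    """
    labels = tree.leaf_labels()
    for leaf in labels:
        if taxa.is_prokaryote(leaf):
            raise AnalysisInputError(
                f"prokaryotic leaf {leaf!r} present; use the outgroup-rooted "
                "orthogroup screen (analysis I/III) instead"
            )
    # one support per distinct unrooted edge (root-adjacent duplicates merged)
    edge_support: dict[frozenset[str], Optional[float]] = {}
    order: list[frozenset[str]] = []
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        side = node.leaf_labels()
        if side == labels:
            continue
        key = side if side in edge_support else (labels - side if (labels - side) in edge_support else side)
        if key in edge_support:
            if edge_support[key] is None:
                edge_support[key] = node.support
        else:
            edge_support[key] = node.support
            order.append(key)

    calls: list[DuplicationCall] = []
    for side in order:
        other = labels - side
        s1 = _side_summary(sorted(side), taxa)
        s2 = _side_summary(sorted(other), taxa)
        if not (s1.has_R and s1.has_O and s2.has_R and s2.has_O):
            continue
        gate = edge_support[side]
        if gate is None or gate < threshold:
            continue
        shared = s1.species & s2.species
        if stringent and not shared:
            continue
        calls.append(
            DuplicationCall(
                tree_id=tree.name,
                orthogroup_id=None,
                node_leaves=side,
                gate=gate,
                side1=s1,
                side2=s2,
                shared_species=shared,
                method=method,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _depth_below(root: Node, node: Node) -> int:
    depth = 0
    cursor = node
    while cursor is not root:
        cursor = cursor.parent
        if cursor is None:
            raise AnalysisInputError("call node is not inside the orthogroup")
        depth += 1
    return depth


def _is_ancestor(a: Node, b: Node) -> bool:
    cursor = b
    while cursor is not None:
        if cursor is a:
            return True
        cursor = cursor.parent
    return False


def classify_pattern(og: Orthogroup, calls: Sequence[DuplicationCall], taxa: TaxonMap) -> str:
    """Retention pattern of an orthogroup's duplication.

    Nested accepted calls are treated as one duplication chain and classified
    at the basal-most call; calls in disjoint subtrees mean independent
    duplications and return ``"OTHER"``.  For the basal call with sides S1
    (the side containing both R and O) and S2: both R+O → ``RO_RO``; S2 with
    R only → ``RO_R``; with O only → ``RO_O``; anything else → ``OTHER``.
    """
    if not calls:
        raise AnalysisInputError("no duplication to classify")
    nodes = [c.node for c in calls]
    if any(n is None for n in nodes):
        raise AnalysisInputError("calls must carry node references")
    ordered = sorted(zip(nodes, calls), key=lambda nc: _depth_below(og.root, nc[0]))
    for (a, _), (b, _) in zip(ordered, ordered[1:]):
        if not _is_ancestor(a, b):
            return "OTHER"
    basal = ordered[0][1]
    s1, s2 = basal.side1, basal.side2
    if not (s1.has_R and s1.has_O):
        s1, s2 = s2, s1
    if not (s1.has_R and s1.has_O):
        return "OTHER"
    if s2.has_R and s2.has_O:
        return "RO_RO"
    if s2.has_R:
        return "RO_R"
    if s2.has_O:
        return "RO_O"
    return "OTHER"


def _mrca(tree: GeneTree, labels: frozenset[str]) -> Node:
    by_label = {l.label: l for l in tree.leaves()}
    missing = labels - by_label.keys()
    if missing:
        raise AnalysisInputError(f"leaves missing from tree: {sorted(missing)}")
    paths = []
    for label in labels:
        path = []
        cursor = by_label[label]
        while cursor is not None:
            path.append(cursor)
            cursor = cursor.parent
        paths.append(list(reversed(path)))
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        node = paths[0][depth]
        if all(p[depth] is node for p in paths):
            mrca = node
        else:
            break
    return mrca


def classify_protist_placement(
    tree: GeneTree,
    paralog_leaves: tuple[frozenset[str], frozenset[str]],
    taxa: TaxonMap,
    threshold: float,
) -> str:
    """Place a previously-called duplication relative to protist homologs.

    ``tree`` is a (rooted) re-estimated phylogeny that includes protist
    sequences; ``paralog_leaves`` are the leaf sets of the two paralogous
    clades from the original orthogroup, re-identified here as the smallest
    clades containing each set.

    * no protist leaf in the tree → ``NO_PROTIST_HOMOLOG``
    * a protist inside a re-identified paralog clade whose support ≥
      threshold → ``PROTIST_IN_PARALOG_CLADE`` (duplication precedes the
      protist divergence)
    * all protists attaching outside the smallest clade containing both
      paralog clades, that clade supported ≥ threshold →
      ``DUPLICATION_AFTER_PROTIST``
    * otherwise → ``NO_RESOLUTION``
    """
    protists = {l.label for l in tree.leaves() if taxa.is_protist(l.label)}
    if not protists:
        return "NO_PROTIST_HOMOLOG"
    clades = [_mrca(tree, side) for side in paralog_leaves]
    for clade in clades:
        inside = protists & clade.leaf_labels()
        if inside and clade.support is not None and clade.support >= threshold:
            return "PROTIST_IN_PARALOG_CLADE"
    union = _mrca(tree, paralog_leaves[0] | paralog_leaves[1])
    if not (protists & union.leaf_labels()):
        if union.support is not None and union.support >= threshold:
            return "DUPLICATION_AFTER_PROTIST"
    return "NO_RESOLUTION"
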