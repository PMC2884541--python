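"""Independent brute-force oracles and tree generators for the test suite.

Everything here evaluates the duplication criteria directly from their
definitions using plain set arithmetic over leaf labels, deliberately
avoiding the package's scanning code paths.
"""

from __future__ import annotations

import numpy as np

from paleodup.taxa import Group
from paleodup.trees import GeneTree, Node

EUK_SPECIES = ["Ath", "Ppa", "Cre", "Hsa", "Tru", "Spu", "Sce", "Spo"]
ALL_SPECIES = EUK_SPECIES + ["Eco", "Rpr", "Bsu", "Mac", "Sso", "Pae"]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def random_labeled_tree(rng: np.random.Generator, n_leaves: int, euk_only=None):
    """A random (possibly multifurcating) tree with random species labels and
    random supports (10% unknown).  Returns (tree, is_eukaryote_only)."""
    if euk_only is None:
        euk_only = bool(rng.random() < 0.5)
    pool = EUK_SPECIES if euk_only else ALL_SPECIES
    nodes = [
        Node(label=f"{rng.choice(pool)}_{i}") for i in range(n_leaves)
    ]
    while len(nodes) > 1:
        k = min(len(nodes), 2 if rng.random() < 0.8 else 3)
        joint = Node()
        for _ in range(k):
            joint.add_child(nodes.pop(int(rng.integers(len(nodes)))))
        if rng.random() < 0.9:
            joint.support = float(rng.integers(0, 101))
        nodes.append(joint)
    root = nodes[0]
    root.support = None
    return GeneTree(root), euk_only


def all_unrooted_binary_trees(labels: list[str]) -> list[Node]:
    """Every unrooted binary topology on the given leaf labels, represented
    with a basal trifurcation.  Counts follow (2n-5)!!: 3, 15, 105, 945,
    10395 for n = 4..8."""
    assert len(labels) >= 3
    base = Node()
    for lab in labels[:3]:
        base.add_child(Node(label=lab))
    trees = [base]
    for lab in labels[3:]:
        grown = []
        for tree in trees:
            edges = [n for n in tree.preorder() if n is not tree]
            for i in range(len(edges)):
                dup = tree.copy()
                dup_edges = [n for n in dup.preorder() if n is not dup]
                target = dup_edges[i]
                parent = target.parent
                joint = Node()
                parent.children = [joint if c is target else c for c in parent.children]
                joint.parent = parent
                joint.add_child(target)
                joint.add_child(Node(label=lab))
                grown.append(dup)
        trees = grown
    return trees


# ---------------------------------------------------------------------------
# brute-force duplication predicates
# ---------------------------------------------------------------------------


def _groups_of(labels, taxa):
    return {taxa.group_of(l) for l in labels}


def _species_of(labels, taxa):
    return {taxa.species_of(l) for l in labels}


def brute_force_node_calls(tree: GeneTree, taxa, threshold, stringent):
    """Accepted duplication nodes, evaluated verbatim from the criteria."""
    accepted = set()
    for node in tree.root.preorder():
        if node.is_leaf:
            continue
        child_leafsets = [[l.label for l in c.leaves()] for c in node.children]
        euk_children = [
            ls for ls in child_leafsets
            if any(not taxa.is_prokaryote(l) for l in ls)
        ]
        if len(euk_children) < 2:
            continue
        if not any(
            {Group.R, Group.O} <= _groups_of(ls, taxa) for ls in child_leafsets
        ):
            continue
        internal = [c for c in node.children if not c.is_leaf]
        if internal:
            if any(c.support is None for c in internal):
                continue
            gate = min(c.support for c in internal)
        else:
            gate = node.support
        if gate is None or gate < threshold:
            continue
        if stringent:
            euk_sides = [
                [l for l in ls if not taxa.is_prokaryote(l)] for ls in child_leafsets
            ]
            euk_sides = [s for s in euk_sides if s]
            ok = False
            for i in range(len(euk_sides)):
                for j in range(i + 1, len(euk_sides)):
                    pair_ro = (
                        {Group.R, Group.O} <= _groups_of(euk_sides[i], taxa)
                        or {Group.R, Group.O} <= _groups_of(euk_sides[j], taxa)
                    )
                    shared = _species_of(euk_sides[i], taxa) & _species_of(
                        euk_sides[j], taxa
                    )
                    if pair_ro and shared:
                        ok = True
            if not ok:
                continue
        accepted.add(node.leaf_labels())
    return accepted


def brute_force_edge_calls(tree: GeneTree, taxa, threshold, stringent):
    """Accepted bipartition edges of a eukaryote-only unrooted tree."""
    full = tree.leaf_labels()
    # edge support per bipartition, merging root-adjacent duplicates
    support = {}
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        side = node.leaf_labels()
        if side == full:
            continue
        key = frozenset((side, full - side))
        if key not in support or support[key] is None:
            support[key] = node.support
    accepted = set()
    for key, sup in support.items():
        side, other = tuple(key) if len(key) == 2 else (next(iter(key)),) * 2
        g1, g2 = _groups_of(side, taxa), _groups_of(other, taxa)
        if not ({Group.R, Group.O} <= g1 and {Group.R, Group.O} <= g2):
            continue
        if sup is None or sup < threshold:
            continue
        if stringent and not (_species_of(side, taxa) & _species_of(other, taxa)):
            continue
        accepted.add(side)
    return accepted
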