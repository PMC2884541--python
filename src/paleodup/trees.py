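"""Gene-tree data model, newick I/O and outgroup-based rerooting.

Trees are held as a simple mutable node structure.  Two newick dialects are
supported: ``"support"`` (the default; a numeric label on an internal node is
read as that node's support value, the convention emitted by common NJ/ML
programs) and ``"bare"`` (internal labels are kept as plain labels and no
support is inferred).

Support values live on the edge *above* a node: ``node.support`` is the
support of the bipartition induced by removing the edge between ``node`` and
its parent.  Rerooting moves supports together with their edges, so the
multiset of (bipartition, support) pairs of the unrooted tree is invariant
under rerooting.

An unrooted tree is represented as a rooted structure with a basal
trifurcation; every operation that is meaningful only on unrooted trees works
on edges (bipartitions), so the representation does not affect results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

from .errors import NewickParseError, OutgroupRootingError, TreeValidationError
from .taxa import TaxonMap

__all__ = ["Node", "GeneTree", "parse_newick", "write_newick", "root_by_prokaryotes"]


@dataclass
class Node:
    """A tree node.  ``length`` and ``support`` describe the parent edge."""

    label: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = field(default=None, repr=False, compare=False)

    # -- structure -----------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    def copy(self) -> "Node":
        dup = Node(self.label, self.length, self.support)
        for child in self.children:
            dup.add_child(child.copy())
        return dup


class GeneTree:
    """A gene-family phylogeny with unique leaf labels.

    Parameters
    ----------
    root:
        Root node of the (possibly unrooted-as-trifurcation) structure.
    rooted:
        Whether the basal node is a genuine root.  A basal bifurcation is
        treated as rooted, a basal multifurcation as unrooted, unless
        overridden explicitly.
    """

    def __init__(self, root: Node, rooted: Optional[bool] = None, name: Optional[str] = None):
        self.root = root
        self.name = name
        if rooted is None:
            rooted = len(root.children) <= 2
        self.rooted = rooted
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        labels = [n.label for n in self.root.preorder() if n.is_leaf]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeValidationError("every leaf must carry a label")
        seen = set()
        for lab in labels:
            if lab in seen:
                raise TreeValidationError(f"duplicate leaf label: {lab!r}")
            seen.add(lab)
        for node in self.root.preorder():
            if node.support is not None and not (0.0 <= node.support <= 100.0):
                raise TreeValidationError(
                    f"support {node.support} outside [0, 100]"
                )
            if node.length is not None and node.length < 0:
                raise TreeValidationError(f"negative branch length {node.length}")

    # -- convenience ---------------------------------------------------
    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.root.preorder() if not n.is_leaf]

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy(), rooted=self.rooted, name=self.name)

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """All non-trivial bipartitions of the unrooted tree, each as a
        frozenset of the two leaf-label sides."""
        all_leaves = self.leaf_labels()
        out = set()
        for node in self.root.preorder():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_labels()
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                out.add(frozenset((side, other)))
        return out

    def __eq__(self, other) -> bool:  # structural equality via canonical newick
        if not isinstance(other, GeneTree):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    def __repr__(self) -> str:
        return f"GeneTree({len(self.leaves())} leaves, rooted={self.rooted})"


# ---------------------------------------------------------------------------
# newick parsing
# ---------------------------------------------------------------------------

_LABEL_FORBIDDEN = set("(),:;[]' \t\n")


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


class _Parser:
    def __init__(self, text: str, dialect: str):
        self.text = text
        self.pos = 0
        self.dialect = dialect

    def error(self, message: str) -> NewickParseError:
        return NewickParseError(message, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] in " \t\r\n":
            self.pos += 1

    def read_label(self) -> str:
        start = self.pos
        if self.peek() == "'":
            self.pos += 1
            while self.pos < len(self.text) and self.text[self.pos] != "'":
                self.pos += 1
            if self.pos >= len(self.text):
                raise self.error("unterminated quoted label")
            label = self.text[start + 1 : self.pos]
            self.pos += 1
            return label
        while self.pos < len(self.text) and self.text[self.pos] not in _LABEL_FORBIDDEN:
            self.pos += 1
        return self.text[start : self.pos]

    def read_number(self, what: str) -> float:
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in _LABEL_FORBIDDEN:
            self.pos += 1
        token = self.text[start : self.pos]
        try:
            return float(token)
        except ValueError:
            self.pos = start
            raise self.error(f"expected a numeric {what}, got {token!r}")

    def parse_clade(self) -> Node:
        self.skip_ws()
        node = Node()
        if self.peek() == "(":
            self.pos += 1
            while True:
                node.add_child(self.parse_clade())
                self.skip_ws()
                if self.peek() == ",":
                    self.pos += 1
                    continue
                if self.peek() == ")":
                    self.pos += 1
                    break
                raise self.error("expected ',' or ')'")
            label = self.read_label()
            if label:
                if self.dialect == "support" and _is_number(label):
                    node.support = float(label)
                else:
                    node.label = label
        else:
            label = self.read_label()
            if not label:
                raise self.error("expected a leaf label")
            node.label = label
        self.skip_ws()
        if self.peek() == ":":
            self.pos += 1
            node.length = self.read_number("branch length")
        return node

    def parse(self) -> Node:
        root = self.parse_clade()
        self.skip_ws()
        if self.peek() != ";":
            raise self.error("expected ';' terminator")
        self.pos += 1
        self.skip_ws()
        if self.pos != len(self.text):
            raise self.error("trailing characters after ';'")
        return root


def parse_newick(text: str, dialect: str = "support", name: Optional[str] = None) -> GeneTree:
    """Parse a newick string into a :class:`GeneTree`.

    With ``dialect="support"`` a numeric internal-node label is stored as the
    node's support and must lie in [0, 100]; with ``dialect="bare"`` internal
    labels are kept verbatim and no supports are set.

    Raises
    ------
    NewickParseError
        On malformed input, with the character offset of the failure.
    TreeValidationError
        On duplicate leaf labels or out-of-range support values.
    """
    if dialect not in ("support", "bare"):
        raise ValueError(f"unknown dialect {dialect!r}")
    root = _Parser(text, dialect).parse()
    return GeneTree(root, name=name)


# ---------------------------------------------------------------------------
# newick writing
# ---------------------------------------------------------------------------

def _format_number(value: float) -> str:
    if value == int(value):
        return str(int(value))
    return repr(value)


def _sort_key(node: Node) -> str:
    return min(n.label for n in node.leaves())


def _write_clade(node: Node, dialect: str, parts: list[str]) -> None:
    if node.is_leaf:
        parts.append(node.label)
    else:
        parts.append("(")
        for i, child in enumerate(sorted(node.children, key=_sort_key)):
            if i:
                parts.append(",")
            _write_clade(child, dialect, parts)
        parts.append(")")
        if node.label is not None:
            parts.append(node.label)
        elif dialect == "support" and node.support is not None:
            parts.append(_format_number(node.support))
    if node.length is not None:
        parts.append(":" + _format_number(node.length))


def write_newick(tree: GeneTree, dialect: str = "support") -> str:
    """Serialize a tree deterministically (children ordered by their
    lexicographically smallest descendant leaf label)."""
    tree.validate()
    parts: list[str] = []
    _write_clade(tree.root, dialect, parts)
    parts.append(";")
    return "".join(parts)


# ---------------------------------------------------------------------------
# rerooting
# ---------------------------------------------------------------------------

def _combine_lengths(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None:
        return b
    if b is None:
        return a
    return a + b


def _invert(node: Node, excluded: Node) -> tuple[Node, bool]:
    """Rebuild the side of the tree 'above' ``excluded`` as a subtree hanging
    from the edge (node, excluded).  Returns (subtree, was_spliced): a splice
    happens when the old root had degree 2 and disappears from the unrooted
    topology."""
    kept = [c.copy() for c in node.children if c is not excluded]
    if node.parent is None:
        if len(kept) == 1:
            return kept[0], True
        new = Node(label=node.label)
        new.children = kept
        for child in new.children:
            child.parent = new
        return new, False
    up, spliced = _invert(node.parent, node)
    # The edge (node.parent, node) changes direction: its attributes, stored
    # on `node` in the old orientation, now belong to `up` as a child here.
    if spliced:
        # `up` already carries the attrs of the old root's other child; the
        # two half-edges around the old root are one unrooted edge.
        if up.support is None:
            up.support = node.support
        up.length = _combine_lengths(up.length, node.length)
    else:
        up.support = node.support
        up.length = node.length
    new = Node(label=node.label)
    new.children = kept + [up]
    for child in new.children:
        child.parent = new
    return new, False


def reroot_at_edge(tree: GeneTree, side_leaves: frozenset[str]) -> GeneTree:
    """Root the tree on the edge whose induced bipartition has ``side_leaves``
    on one side.  The new root has exactly two children; both carry the
    support of the split edge, and its length (if any) is halved between
    them."""
    target = None
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        if node.leaf_labels() == side_leaves:
            target = node
            break
    if target is None:
        # the complement may be stored instead (root-adjacent edges)
        complement = tree.leaf_labels() - side_leaves
        for node in tree.root.preorder():
            if node is not tree.root and node.leaf_labels() == complement:
                target = node
                break
    if target is None:
        raise ValueError("no edge induces the requested bipartition")

    below = target.copy()
    above, spliced = _invert(target.parent, target)
    if spliced:
        # target was a child of a degree-2 root: `above` is the old sibling
        # and already carries its own half-edge attributes.
        edge_length = _combine_lengths(target.length, above.length)
        if above.support is None:
            above.support = target.support
    else:
        edge_length = target.length
        above.support = target.support
    half = None if edge_length is None else edge_length / 2.0
    below.length = half
    above.length = half
    root = Node()
    root.children = [below, above]
    below.parent = root
    above.parent = root
    return GeneTree(root, rooted=True, name=tree.name)


def _edge_bipartitions(tree: GeneTree) -> list[frozenset[str]]:
    """One representative leaf-set per distinct edge of the unrooted tree."""
    all_leaves = tree.leaf_labels()
    seen: set[frozenset[str]] = set()
    edges: list[frozenset[str]] = []
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        side = node.leaf_labels()
        if side in seen or (all_leaves - side) in seen or side == all_leaves:
            continue
        seen.add(side)
        edges.append(side)
    return edges


_MIXED_PENALTY = 10**9


def _outgroup_score(side: frozenset[str], taxa: TaxonMap) -> int:
    n_prok = sum(1 for leaf in side if taxa.is_prokaryote(leaf))
    n_euk = len(side) - n_prok
    if n_euk == 0:
        return n_prok
    return n_prok - n_euk - _MIXED_PENALTY


def root_by_prokaryotes(tree: GeneTree, taxa: TaxonMap) -> GeneTree:
    """Root a gene tree on its prokaryotic outgroup.

    Every edge of the unrooted tree is scored in both orientations: a side
    containing only prokaryotic leaves scores its prokaryote count; a side
    containing any eukaryotic leaf scores (prokaryotes - eukaryotes) minus a
    penalty large enough that any prokaryote-pure side beats every mixed
    side.  The edge/orientation with the best score becomes the root edge,
    with the winning side as the outgroup; ties are broken by the
    lexicographically smallest sorted leaf-label tuple of the outgroup side.
    Deterministic by construction.
    """
    labels = tree.leaf_labels()
    prok = {leaf for leaf in labels if taxa.is_prokaryote(leaf)}
    if not prok:
        raise OutgroupRootingError(
            "tree has no prokaryotic leaves; cannot outgroup-root "
            "(use the bipartition method for eukaryote-only families)"
        )
    if prok == labels:
        raise OutgroupRootingError("tree has no eukaryotic leaves")

    best: Optional[tuple[int, tuple[str, ...], frozenset[str]]] = None
    for side in _edge_bipartitions(tree):
        for candidate in (side, labels - side):
            if not candidate or candidate == labels:
                continue
            score = _outgroup_score(candidate, taxa)
            key = (-score, tuple(sorted(candidate)))
            if best is None or key < (best[0], best[1]):
                best = (key[0], key[1], candidate)
    assert best is not None
    return reroot_at_edge(tree, best[2])
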