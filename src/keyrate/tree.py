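"""Rooted phylogenetic trees with branch lengths.

The tree model is deliberately minimal: a rooted tree of :class:`TreeNode`
objects with arbitrary arity (polytomies are first-class), non-negative
branch lengths on every non-root node, and unique non-empty leaf labels.
Ultrametricity (equal root-to-leaf path lengths, the defining property of a
chronogram) is a checkable predicate, never an assumption.

Newick parsing is delegated to dendropy; writing is a short deterministic
recursion so that parse -> write -> parse round-trips topology, labels and
branch lengths to 12 significant digits.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "TreeNode",
    "PhyloTree",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "is_ultrametric",
]


class NewickParseError(ValueError):
    """Raised for malformed Newick input or tree invariant violations."""


class TreeNode:
    """A node in a rooted tree.

    ``length`` is the length of the branch subtending this node (``None``
    for the root, or when the source Newick carried no length on this edge).
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind} length={self.length}>"


class PhyloTree:
    """A validated rooted tree.

    Invariants enforced on construction: unique non-empty leaf labels and
    non-negative branch lengths on all non-root nodes. Zero-length branches
    are allowed (chronograms routinely contain near-zero edges).
    """

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self._validate()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    # -- traversal ----------------------------------------------------

    def preorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def postorder(self) -> Iterator[TreeNode]:
        # reversed preorder visits children before parents; recursion-free
        # so caterpillar trees of any depth are safe
        return reversed(self.preorder())

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    # -- metrics ------------------------------------------------------

    @property
    def total_length(self) -> float:
        """Sum of branch lengths over all non-root nodes."""
        return sum(n.length or 0.0 for n in self.preorder() if n.parent is not None)

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path length for every leaf."""
        depth: dict[int, float] = {id(self.root): 0.0}
        out: dict[str, float] = {}
        for node in self.preorder():
            if node.parent is not None:
                depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
            if node.is_leaf:
                out[node.label] = depth[id(node)]
        return out

    def is_ultrametric(self, rel_tolerance: float = 1e-6) -> bool:
        return is_ultrametric(self, rel_tolerance)

    # -- manipulation -------------------------------------------------

    def copy(self) -> "PhyloTree":
        def _clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for child in node.children:
                new.add_child(_clone(child))
            return new

        return PhyloTree(_clone(self.root))

    def rerooted_at(self, node_label: str) -> "PhyloTree":
        """Return a copy rerooted at the named internal node.

        The parent chain above the target is reversed edge by edge; each
        reversed edge keeps its length, so total branch length (and
        unordered parsimony, which is unrooted) is preserved. Nodes of
        out-degree one that the reversal may create are kept, not
        suppressed.
        """
        clone = self.copy()
        target = None
        for n in clone.preorder():
            if n.label == node_label and not n.is_leaf:
                target = n
                break
        if target is None:
            raise ValueError(f"no internal node labelled {node_label!r}")
        if target is clone.root:
            return clone

        path: list[TreeNode] = []
        n: Optional[TreeNode] = target
        while n is not None:
            path.append(n)
            n = n.parent
        # the reversed edge child<-parent keeps the length the old child carried
        reversed_len = {id(child): child.length for child in path[:-1]}
        for child, parent in zip(path, path[1:]):
            parent.children.remove(child)
            child.children.append(parent)
        for child, parent in zip(path, path[1:]):
            parent.parent = child
            parent.length = reversed_len[id(child)]
        target.parent = None
        target.length = None
        return PhyloTree(target)

    # -- output -------------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.preorder():
            if node.parent is not None and node.length is not None and node.length < 0:
                raise NewickParseError(
                    f"negative branch length {node.length!r} on node {node.label!r}"
                )
            if node.is_leaf:
                if not node.label:
                    raise NewickParseError("leaf with empty label")
                if node.label in seen:
                    raise NewickParseError(f"duplicate leaf label {node.label!r}")
                seen.add(node.label)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_leaves} leaves>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Quoted and unquoted labels are accepted; polytomies are preserved, not
    arbitrarily resolved. Raises :class:`NewickParseError` for malformed
    structure, duplicate leaf labels, or negative branch lengths.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        # suppress taxon creation so duplicate-label diagnostics stay ours
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def _convert(dnode: dendropy.Node) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(_convert(dchild))
        return node

    root = _convert(dtree.seed_node)
    root.length = None  # a root edge length has no meaning on a rooted tree
    return PhyloTree(root)


_NEWICK_SPECIAL = set("()[]{}/\\,;:=*'\"`<>^ \t\n")


def _quote(label: str) -> str:
    if any(c in _NEWICK_SPECIAL for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree as Newick, branch lengths to 12 significant digits."""

    def _write(node: TreeNode, out: io.StringIO) -> None:
        if node.children:
            out.write("(")
            for i, child in enumerate(node.children):
                if i:
                    out.write(",")
                _write(child, out)
            out.write(")")
            if node.label:
                out.write(_quote(node.label))
        else:
            out.write(_quote(node.label))
        if node.length is not None:
            out.write(":" + format(node.length, ".12g"))

    buf = io.StringIO()
    _write(tree.root, buf)
    buf.write(";")
    return buf.getvalue()


def is_ultrametric(tree: PhyloTree, rel_tolerance: float = 1e-6) -> bool:
    """True iff all root-to-leaf path lengths agree within a relative tolerance.

    The test is ``max - min <= rel_tolerance * max``; a single-leaf tree, or
    one whose depths are all zero, is trivially ultrametric.
    """
    depths = list(tree.leaf_depths().values())
    hi, lo = max(depths), min(depths)
    if hi == 0.0:
        return True
    return (hi - lo) <= rel_tolerance * hi
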