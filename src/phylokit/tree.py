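"""The two-class tree model: :class:`Node` and :class:`Tree`.

The design goal is scale: a tree with 10^6 leaves must load, traverse and
manipulate comfortably on a desktop. Nodes therefore carry only their local
data — label, branch length, parent/children links and a lazily allocated
attribute map — and every algorithm in the package is iterative, never
recursive, so depth is bounded by heap memory rather than the interpreter's
recursion limit.

Conventions
-----------
* A node is a leaf iff it has no children.
* ``edge_length`` is the length of the edge to the parent. ``None`` (absent)
  is distinct from ``0.0`` in storage, but all path arithmetic (depths,
  patristic distances) treats absent as zero.
* Children are an ordered list; every operation preserves insertion order, so
  serialization and traversal are deterministic.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterator, Optional

from .errors import LabelLookupError, TreeStructureError

__all__ = ["Node", "Tree", "isomorphic"]


class Node:
    """One vertex of a tree: local data plus parent/children links."""

    __slots__ = ("label", "edge_length", "parent", "children", "_attributes")

    def __init__(self, label: Optional[str] = None,
                 edge_length: Optional[float] = None):
        if edge_length is not None and edge_length < 0:
            raise ValueError(f"edge_length must be >= 0, got {edge_length}")
        self.label = label
        self.edge_length = edge_length
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self._attributes: Optional[dict] = None

    @property
    def attributes(self) -> dict:
        """Free-form annotation map (comments etc.); ignored by all algorithms.

        Allocated on first access so that bare nodes stay small.
        """
        if self._attributes is None:
            self._attributes = {}
        return self._attributes

    def is_leaf(self) -> bool:
        return not self.children

    def is_root(self) -> bool:
        return self.parent is None

    @property
    def num_children(self) -> int:
        return len(self.children)

    def add_child(self, child: "Node") -> None:
        """Append ``child`` to this node's children and link it back.

        Raises :class:`TreeStructureError` if ``child`` already has a parent or
        if attaching it would create a cycle (i.e. ``child`` is an ancestor of
        this node).
        """
        if child.parent is not None:
            raise TreeStructureError("child already has a parent; detach it first")
        if child is self:
            raise TreeStructureError("cannot attach a node to itself")
        # a parentless node can only be an ancestor of self if it is the root
        # of self's component; skip the walk for childless nodes, which cannot
        # be anyone's ancestor (keeps bulk construction O(1) per attachment)
        if child.children:
            anc = self
            while anc.parent is not None:
                anc = anc.parent
            if anc is child:
                raise TreeStructureError(
                    "cannot attach a node to its own descendant (cycle)")
        self.children.append(child)
        child.parent = self

    def detach(self) -> "Node":
        """Unlink this node from its parent and return it (root of its subtree)."""
        if self.parent is None:
            raise TreeStructureError("cannot detach a root node")
        self.parent.children.remove(self)
        self.parent = None
        return self

    def ancestors(self, include_self: bool = False) -> Iterator["Node"]:
        """Yield ancestors from (optionally) this node up to the root."""
        node = self if include_self else self.parent
        while node is not None:
            yield node
            node = node.parent

    def depth(self) -> float:
        """Weighted distance from the root (missing edge lengths count as 0)."""
        total = 0.0
        node = self
        while node.parent is not None:
            if node.edge_length is not None:
                total += node.edge_length
            node = node.parent
        return total

    def __repr__(self) -> str:
        bits = [f"label={self.label!r}"]
        if self.edge_length is not None:
            bits.append(f"edge_length={self.edge_length}")
        bits.append(f"children={len(self.children)}")
        return f"<Node {' '.join(bits)}>"

    def __str__(self) -> str:
        return self.label if self.label is not None else ""


class Tree:
    """A root node plus a rootedness flag; the traversal/manipulation handle.

    Most functionality lives in sibling modules and is re-exposed here as thin
    methods so that common workflows read naturally::

        tree = read_tree_newick("taxa.nwk.gz")
        for node in tree.traverse_postorder():
            ...
        print(tree.height())
    """

    __slots__ = ("root", "is_rooted")

    def __init__(self, root: Optional[Node] = None, is_rooted: bool = True):
        self.root = root if root is not None else Node()
        if self.root.parent is not None:
            raise TreeStructureError("Tree root must not have a parent")
        self.is_rooted = is_rooted

    # -- structural queries -------------------------------------------------

    def num_nodes(self) -> tuple[int, int, int]:
        """Return ``(total, leaves, internal)`` node counts via a full traversal."""
        total = leaves = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            total += 1
            if node.children:
                stack.extend(node.children)
            else:
                leaves += 1
        return total, leaves, total - leaves

    def leaf_map(self) -> dict[str, Node]:
        """Map each leaf label to its leaf node.

        Raises :class:`LabelLookupError` on duplicate leaf labels; unlabeled
        leaves are skipped (they cannot be addressed by label).
        """
        mapping: dict[str, Node] = {}
        dupes = set()
        for leaf in self.traverse_leaves():
            if leaf.label is None:
                continue
            if leaf.label in mapping:
                dupes.add(leaf.label)
            mapping[leaf.label] = leaf
        if dupes:
            raise LabelLookupError(
                f"duplicate leaf labels: {sorted(dupes)}", missing=sorted(dupes))
        return mapping

    def contains(self, node: Node) -> bool:
        """True if ``node`` belongs to this tree (walks up to the root)."""
        while node.parent is not None:
            node = node.parent
        return node is self.root

    def copy(self) -> "Tree":
        """Deep copy of the tree (labels, lengths and attributes copied)."""
        new_root = Node(self.root.label, self.root.edge_length)
        if self.root._attributes:
            new_root._attributes = dict(self.root._attributes)
        stack = [(self.root, new_root)]
        while stack:
            old, new = stack.pop()
            for child in old.children:
                c = Node(child.label, child.edge_length)
                if child._attributes:
                    c._attributes = dict(child._attributes)
                new.children.append(c)
                c.parent = new
                stack.append((child, c))
        return Tree(new_root, is_rooted=self.is_rooted)

    # -- delegating conveniences (implementations live in sibling modules) --

    def traverse_preorder(self):
        from .traverse import traverse_preorder
        return traverse_preorder(self)

    def traverse_postorder(self):
        from .traverse import traverse_postorder
        return traverse_postorder(self)

    def traverse_inorder(self):
        from .traverse import traverse_inorder
        return traverse_inorder(self)

    def traverse_levelorder(self):
        from .traverse import traverse_levelorder
        return traverse_levelorder(self)

    def traverse_rootdistorder(self, ascending: bool = True):
        from .traverse import traverse_rootdistorder
        return traverse_rootdistorder(self, ascending=ascending)

    def traverse_leaves(self):
        from .traverse import traverse_leaves
        return traverse_leaves(self)

    def newick(self, precision: Optional[int] = None) -> str:
        from .newick import write_tree_newick
        return write_tree_newick(self, precision=precision)

    def height(self) -> float:
        from .stats import height
        return height(self)

    def mrca(self, labels) -> Node:
        from .stats import mrca
        return mrca(self, labels)

    def distance_matrix(self):
        from .stats import distance_matrix
        return distance_matrix(self)

    def reroot(self, node: Node, length_along_edge: Optional[float] = None) -> "Tree":
        from .manipulate import reroot
        return reroot(self, node, length_along_edge)

    def extract_tree_with(self, leaf_labels) -> "Tree":
        from .manipulate import extract_tree_with
        return extract_tree_with(self, leaf_labels)

    def lineages_through_time(self, output_path=None, log_scale_counts=False,
                              color="blue"):
        """Compute the LTT series and render it; returns the matplotlib Axes."""
        from .ltt import ltt, plot_ltt
        return plot_ltt(ltt(self), output_path=output_path,
                        log_scale_counts=log_scale_counts, color=color)

    def __repr__(self) -> str:
        total, leaves, _ = self.num_nodes()
        return f"<Tree nodes={total} leaves={leaves} rooted={self.is_rooted}>"

    def __str__(self) -> str:
        return self.newick()


# -- comparison -------------------------------------------------------------

def _length_eq(a: Optional[float], b: Optional[float], rel_tol: float) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return math.isclose(a, b, rel_tol=rel_tol, abs_tol=rel_tol)


def isomorphic(t1: Tree, t2: Tree, rel_tol: float = 1e-9,
               ordered: bool = False) -> bool:
    """Label-preserving isomorphism with edge lengths equal within ``rel_tol``.

    With ``ordered=True`` child order must match exactly (appropriate for
    round-trip checks, where order is preserved). The default unordered mode
    matches internal nodes by their descendant leaf-label set and therefore
    requires leaf labels to be unique and present in both trees.
    """
    if ordered:
        stack = [(t1.root, t2.root)]
        while stack:
            a, b = stack.pop()
            if a.label != b.label or len(a.children) != len(b.children):
                return False
            if not _length_eq(a.edge_length, b.edge_length, rel_tol):
                return False
            stack.extend(zip(a.children, b.children))
        return True

    sig1 = _clade_signature(t1)
    sig2 = _clade_signature(t2)
    if sig1.keys() != sig2.keys():
        return False
    for clade, entries1 in sig1.items():
        entries2 = sig2[clade]
        if len(entries1) != len(entries2):
            return False
        for (lab1, len1), (lab2, len2) in zip(entries1, entries2):
            if lab1 != lab2 or not _length_eq(len1, len2, rel_tol):
                return False
    return True


def _clade_signature(tree: Tree):
    """Map each clade (frozenset of descendant leaf labels) to its node data.

    Unifurcation chains share a clade; their entries are kept in root-to-leaf
    order so chains compare positionally.
    """
    from .traverse import traverse_postorder

    clades: dict[frozenset, list] = {}
    below: dict[int, frozenset] = {}
    order: dict[int, int] = {}
    for rank, node in enumerate(tree.traverse_preorder()):
        order[id(node)] = rank
    for node in traverse_postorder(tree):
        if node.is_leaf():
            if node.label is None:
                raise ValueError("unordered comparison requires labeled leaves")
            leaves = frozenset((node.label,))
        else:
            leaves = frozenset().union(*(below.pop(id(c)) for c in node.children))
        below[id(node)] = leaves
        clades.setdefault(leaves, []).append(
            (order[id(node)], node.label, node.edge_length))
    for entries in clades.values():
        entries.sort()  # chain order = discovery (root first)
        entries[:] = [(lab, ln) for _, lab, ln in entries]
    # duplicate leaf labels make clade sets collide meaninglessly
    leaf_labels = Counter(l.label for l in tree.traverse_leaves())
    if any(v > 1 for v in leaf_labels.values()):
        raise ValueError("unordered comparison requires unique leaf labels")
    return clades
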