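"""Structure-changing operations: rerooting, pruning, extraction, cleanup.

Conventions shared by these operations:

* ``extract_tree_with`` COPIES (the input tree is untouched);
  ``prune_leaves``, ``reroot`` and ``suppress_unifurcations`` work IN PLACE
  and return the same :class:`~phylokit.tree.Tree` handle.
* merging edge lengths across a suppressed node treats ``None`` as 0 but
  yields ``None`` only when both operands are absent, preserving the
  stored/absent distinction where it can.
* rerooting reverses the edges on the old root path with lengths preserved,
  so the total branch length and every leaf-to-leaf patristic distance are
  conserved (a stored length on the OLD root itself — a "root edge" — has no
  parent edge to migrate to and is dropped).
"""

from __future__ import annotations

from typing import Iterable, Optional

from .errors import LabelLookupError, TreeStructureError
from .tree import Node, Tree

__all__ = ["reroot", "suppress_unifurcations", "extract_tree_with",
           "prune_leaves"]


def _merge_lengths(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def reroot(tree: Tree, node: Node,
           length_along_edge: Optional[float] = None) -> Tree:
    """Reroot ``tree`` at ``node``, in place.

    Without ``length_along_edge``, ``node`` itself becomes the root (its
    former parent becomes a child). With it, a new root is created on the
    edge above ``node``, ``length_along_edge`` away from ``node``; the
    remainder of the edge stays on the old-parent side. A former root left
    with a single child is suppressed.
    """
    if not tree.contains(node):
        raise TreeStructureError("node does not belong to this tree")

    if length_along_edge is not None:
        if node.parent is None:
            raise TreeStructureError(
                "length_along_edge requires a non-root node")
        edge = node.edge_length if node.edge_length is not None else 0.0
        if not 0 <= length_along_edge <= edge:
            raise ValueError(
                f"length_along_edge must be in [0, {edge}], "
                f"got {length_along_edge}")
        parent = node.parent
        split = Node(edge_length=edge - length_along_edge)
        idx = parent.children.index(node)
        parent.children[idx] = split
        split.parent = parent
        node.parent = split
        node.edge_length = length_along_edge
        split.children.append(node)
        node = split

    if node is tree.root:
        return tree

    # path from the new root up to the old root, with the edge lengths
    # currently stored on the child side of each path edge
    path = [node]
    while path[-1].parent is not None:
        path.append(path[-1].parent)
    lengths = [path[i].edge_length for i in range(len(path) - 1)]

    for i in range(len(path) - 1):
        path[i + 1].children.remove(path[i])
    for i in range(len(path) - 1):
        child, parent = path[i], path[i + 1]
        child.children.append(parent)
        parent.parent = child
        parent.edge_length = lengths[i]

    node.parent = None
    node.edge_length = None
    old_root = path[-1]
    if len(old_root.children) == 1:
        _splice_out(old_root)
    tree.root = node
    return tree


def _splice_out(node: Node) -> None:
    """Remove a unifurcation, merging its edge length into its only child's."""
    (child,) = node.children
    child.edge_length = _merge_lengths(node.edge_length, child.edge_length)
    parent = node.parent
    child.parent = parent
    if parent is not None:
        parent.children[parent.children.index(node)] = child
    node.parent = None
    node.children = []


def suppress_unifurcations(tree: Tree) -> Tree:
    """Remove every non-root internal node with exactly one child, in place.

    Merged nodes add their edge length to their child's, so root-to-leaf
    distances are unchanged. The root is kept even if unary, preserving the
    tree's anchoring (rerooting and pruning handle their own root cleanup).
    """
    from .traverse import traverse_preorder

    # splicing never changes any OTHER node's child count, so one snapshot
    # pass visits (and removes) every unary node, chains included
    for node in list(traverse_preorder(tree)):
        if node.parent is not None and len(node.children) == 1:
            _splice_out(node)
    return tree


def extract_tree_with(tree: Tree, leaf_labels: Iterable[str]) -> Tree:
    """Return a NEW tree induced on the given leaves; the input is untouched.

    The result is the minimal spanning topology of the chosen leaves rooted
    at their MRCA: unifurcations are suppressed on the fly and edge lengths
    are summed along collapsed paths. Any length dangling above the MRCA is
    dropped (the new root stores no edge length).
    """
    wanted = set(leaf_labels)
    leaf_nodes = tree.leaf_map()
    missing = sorted(wanted - leaf_nodes.keys())
    if missing:
        raise LabelLookupError(f"labels not found among leaves: {missing}",
                               missing=missing)
    if not wanted:
        raise LabelLookupError("cannot extract an empty leaf set")

    from .traverse import traverse_postorder

    # survivors[id(node)] = (copy, pending edge length below any collapse)
    survivors: dict[int, Node] = {}
    result_root: Optional[Node] = None
    for node in traverse_postorder(tree):
        if node.is_leaf():
            if node.label in wanted:
                copy = Node(node.label, node.edge_length)
                survivors[id(node)] = copy
            continue
        kept = [survivors.pop(id(c)) for c in node.children
                if id(c) in survivors]
        if not kept:
            continue
        if len(kept) == 1:
            # pass-through: collapse this unary step into the child's edge
            (copy,) = kept
            copy.edge_length = _merge_lengths(node.edge_length,
                                              copy.edge_length)
            survivors[id(node)] = copy
        else:
            copy = Node(node.label, node.edge_length)
            for c in kept:
                c.parent = copy
                copy.children.append(c)
            survivors[id(node)] = copy
    result_root = survivors.get(id(tree.root))
    if result_root is None:  # single kept leaf below the root
        (result_root,) = survivors.values()
    result_root.edge_length = None
    result_root.parent = None
    return Tree(result_root, is_rooted=tree.is_rooted)


def prune_leaves(tree: Tree, leaf_labels: Iterable[str]) -> Tree:
    """Remove the named leaves in place, then clean up the topology.

    Internal nodes left childless are removed; unifurcations are suppressed;
    a root left unary is collapsed downward so the result agrees with
    ``extract_tree_with`` on the complementary leaf set. Pruning every leaf
    is an error.
    """
    to_remove = set(leaf_labels)
    if not to_remove:
        return tree
    leaf_nodes = tree.leaf_map()
    missing = sorted(to_remove - leaf_nodes.keys())
    if missing:
        raise LabelLookupError(f"labels not found among leaves: {missing}",
                               missing=missing)
    if to_remove >= leaf_nodes.keys():
        raise TreeStructureError("cannot prune every leaf of the tree")

    for label in sorted(to_remove):
        node = leaf_nodes[label]
        parent = node.parent
        node.detach()
        # remove ancestors that just lost their last child
        while parent is not None and not parent.children:
            gp = parent.parent
            if gp is None:
                raise TreeStructureError("cannot prune every leaf of the tree")
            parent.detach()
            parent = gp

    suppress_unifurcations(tree)
    while len(tree.root.children) == 1:
        child = tree.root.children[0]
        child.parent = None
        tree.root.children = []
        tree.root = child
        child.edge_length = None
    return tree
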