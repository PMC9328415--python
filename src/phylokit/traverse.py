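"""Generator-based tree traversals.

All traversals are iterative (explicit stack/queue), so they work on trees
whose depth far exceeds the interpreter recursion limit — a caterpillar with
10^5 internal nodes iterates as happily as a balanced tree. Pre-, post-,
level-order and leaf traversals are lazy: consuming the first k items touches
only the visited frontier. Root-distance order requires a global sort and is
materialized internally.
"""

from __future__ import annotations

import enum
from collections import deque
from typing import Iterator, Union

from .errors import UnsupportedTopologyError
from .tree import Node, Tree

__all__ = [
    "TraversalOrder",
    "traverse_preorder",
    "traverse_inorder",
    "traverse_postorder",
    "traverse_levelorder",
    "traverse_rootdistorder",
    "traverse_leaves",
]


class TraversalOrder(enum.Enum):
    """The supported node visit orders."""

    PREORDER = "preorder"
    INORDER = "inorder"
    POSTORDER = "postorder"
    LEVELORDER = "levelorder"
    ROOTDISTORDER_ASC = "rootdistorder-ascending"
    ROOTDISTORDER_DESC = "rootdistorder-descending"
    LEAVES = "leaves-only"


def _root_of(tree: Union[Tree, Node]) -> Node:
    return tree.root if isinstance(tree, Tree) else tree


def traverse_preorder(tree: Union[Tree, Node]) -> Iterator[Node]:
    """Yield each node before any of its descendants (children in stored order)."""
    stack = [_root_of(tree)]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def traverse_postorder(tree: Union[Tree, Node]) -> Iterator[Node]:
    """Yield each node after all of its descendants."""
    # each frame holds (node, next-child-index); a node is emitted once its
    # last child subtree has been exhausted
    stack: list[list] = [[_root_of(tree), 0]]
    while stack:
        frame = stack[-1]
        node, idx = frame
        if idx < len(node.children):
            frame[1] += 1
            stack.append([node.children[idx], 0])
        else:
            yield node
            stack.pop()


def traverse_inorder(tree: Union[Tree, Node]) -> Iterator[Node]:
    """Strictly binary in-order: left subtree, node, right subtree.

    Unary chains are permitted (child before node); a node with three or more
    children has no in-order and raises :class:`UnsupportedTopologyError`.
    """
    stack: list[list] = [[_root_of(tree), 0]]
    while stack:
        frame = stack[-1]
        node, stage = frame
        n = len(node.children)
        if n > 2:
            raise UnsupportedTopologyError(
                f"in-order traversal undefined for node {node!r} "
                f"with {n} children")
        if stage == 0:
            frame[1] = 1
            if n >= 1:
                stack.append([node.children[0], 0])
            else:
                yield node
                stack.pop()
        elif stage == 1:
            yield node
            frame[1] = 2
            if n == 2:
                stack.append([node.children[1], 0])
            else:
                stack.pop()
        else:
            stack.pop()


def traverse_levelorder(tree: Union[Tree, Node]) -> Iterator[Node]:
    """Breadth-first: non-decreasing depth, left-to-right within a level."""
    queue = deque((_root_of(tree),))
    while queue:
        node = queue.popleft()
        yield node
        queue.extend(node.children)


def traverse_rootdistorder(tree: Union[Tree, Node],
                           ascending: bool = True) -> Iterator[Node]:
    """Yield nodes ordered by weighted distance from the root.

    Distance is the sum of edge lengths on the root path, with missing lengths
    treated as 0. Ties are broken by preorder discovery rank (stable), so with
    all lengths absent the ascending order reduces to preorder.
    """
    entries = []
    # one preorder pass computes distances incrementally and assigns ranks
    stack = [(_root_of(tree), 0.0)]
    rank = 0
    while stack:
        node, dist = stack.pop()
        entries.append((dist, rank, node))
        rank += 1
        for child in reversed(node.children):
            el = child.edge_length
            stack.append((child, dist + (el if el is not None else 0.0)))
    entries.sort(key=lambda e: (e[0], e[1]) if ascending else (-e[0], e[1]))
    for _, _, node in entries:
        yield node


def traverse_leaves(tree: Union[Tree, Node]) -> Iterator[Node]:
    """Yield exactly the leaves, in preorder-induced order."""
    for node in traverse_preorder(tree):
        if not node.children:
            yield node


_DISPATCH = {
    TraversalOrder.PREORDER: traverse_preorder,
    TraversalOrder.INORDER: traverse_inorder,
    TraversalOrder.POSTORDER: traverse_postorder,
    TraversalOrder.LEVELORDER: traverse_levelorder,
    TraversalOrder.ROOTDISTORDER_ASC:
        lambda t: traverse_rootdistorder(t, ascending=True),
    TraversalOrder.ROOTDISTORDER_DESC:
        lambda t: traverse_rootdistorder(t, ascending=False),
    TraversalOrder.LEAVES: traverse_leaves,
}


def traverse(tree: Union[Tree, Node], order: TraversalOrder) -> Iterator[Node]:
    """Dispatch to the traversal named by ``order``."""
    return _DISPATCH[order](tree)
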