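"""Summarizing statistics: height, branch lengths, patristic distances,
MRCA queries, treeness, the Gamma statistic, and minimum leaf distances.

Missing edge lengths are treated as 0 wherever paths are summed (height,
depths, patristic distances, Gamma) but are EXCLUDED from branch-length
averages: an unmeasured edge should not drag a mean toward zero, while path
arithmetic needs a total function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np

from .errors import (LabelLookupError, NotUltrametricError,
                     TreeStructureError, UndefinedStatisticError)
from .traverse import traverse_leaves, traverse_postorder, traverse_preorder
from .tree import Node, Tree

__all__ = [
    "height", "avg_branch_length", "distance_between", "distance_matrix",
    "LeafDistanceMatrix", "mrca", "LcaIndex", "treeness",
    "gamma_statistic", "gamma_computation", "GammaComputation",
    "min_leaf_distances", "node_depths",
]


def node_depths(tree: Tree) -> dict[Node, float]:
    """Weighted depth (root-path edge-length sum) of every node, one pass."""
    depths: dict[Node, float] = {}
    stack = [(tree.root, 0.0)]
    while stack:
        node, d = stack.pop()
        depths[node] = d
        for child in node.children:
            el = child.edge_length
            stack.append((child, d + (el if el is not None else 0.0)))
    return depths


def height(tree: Tree) -> float:
    """Maximum root-to-leaf edge-length sum (missing lengths count as 0)."""
    best = 0.0
    stack = [(tree.root, 0.0)]
    while stack:
        node, d = stack.pop()
        if not node.children:
            if d > best:
                best = d
            continue
        for child in node.children:
            el = child.edge_length
            stack.append((child, d + (el if el is not None else 0.0)))
    return best


def avg_branch_length(tree: Tree, which: str = "all") -> float:
    """Arithmetic mean of stored edge lengths of a class of edges.

    ``which`` selects ``"all"`` edges, ``"internal"`` (child is an internal
    node; a stored length on the root counts here), or ``"leaf"`` (child is
    a leaf). Edges with no stored length are excluded from the mean;
    :class:`UndefinedStatisticError` if no qualifying edge has one.
    """
    if which not in ("all", "internal", "leaf"):
        raise ValueError(f"which must be 'all', 'internal' or 'leaf': {which!r}")
    total = 0.0
    count = 0
    for node in traverse_preorder(tree):
        if node.edge_length is None:
            continue
        is_leaf_edge = not node.children
        if which == "internal" and is_leaf_edge:
            continue
        if which == "leaf" and not is_leaf_edge:
            continue
        total += node.edge_length
        count += 1
    if count == 0:
        raise UndefinedStatisticError(
            f"no {which} edges with stored lengths to average")
    return total / count


def _mrca_nodes(u: Node, v: Node) -> Node:
    """MRCA of two nodes by two-pointer depth equalization (topological)."""
    du = sum(1 for _ in u.ancestors())
    dv = sum(1 for _ in v.ancestors())
    while du > dv:
        u = u.parent
        du -= 1
    while dv > du:
        v = v.parent
        dv -= 1
    while u is not v:
        if u.parent is None or v.parent is None:
            raise TreeStructureError("nodes belong to different trees")
        u = u.parent
        v = v.parent
    return u


def distance_between(tree: Tree, u: Node, v: Node) -> float:
    """Patristic distance: edge-length sum on the unique u-v path."""
    if not (tree.contains(u) and tree.contains(v)):
        raise TreeStructureError("nodes belong to different trees")
    if u is v:
        return 0.0
    anc = _mrca_nodes(u, v)
    total = 0.0
    for node in (u, v):
        while node is not anc:
            if node.edge_length is not None:
                total += node.edge_length
            node = node.parent
    return total


def mrca(tree: Tree, labels: Iterable[str]) -> Node:
    """Deepest node ancestral to (or equal to) every named leaf."""
    labels = list(labels)
    if not labels:
        raise LabelLookupError("mrca requires at least one leaf label")
    leaf_nodes = tree.leaf_map()
    missing = sorted(set(labels) - leaf_nodes.keys())
    if missing:
        raise LabelLookupError(f"labels not found among leaves: {missing}",
                               missing=missing)
    node = leaf_nodes[labels[0]]
    for label in labels[1:]:
        node = _mrca_nodes(node, leaf_nodes[label])
    return node


class LcaIndex:
    """Binary-lifting ancestor index for repeated MRCA queries.

    Building is O(n log n); each query is O(log n). Useful when many pairs
    are queried on a large, static tree (the all-pairs MRCA workload); for
    one-off queries, :func:`mrca` needs no preprocessing.
    """

    def __init__(self, tree: Tree):
        order = list(traverse_preorder(tree))
        n = len(order)
        self._index = {id(node): i for i, node in enumerate(order)}
        self._nodes = order
        depth = np.zeros(n, dtype=np.int32)
        parent = np.full(n, -1, dtype=np.int64)
        for i, node in enumerate(order):
            if node.parent is not None:
                p = self._index[id(node.parent)]
                parent[i] = p
                depth[i] = depth[p] + 1
        self._depth = depth
        levels = max(1, int(depth.max()).bit_length())
        up = np.full((levels, n), -1, dtype=np.int64)
        up[0] = parent
        for k in range(1, levels):
            prev = up[k - 1]
            valid = prev >= 0
            up[k, valid] = prev[prev[valid]]
        self._up = up

    def mrca(self, u: Node, v: Node) -> Node:
        i, j = self._index[id(u)], self._index[id(v)]
        depth, up = self._depth, self._up
        if depth[i] < depth[j]:
            i, j = j, i
        diff = int(depth[i] - depth[j])
        k = 0
        while diff:
            if diff & 1:
                i = int(up[k, i])
            diff >>= 1
            k += 1
        if i == j:
            return self._nodes[i]
        for k in range(up.shape[0] - 1, -1, -1):
            if up[k, i] != up[k, j]:
                i, j = int(up[k, i]), int(up[k, j])
        return self._nodes[int(up[0, i])]


@dataclass(eq=False)
class LeafDistanceMatrix:
    """All-pairs patristic distances between labeled leaves.

    ``labels`` fixes the row/column order (preorder leaf order);
    ``matrix`` is a symmetric numpy array with zero diagonal.
    """

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self._idx = {lab: i for i, lab in enumerate(self.labels)}

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.matrix[self._idx[a], self._idx[b]])

    def __len__(self) -> int:
        return len(self.labels)

    def to_tsv(self, path, precision: int = 6) -> None:
        """Write as TSV with a label header row and column."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.matrix):
                vals = "\t".join(f"{v:.{precision}f}" for v in row)
                fh.write(f"{lab}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path) -> "LeafDistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
        return cls(header, np.asarray(rows, dtype=float))


def distance_matrix(tree: Tree) -> LeafDistanceMatrix:
    """All-pairs leaf patristic distances in ONE post-order pass.

    At each internal node the leaf sets of its children are joined: for
    leaves a (under child i) and b (under child j, i < j) the distance is
    dist(a, node) + dist(b, node). Total work is O(n^2) for n leaves —
    never one MRCA query per pair.
    """
    labels = []
    label_set = set()
    for leaf in traverse_leaves(tree):
        if leaf.label is None:
            raise LabelLookupError("distance_matrix requires labeled leaves")
        if leaf.label in label_set:
            raise LabelLookupError(f"duplicate leaf label {leaf.label!r}",
                                   missing=[leaf.label])
        label_set.add(leaf.label)
        labels.append(leaf.label)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n), dtype=float)

    # below[id(node)] -> (leaf index array, distances of those leaves to node)
    below: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in traverse_postorder(tree):
        if not node.children:
            below[id(node)] = (np.array([index[node.label]], dtype=np.int64),
                               np.zeros(1))
            continue
        parts = []
        for child in below_children(node, below):
            idxs, dists = child
            parts.append((idxs, dists))
        for i in range(len(parts)):
            ai, ad = parts[i]
            for j in range(i + 1, len(parts)):
                bi, bd = parts[j]
                block = ad[:, None] + bd[None, :]
                D[np.ix_(ai, bi)] = block
                D[np.ix_(bi, ai)] = block.T
        below[id(node)] = (np.concatenate([p[0] for p in parts]),
                           np.concatenate([p[1] for p in parts]))
    return LeafDistanceMatrix(labels, D)


def below_children(node: Node, below: dict):
    """Pop each child's (indices, distances-to-child) lifted across its edge."""
    for child in node.children:
        idxs, dists = below.pop(id(child))
        el = child.edge_length if child.edge_length is not None else 0.0
        yield idxs, dists + el


def treeness(tree: Tree) -> float:
    """Fraction of total branch length on internal edges, in [0, 1].

    An internal edge is one whose child is not a leaf; a stored length on
    the root counts as internal. Star trees give 0; zero total length is an
    error.
    """
    internal = total = 0.0
    for node in traverse_preorder(tree):
        if node.edge_length is None:
            continue
        total += node.edge_length
        if node.children:
            internal += node.edge_length
    if total <= 0:
        raise UndefinedStatisticError(
            "treeness undefined: total stored branch length is zero")
    return internal / total


@dataclass
class GammaComputation:
    """Intermediate quantities of the Gamma statistic.

    ``intervals`` holds the internode intervals g_2..g_n: g_k is the span of
    time during which the (ultrametric) tree has exactly k lineages, with
    g_n ending at the tips. ``weighted_total`` is T = sum_{j=2..n} j * g_j,
    the total branch length of the reconstructed genealogy.
    """

    n: int
    intervals: list[float]          # g_2 .. g_n
    weighted_total: float           # T
    gamma: float


def gamma_computation(tree: Tree, ultrametricity_rel_tol: float = 1e-6
                      ) -> GammaComputation:
    """Gamma statistic of an ultrametric tree, with its intermediates.

    The statistic standardizes the internode intervals of the genealogy:

        gamma = [ (1/(n-2)) * sum_{i=2..n-1} sum_{k=2..i} k*g_k  -  T/2 ]
                / ( T * sqrt(1 / (12*(n-2))) )

    Under a constant-rate pure-birth model gamma is asymptotically standard
    normal; gamma < 0 means branching events concentrate early, gamma > 0
    late. A node with c children contributes c-1 coincident branching
    events (zero-length intervals), so multifurcations are the continuous
    limit of the binary definition.
    """
    depths = node_depths(tree)
    leaf_depths = [depths[leaf] for leaf in traverse_leaves(tree)]
    n = len(leaf_depths)
    if n < 3:
        raise UndefinedStatisticError(
            f"gamma statistic requires >= 3 leaves, got {n}")
    h = max(leaf_depths)
    max_dev = max(abs(d - h) for d in leaf_depths)
    if h <= 0:
        raise UndefinedStatisticError("gamma undefined on a zero-height tree")
    if max_dev > ultrametricity_rel_tol * h:
        raise NotUltrametricError(
            f"tree is not ultrametric: max leaf-depth deviation {max_dev:g} "
            f"exceeds {ultrametricity_rel_tol:g} x height ({h:g})", max_dev)

    event_depths: list[float] = []
    for node, d in depths.items():
        c = len(node.children)
        if c >= 2:
            event_depths.extend([d] * (c - 1))
    event_depths.sort()
    if len(event_depths) != n - 1:
        raise UndefinedStatisticError(
            f"expected {n - 1} branching events, found {len(event_depths)}")

    # g_k = time with exactly k lineages, k = 2..n
    g = [0.0] * (n + 1)
    for k in range(2, n):
        g[k] = event_depths[k - 1] - event_depths[k - 2]
    g[n] = h - event_depths[n - 2]

    T = sum(j * g[j] for j in range(2, n + 1))
    if T <= 0:
        raise UndefinedStatisticError("gamma undefined: zero genealogy length")
    running = 0.0
    acc = 0.0
    for i in range(2, n):
        running += i * g[i]
        acc += running
    numerator = acc / (n - 2) - T / 2.0
    gamma = numerator / (T * math.sqrt(1.0 / (12.0 * (n - 2))))
    return GammaComputation(n=n, intervals=g[2:], weighted_total=T,
                            gamma=gamma)


def gamma_statistic(tree: Tree, ultrametricity_rel_tol: float = 1e-6) -> float:
    """The Gamma statistic (see :func:`gamma_computation` for details)."""
    return gamma_computation(tree, ultrametricity_rel_tol).gamma


def min_leaf_distances(tree: Tree) -> dict[Node, float]:
    """Minimum weighted distance from each node down to any descendant leaf.

    Leaves map to 0; an internal node u maps to
    min over children c of (value(c) + length(c)). One post-order pass.
    """
    values: dict[Node, float] = {}
    for node in traverse_postorder(tree):
        if not node.children:
            values[node] = 0.0
        else:
            values[node] = min(
                values[c] + (c.edge_length if c.edge_length is not None else 0.0)
                for c in node.children)
    return values
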