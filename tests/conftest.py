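"""Shared fixtures and independent reference implementations (oracles).

The oracles here are deliberately naive — recursive definitions, per-leaf
path walks, ancestor-set intersections — so they share no code path with the
package's iterative implementations.
"""

from __future__ import annotations

import math

import pytest
from hypothesis import HealthCheck, settings

from phylokit import Node, Tree, random_tree

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")

MODELS = ("yule", "coalescent", "random-attachment")


# -- tree enumeration -------------------------------------------------------

def _forest_shapes(n: int):
    """All ordered forests (tuples of shapes) with exactly n nodes total."""
    if n == 0:
        yield ()
        return
    for first in range(1, n + 1):
        for head in _tree_shapes(first):
            for tail in _forest_shapes(n - first):
                yield (head,) + tail


def _tree_shapes(n: int):
    """All ordered rooted tree shapes with exactly n nodes."""
    for forest in _forest_shapes(n - 1):
        yield forest


def build_from_shape(shape, lengths: bool = True) -> Tree:
    """Materialize a shape tuple into a Tree with deterministic labels/lengths."""
    counter = [0]

    def new_node():
        label = f"n{counter[0]}"
        counter[0] += 1
        return Node(label)

    root = new_node()
    stack = [(root, shape)]
    while stack:
        node, kids = stack.pop()
        for kid_shape in kids:
            child = new_node()
            if lengths:
                # a deliberately tie-rich pattern: repeats and zeros
                child.edge_length = (counter[0] % 4) * 0.5
            node.children.append(child)
            child.parent = node
            stack.append((child, kid_shape))
    return Tree(root)


def all_trees_up_to(max_nodes: int, lengths: bool = True):
    """Every ordered rooted tree with 1..max_nodes nodes (Catalan-many each)."""
    for n in range(1, max_nodes + 1):
        for shape in _tree_shapes(n):
            yield build_from_shape(shape, lengths=lengths)


# -- naive reference traversals (recursive) ---------------------------------

def ref_preorder(node: Node):
    out = [node]
    for c in node.children:
        out.extend(ref_preorder(c))
    return out


def ref_postorder(node: Node):
    out = []
    for c in node.children:
        out.extend(ref_postorder(c))
    out.append(node)
    return out


def ref_inorder(node: Node):
    kids = node.children
    if len(kids) == 0:
        return [node]
    if len(kids) == 1:
        return ref_inorder(kids[0]) + [node]
    assert len(kids) == 2
    return ref_inorder(kids[0]) + [node] + ref_inorder(kids[1])


def ref_levelorder(root: Node):
    """Independent characterization: sort by (edge depth, preorder rank)."""
    pre = ref_preorder(root)
    rank = {id(n): i for i, n in enumerate(pre)}
    depth = {}
    for n in pre:
        depth[id(n)] = 0 if n.parent is None else depth[id(n.parent)] + 1
    return sorted(pre, key=lambda n: (depth[id(n)], rank[id(n)]))


def ref_rootdistorder(root: Node, ascending: bool = True):
    pre = ref_preorder(root)
    rank = {id(n): i for i, n in enumerate(pre)}
    dist = {}
    for n in pre:
        up = 0.0 if n.parent is None else dist[id(n.parent)]
        dist[id(n)] = up + (n.edge_length or 0.0)
    sign = 1.0 if ascending else -1.0
    return sorted(pre, key=lambda n: (sign * dist[id(n)], rank[id(n)]))


# -- naive reference statistics ---------------------------------------------

def path_to_root(node: Node):
    out = [node]
    while out[-1].parent is not None:
        out.append(out[-1].parent)
    return out


def leaf_depth_walk(leaf: Node) -> float:
    total = 0.0
    node = leaf
    while node.parent is not None:
        total += node.edge_length or 0.0
        node = node.parent
    return total


def brute_distance(u: Node, v: Node) -> float:
    """Edge-length sum of the u-v path, via rootward walks to the first
    shared ancestor (which is the MRCA, since paths go rootward)."""
    anc_v = {id(n) for n in path_to_root(v)}
    total = 0.0
    node = u
    while id(node) not in anc_v:
        total += node.edge_length or 0.0
        node = node.parent
    meet = node
    node = v
    while node is not meet:
        total += node.edge_length or 0.0
        node = node.parent
    return total


def brute_mrca(u: Node, v: Node) -> Node:
    """Deepest element of the intersection of the two ancestor sets."""
    anc_u = path_to_root(u)
    anc_v = {id(n) for n in path_to_root(v)}
    for node in anc_u:  # ordered leaf-to-root: first hit is deepest
        if id(node) in anc_v:
            return node
    raise AssertionError("nodes share no ancestor")


def gamma_oracle(tree: Tree) -> float:
    """Direct evaluation of the Gamma formula from per-node path walks."""
    nodes = ref_preorder(tree.root)
    leaves = [n for n in nodes if not n.children]
    n = len(leaves)
    assert n >= 3
    H = max(leaf_depth_walk(l) for l in leaves)
    times = []
    for v in nodes:
        if v.children:
            d = leaf_depth_walk(v) if v.parent is not None else 0.0
            times.extend([d] * (len(v.children) - 1))
    times.sort()
    assert len(times) == n - 1
    g = {}
    for k in range(2, n):
        g[k] = times[k - 1] - times[k - 2]
    g[n] = H - times[n - 2]
    T = sum(j * g[j] for j in range(2, n + 1))
    mean_cum = sum(sum(k * g[k] for k in range(2, i + 1))
                   for i in range(2, n)) / (n - 2)
    return (mean_cum - T / 2.0) / (T * math.sqrt(1.0 / (12.0 * (n - 2))))


def total_branch_length(tree: Tree) -> float:
    return sum(n.edge_length or 0.0 for n in ref_preorder(tree.root))


# -- test-only NeXML emitter -------------------------------------------------

def nexml_of(tree: Tree) -> str:
    """Serialize a tree as minimal NeXML (brute-force; tests only)."""
    nodes = ref_preorder(tree.root)
    ids = {id(n): f"n{i}" for i, n in enumerate(nodes)}
    parts = ['<nex:nexml xmlns:nex="http://www.nexml.org/2009" version="0.9">',
             '<trees otus="tax1"><tree id="tree1">']
    for n in nodes:
        label = f' label="{n.label}"' if n.label is not None else ""
        root_attr = ' root="true"' if n.parent is None else ""
        parts.append(f'<node id="{ids[id(n)]}"{label}{root_attr}/>')
    for i, n in enumerate(nodes):
        if n.parent is None:
            continue
        length = f' length="{n.edge_length!r}"' if n.edge_length is not None else ""
        parts.append(f'<edge id="e{i}" source="{ids[id(n.parent)]}" '
                     f'target="{ids[id(n)]}"{length}/>')
    parts.append("</tree></trees></nex:nexml>")
    return "".join(parts)


# -- fixtures ----------------------------------------------------------------

@pytest.fixture
def small_tree():
    """The hand-checkable 5-node tree used throughout the contract examples."""
    from phylokit import read_tree_newick
    return read_tree_newick("((A:1,B:3)X:1,C:1)R;")


def random_trees(count: int, max_leaves: int, seed0: int = 0,
                 models=MODELS):
    """A deterministic batch of random trees cycling through the models."""
    out = []
    for i in range(count):
        model = models[i % len(models)]
        n = 2 + (seed0 + 7 * i) % (max_leaves - 1)
        out.append(random_tree(n, model, seed=seed0 + i))
    return out
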