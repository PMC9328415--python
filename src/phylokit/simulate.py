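"""Random binary tree generation for benchmarks and tests.

Three topology models, each exercising a different code path:

* ``yule`` — forward-time pure-birth process: while fewer than n tips exist,
  wait Exp(k * rate) with k current tips, then split a uniformly chosen tip;
  after the n-th tip appears, one final Exp(n * rate) interval extends all
  tips to the present. The result is ultrametric, and the time with exactly
  k lineages is Exp(k * rate) for k = 2..n — the null model under which the
  Gamma statistic is asymptotically standard normal.
* ``coalescent`` — backward-time pairwise merging: with k lineages the
  waiting time to the next merge is Exp(C(k,2) * rate) and the merging pair
  is uniform. Ultrametric, with the deep internal structure typical of
  genealogies.
* ``random-attachment`` — each new leaf is attached on a uniformly chosen
  existing edge by inserting a new internal node there, with both new edge
  lengths drawn from the branch-length law. NON-ultrametric; exercises the
  general (non-clock) paths of the statistics.

All models produce strictly binary trees with leaves labeled L1..Ln, and an
identical spec (model, parameters, seed) reproduces a byte-identical Newick
string: randomness comes from one ``random.Random(seed)`` stream per call,
never from global state.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .tree import Node, Tree

__all__ = ["BranchLengthLaw", "FixtureSpec", "generate_tree", "random_tree"]


@dataclass(frozen=True)
class BranchLengthLaw:
    """Distribution for drawn edge lengths.

    ``kind`` is ``"exponential"`` (params: rate), ``"uniform"`` (params:
    low, high) or ``"constant"`` (params: value).
    """

    kind: str = "exponential"
    params: tuple[float, ...] = (1.0,)

    def __post_init__(self):
        if self.kind == "exponential":
            if len(self.params) != 1 or self.params[0] <= 0:
                raise ValueError("exponential law needs one positive rate")
        elif self.kind == "uniform":
            if len(self.params) != 2 or not 0 <= self.params[0] <= self.params[1]:
                raise ValueError("uniform law needs 0 <= low <= high")
        elif self.kind == "constant":
            if len(self.params) != 1 or self.params[0] < 0:
                raise ValueError("constant law needs one non-negative value")
        else:
            raise ValueError(f"unknown branch-length law {self.kind!r}")

    def draw(self, rng: random.Random) -> float:
        if self.kind == "exponential":
            return rng.expovariate(self.params[0])
        if self.kind == "uniform":
            return rng.uniform(*self.params)
        return self.params[0]


@dataclass(frozen=True)
class FixtureSpec:
    """Complete description of one random tree: model, size, lengths, seed."""

    n_leaves: int
    model: str = "yule"             # yule | coalescent | random-attachment
    rate: float = 1.0               # event rate for yule / coalescent
    length_law: BranchLengthLaw = field(default_factory=BranchLengthLaw)
    seed: int = 0

    def __post_init__(self):
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.model not in ("yule", "coalescent", "random-attachment"):
            raise ValueError(f"unknown topology model {self.model!r}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def generate_tree(spec: FixtureSpec) -> Tree:
    """Generate the tree described by ``spec`` (deterministic in the spec)."""
    rng = random.Random(spec.seed)
    n = spec.n_leaves
    if n == 1:
        return Tree(Node("L1"))
    if spec.model == "yule":
        return _yule(n, spec.rate, rng)
    if spec.model == "coalescent":
        return _coalescent(n, spec.rate, rng)
    return _random_attachment(n, spec.length_law, rng)


def random_tree(n_leaves: int, model: str = "yule", seed: int = 0,
                rate: float = 1.0,
                length_law: Optional[BranchLengthLaw] = None) -> Tree:
    """Convenience wrapper building a :class:`FixtureSpec` and generating it."""
    return generate_tree(FixtureSpec(
        n_leaves=n_leaves, model=model, rate=rate,
        length_law=length_law or BranchLengthLaw(), seed=seed))


def _label_leaves(tree: Tree) -> Tree:
    i = 0
    for leaf in tree.traverse_leaves():
        i += 1
        leaf.label = f"L{i}"
    return tree


def _yule(n: int, rate: float, rng: random.Random) -> Tree:
    root = Node()
    t = 0.0
    active: list[tuple[Node, float]] = []   # (tip node, birth time)
    for _ in range(2):
        child = Node()
        root.children.append(child)
        child.parent = root
        active.append((child, 0.0))
    while len(active) < n:
        t += rng.expovariate(len(active) * rate)
        idx = rng.randrange(len(active))
        node, birth = active[idx]
        node.edge_length = t - birth
        left, right = Node(), Node()
        for c in (left, right):
            node.children.append(c)
            c.parent = node
        active[idx] = (left, t)
        active.append((right, t))
    t += rng.expovariate(n * rate)
    for node, birth in active:
        node.edge_length = t - birth
    return _label_leaves(Tree(root))


def _coalescent(n: int, rate: float, rng: random.Random) -> Tree:
    # ages are measured backward from the tips (present = 0)
    lineages: list[tuple[Node, float]] = [(Node(), 0.0) for _ in range(n)]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.expovariate(k * (k - 1) / 2.0 * rate)
        i, j = rng.sample(range(k), 2)
        (a, age_a), (b, age_b) = lineages[i], lineages[j]
        parent = Node()
        a.edge_length = t - age_a
        b.edge_length = t - age_b
        for c in (a, b):
            parent.children.append(c)
            c.parent = parent
        for idx in sorted((i, j), reverse=True):  # O(1) swap-remove
            lineages[idx] = lineages[-1]
            lineages.pop()
        lineages.append((parent, t))
    return _label_leaves(Tree(lineages[0][0]))


def _random_attachment(n: int, law: BranchLengthLaw,
                       rng: random.Random) -> Tree:
    root = Node()
    attachable: list[Node] = []             # every non-root node = one edge
    for _ in range(2):
        child = Node(edge_length=law.draw(rng))
        root.children.append(child)
        child.parent = root
        attachable.append(child)
    leaves = 2
    while leaves < n:
        target = attachable[rng.randrange(len(attachable))]
        parent = target.parent
        mid = Node(edge_length=law.draw(rng))
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        target.parent = mid
        mid.children.append(target)
        new_leaf = Node(edge_length=law.draw(rng))
        mid.children.append(new_leaf)
        new_leaf.parent = mid
        attachable.extend((mid, new_leaf))
        leaves += 1
    return _label_leaves(Tree(root))
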