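# phylokit

A massively scalable Python library for loading, traversing, manipulating and
summarizing phylogenetic trees.

Phylogenetic methods — clustering, rerooting, dating, epidemiological and
metagenomic analyses — are usually written as a series of tree traversals on
top of a general-purpose tree package, so their practical performance is
bounded by that package. As sequencing datasets grow, trees with 10^5–10^6
leaves are now routine, and tree libraries that build heavyweight node
objects or recurse over the topology become the bottleneck. phylokit takes
the opposite approach: the entire data model is **two classes** (`Node`,
holding a label, a branch length, parent/children links and an optional
annotation map; and `Tree`, a root plus a rootedness flag), every algorithm
is iterative, and traversals are generators, so a million-leaf tree loads,
serializes and traverses in seconds on a laptop and never touches the
interpreter recursion limit.

## What it does

* **Input**: Newick, NEXUS (TREES block with TRANSLATE) and NeXML, from
  literal strings, plaintext files or gzip files (detected by magic bytes).
  **Output**: Newick, with exact shortest-round-trip branch lengths.
* **Traversals** (all lazy generators, all iterative): pre-order, in-order
  (strictly binary), post-order, level-order, root-distance order
  (ascending/descending, ties by preorder rank) and leaves-only.
* **Manipulation**: rerooting at a node or at a point on an edge (edge
  reversal; conserves total branch length and all leaf-to-leaf distances),
  unifurcation suppression, leaf pruning, and copying extraction of the
  subtree induced on a leaf subset.
* **Statistics**: tree height; mean branch length (all / internal / leaf
  edges); patristic distances and the full leaf distance matrix in one
  post-order pass; MRCA queries (two-pointer walks, plus a binary-lifting
  index for bulk querying); treeness; the Gamma statistic; per-node minimum
  leaf distances.
* **Lineages-Through-Time**: the exact step function of lineage count
  against time (area identically equal to total branch length) and a
  matplotlib step-plot renderer.
* **Fixture generator**: strictly binary random trees under pure-birth
  (Yule), Kingman coalescent, or random-attachment models, byte-reproducible
  from a seed.

## The statistics, precisely

For a rooted tree with branch lengths, the *patristic distance* d(u,v) is
the edge-length sum on the unique u–v path. *Treeness* is the fraction of
total branch length on internal edges, Σ_internal ℓ / Σ ℓ ∈ [0,1]. For an
ultrametric tree with n tips, let g_k (k = 2..n) be the timespan during
which exactly k lineages exist and T = Σ_{j=2}^{n} j·g_j; the *Gamma
statistic* is

    γ = [ (1/(n−2)) · Σ_{i=2}^{n−1} Σ_{k=2}^{i} k·g_k  −  T/2 ]
        / ( T · sqrt( 1 / (12(n−2)) ) )

Under a constant-rate pure-birth process γ is asymptotically standard
normal; γ < 0 indicates branching concentrated toward the root, γ > 0
toward the tips.

## Worked example

```python
import gzip
from phylokit import read_tree_newick, random_tree, write_tree_newick, \
    min_leaf_distances, gamma_statistic, treeness, height

# simulate a 1000-tip coalescent genealogy and store it gzipped
tree = random_tree(1000, "coalescent", seed=42)
with gzip.open("example.nwk.gz", "wb") as fh:
    fh.write(write_tree_newick(tree).encode())

tree = read_tree_newick("example.nwk.gz")      # gzip auto-detected
total, leaves, internal = tree.num_nodes()
print(f"leaves={leaves} nodes={total}")
print(f"height={height(tree):.4f}")
print(f"treeness={treeness(tree):.4f}")
print(f"gamma={gamma_statistic(tree):.4f}")
mld = min_leaf_distances(tree)
print(f"min leaf distance from root: {mld[tree.root]:.4f}")
tree.lineages_through_time(output_path="ltt.png", color="blue")
```

prints

```
leaves=1000 nodes=1999
height=1.2388
treeness=0.8359
gamma=36.9155
min leaf distance from root: 1.2388
```

and writes the LTT plot to `ltt.png`. The numbers mean: the genealogy is
1.24 coalescent time units deep; 84% of its length sits on internal
branches (coalescent trees are dominated by the deep two- and
three-lineage intervals); γ ≫ 0 because, seen forward in time from the
root, coalescent branching events pile up near the tips; and since the
tree is ultrametric, the *minimum* root-to-leaf distance equals the height.
The same computation recurs at the shell:

```sh
phylokit generate -n 100 --seed 1 --model coalescent | phylokit stats -
```

```
nodes	199
leaves	100
internal	99
height	2.682965
avg_branch_length_all	0.056661
avg_branch_length_internal	0.094684
avg_branch_length_leaf	0.019398
treeness	0.827098
gamma	11.083412
```

The CLI also exposes `convert`, `traverse`, `mrca`, `distmat`, `ltt`,
`reroot`, `extract` and `prune`; see `phylokit --help`.

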