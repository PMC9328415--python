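# Methods

This note documents the data model, the algorithms, the conventions adopted
where formats and definitions are genuinely ambiguous, the random-tree
models used for validation, and the known limitations. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

A tree is a web of `Node` objects (label, branch length to the parent,
parent/children links, lazily allocated annotation dict) under a `Tree`
handle (root + rootedness flag). `Node` uses `__slots__` and allocates its
annotation map only on first use, which keeps a 10^6-leaf tree within
desktop memory. Bipartition/split indexing for multi-tree comparison is
deliberately absent: this library is designed for fast single-tree work,
and maintaining split hashes would tax every load and edit.

Children are an **ordered list**; every operation preserves insertion
order, so serialization and traversal are deterministic and tests can be
exact. Tie-breaking wherever an order is otherwise unspecified (e.g. equal
root distances) is by preorder discovery rank.

**Missing vs zero branch lengths.** A `None` edge length is preserved in
storage and round trips (absent ≠ 0 in the file), but all path arithmetic
(depths, height, patristic distances, Gamma, LTT) treats it as 0 so sums
are total. Branch-length *averages* instead exclude unmeasured edges: an
absent length should not drag a mean toward zero. Both choices are applied
uniformly.

All algorithms are iterative (explicit stack, queue, or heapless sorted
list). This is a hard requirement, not a style choice: a caterpillar tree
with 10^5 internal nodes exceeds any practical recursion limit, and the
test suite traverses exactly such a tree.

## Formats

* **Newick.** Single-pass character-level parser with O(length) work and
  parse errors carrying character offsets. Quoted labels use `''` escapes;
  underscores in unquoted labels are kept verbatim (the "underscore means
  space" convention is ambiguous across tools and destroys round trips).
  Square-bracket comments are stored verbatim on the node whose syntactic
  position they follow (`comment_0`, `comment_1`, ... in the annotation
  map) and never parsed as structure; a leading `[&R]`/`[&U]` comment sets
  the rootedness flag. Multi-tree files: `read_tree_newick` returns the
  first statement, `read_trees_newick` all of them. Branch lengths are
  written with Python's shortest-round-trip float representation unless a
  fixed precision is requested, so write∘parse is the identity on doubles.
* **NEXUS.** The TREES block only: `TRANSLATE` tokens are substituted into
  node labels before trees are returned; `TREE`/`UTREE` statements keep
  file order; statement splitting respects quotes and comments. Writing
  NEXUS is out of scope (a test-only emitter covers round-trip testing).
* **NeXML.** The structural subset: `tree`/`node`/`edge` (plus `rootedge`)
  with ids, labels/otu references and lengths; non-structural attributes
  are retained opaquely. The unique parentless node is the root; anything
  else (undeclared edge endpoints, multiple roots) is a parse error.
* **Sources.** Any reader accepts a literal string, a plaintext path or a
  gzip path; gzip is detected by magic bytes, never by extension.

## Traversals

Pre-, post-, level-order and leaves-only are lazy generators whose work is
bounded by the visited frontier. In-order is defined only for strictly
binary nodes (unary chains visit child before node); a 3+-furcation raises
an error naming the node, because the benchmark topologies are binary and
any silent split convention would be an invented semantics. Root-distance
order sorts by *weighted* root distance (edge-length sums, missing = 0) —
matching the patristic metric used elsewhere — with ties broken by
preorder rank, which requires a full preorder numbering pass; it is
therefore O(n log n) and materialized, unlike the other traversals.

## Manipulation

`reroot` walks the old root path, reverses each edge while carrying its
length, and suppresses the former root if left unary; total branch length
and the entire leaf-to-leaf patristic metric are conserved (verified
numerically at 1e-9). Rerooting at a node makes *that node* the root; the
alternative convention (bisect the parent edge) is available explicitly via
`length_along_edge`. A stored length on the old root (a "root edge") has no
parent edge to migrate to and is dropped.

`suppress_unifurcations` splices every non-root unary node, summing its
edge length into its child's; the root is exempt so a standalone cleanup
never silently re-anchors the tree. `extract_tree_with` *copies* the
induced subtree, collapsing unary pass-throughs on the fly, and roots the
result at the MRCA of the kept leaves (dropping any length dangling above
it); `prune_leaves` edits *in place* and collapses a unary root downward so
that pruning S is exactly extraction of the complement of S. The
copy/in-place split mirrors the natural read/write usage of the two
operations.

## Statistics

* `height`, `min_leaf_distances`: single sweeps over (node, depth) pairs.
* `distance_matrix`: one post-order pass; at each internal node the
  children's leaf lists (with distances lifted across the child edge) are
  joined pairwise into the matrix. O(n²) total for n leaves, never one
  MRCA query per pair. Requires unique leaf labels.
* `mrca`: two-pointer depth equalization for ad-hoc queries; `LcaIndex`
  builds a binary-lifting table (numpy int64, O(n log n)) for bulk
  workloads such as all-pairs MRCA on large trees.
* `treeness`: internal-edge length fraction; a stored root length counts
  as internal (it is not a terminal branch; conventions differ, so the
  choice is stated). The complement identity
  treeness + leaf fraction = 1 holds exactly.
* `gamma_statistic`: leaf depths must agree with the height within a
  relative tolerance of 1e-6 (floating-point path sums drift; exceeding it
  raises an error reporting the maximum deviation). Branching-event depths
  are sorted; a c-furcation contributes c−1 coincident events (zero-length
  intervals), the continuous limit of the binary definition. The internode
  intervals g_2..g_n and T = Σ j·g_j then feed the standardized statistic
  directly. Requires n ≥ 3 and positive height.

## Lineages-Through-Time

Time runs forward from the root at 0 (works for non-ultrametric trees;
negate the axis for backward-time conventions). The lineage count at time
t is the number of edges spanning t; the count rises by c−1 at a
c-furcation and falls by 1 at any leaf shallower than the deepest, so the
integral of the step function equals total branch length *identically* —
the invariant the tests assert at 1e-9. Simultaneous events merge into one
breakpoint (times strictly increase), and leaves within 1e-9 × t_end of
the maximum depth are treated as reaching it (path sums of equal-depth
tips differ by ulps). Rendering is a thin matplotlib `step` adapter; the
log-counts option scales the axis, not the data.

## Random-tree models

The generator exists so that every capability is testable at any size with
no external data. The three models are this package's own choices, each
exercising a different regime:

* **yule** (default; rate λ = 1): forward-time pure birth; with k tips the
  next split arrives after Exp(kλ) and hits a uniform tip; after the n-th
  tip, one final Exp(nλ) interval extends all tips to the present. The
  intervals g_k are thus independent Exp(kλ), so γ is asymptotically
  standard normal — the calibration the validation run checks (2000 trees
  at n = 50 give sample mean ≈ 0.03 and variance ≈ 0.97; the small
  positive mean is the finite-n bias of the statistic).
* **coalescent** (rate 1): backward-time Kingman merging, waiting
  Exp(C(k,2)) between merges; ultrametric with deep basal structure.
* **random-attachment**: each new leaf is inserted on a uniformly chosen
  existing edge via a new internal node, with fresh edge lengths drawn
  from the branch-length law (exponential(1) by default; uniform and
  constant laws available). Non-ultrametric; exercises the general-metric
  code paths.

All models emit strictly binary trees labeled L1..Ln from a single
`random.Random(seed)` stream, so identical specifications are
byte-identical across platforms. What the generator does *not* emulate:
real estimation artifacts (zero-length and negative branches, polytomies
from collapsed support, label conventions), rate heterogeneity across
lineages, and sampling-through-time tips. Passing tests therefore
demonstrate algorithmic correctness on clean binary trees, not robustness
to every artifact of inferred phylogenies (polytomies and missing lengths
are, however, covered by the hand-built cases).

## Validation sizes

The standard validation run uses: 200 trees of 2–512 leaves for round
trips; all 197 ordered rooted trees with ≤ 7 nodes plus 100 random trees
for traversal contracts; 50 trees of ≤ 64 leaves against brute-force
distance/MRCA oracles; 30 trees for the conservation laws; 100 trees plus
2000 Yule replicates (n = 50) for Gamma; and the full
generate→write→parse→post-order pipeline at 100,000 leaves (with a
1,000,000-leaf repetition in the test suite). These sizes make every
oracle comparison exhaustive or near-exhaustive while keeping a complete
run in the single-digit seconds.

## Known limitations

* Newick output only (NEXUS/NeXML writing is out of scope).
* `distance_matrix` is dense O(n²) memory: practical to ~2×10^4 leaves,
  by design (the all-pairs answer itself is quadratic).
* Rerooting drops a stored root-edge length (see above).
* The Nexus parser handles the TREES block subset only — no DATA/TAXA
  block interpretation beyond TRANSLATE.
* Node labels are not interpreted: branch support stored as internal
  labels stays text.
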