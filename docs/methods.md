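# Methods

This note records the model, the algorithmic choices that were genuinely
open, and what the tests do and do not establish.

## Model and assumptions

The input is a finite family `Y` of clusters (non-empty proper subsets of a
taxon universe `X`), usually obtained as the union of the per-edge
descendant leaf sets of several rooted gene trees.  The target object is a
rooted DAG with one root, bijectively leaf-labeled sinks, and reticulation
nodes of in-degree ≥ 2, such that every cluster of `Y` is *displayed* in the
soft-wired sense: some choice of one incoming edge per reticulation makes
the cluster the exact descendant leaf set of a node.  Complexity is measured
by the reticulation number `r = |E| − |V| + 1` (equal to the sum of
`indeg − 1` over non-root nodes), the *level* (maximum `r` over biconnected
components), and the redundant-cluster count `c` (non-trivial proper
clusters displayed beyond `Y`).  The method is a heuristic: it makes no
claim of minimizing `r` or `c` globally, only of selecting the best network
among the candidates its own search produces.

Trees are assumed rooted; leaf labels are unique per tree but the trees need
not be binary nor share identical taxon sets.  Branch lengths and bootstrap
values are ignored.

## Per-taxon conflict statistics

`f(x)` counts the clusters containing `x`.  For the conflict degree `d(x)`
two semantics are implemented (`taxon_incompatibility_degree`):

* **shared** (default): the number of incompatibility-graph edges whose two
  clusters both contain `x`.  On `{{1,2},{2,3}}` this gives
  `d = (0, 1, 0)` — only the shared taxon carries the conflict — and it is
  the semantics under which the statement "only removing taxon 2 makes the
  remainder compatible" is true, because only a taxon in the intersection of
  an incompatible pair can resolve that pair without merely shrinking one
  cluster to a singleton.
* **removal**: `d(Y) − d(Y with x deleted)`.  This subtractive reading also
  credits `x` with edges that disappear because a conflicting cluster
  collapsed to a trivial singleton (on the same example it yields
  `(1, 1, 1)`), which makes it a poor guide for choosing reticulate taxa;
  it is kept because it is the natural differencing of the published
  edge-count formula.

Scoring in the greedy mode uses the non-trivial sub-family only (the
incompatibility graph is defined on non-trivial clusters; singleton
leftovers of earlier removals carry no signal).  Removal candidates in both
modes are restricted to taxa with shared conflict degree > 0; an
incompatible set always has at least one.

## Construction pipeline

Step 1 decomposes `IG(Y)` into non-trivial connected components and
collapses each component's maximal ST-sets.  Maximal ST-sets are grown by
greedy pairwise agglomeration (merge any current pair that forms an ST-set,
earliest pair first, to a fixpoint); a minimal non-trivial cluster of a
laminar restriction always contains a mergeable pair, so the fixpoint
reaches the maximal partition, and the operation is idempotent.  Meta-taxon
labels are reserved `&`-prefixed tokens that encode their base taxa, making
every collapse invertible without side tables; they never appear in output.

Components whose taxon sets overlap or nest (possible when gene trees share
taxa) are merged into a single construction group, because the step-4
substitution grafts one subnetwork per component at the backbone node
carrying its taxon set — only well defined for disjoint sets.  Merged
groups additionally absorb compatible clusters nested inside their taxon
union (for a true single component such clusters always lie inside a
maximal ST-set and are restored by meta expansion; for merged groups they
would otherwise be lost with the replaced backbone subtree).

Step 2 removes (meta-)taxa until compatible — greedy argmax of `s(x)` per
weighting in frin mode, depth-first over all candidates in cass mode — with
a fresh ST-collapse after every removal, then rebuilds the remainder tree
and re-adds the removed items in reverse order.  Each reinsertion tries all
ordered pairs of current edges (including a synthetic edge above the root,
which plays the role of a dummy outgroup and lets reticulations span the
root region; it is suppressed when unused) as attachment points of a new
in-degree-2 reticulation whose single child is the removed item.  Partial
networks are pruned unless they represent the intermediate cluster set of
their level.  Finished component networks must be *simple*: no bridge may
have a reticulation strictly below it.  This cut-arc reading, rather than a
cut-node reading, is used deliberately: expansions of intermediate collapse
rounds graft pure pendant subtrees whose attachment arcs are bridges, and
only reticulations below a bridge actually violate simplicity.  (The public
`is_simple_level_k` keeps the articulation-point definition with leaves
exempt.)  Merged groups are exempt from the simplicity filter, which is
unattainable for them by construction.

Steps 3–4 build the backbone from the out-of-component clusters, each
group's taxon union, and its maximal membership-equivalent taxon classes,
then substitute the group networks and expand meta-taxa, using the full
input family to restore structure nested inside ST-sets.

## Determinism and input-order dependence

The entire pipeline is deterministic.  Where iteration order is genuinely
open, the two modes differ on purpose:

* Frin mode is made *independent* of the input order: score ties break by
  natural label order (`tie_break="lexicographic"`, the default;
  `"first-encounter"` is available), and trees store children in canonical
  label order so that placement enumeration depends only on the tree's
  shape.  This is what the method's stability claim is about, and score
  ties do occur in practice (the bundled ten-taxon example has them at
  every weighting), so first-encounter tie-breaking would destroy the
  property the mode exists for.
* Cass mode branches over removal candidates in taxon first-encounter
  order and keeps the first network found, which reproduces the baseline's
  characteristic input-order dependence.

Per distinct trace, frin mode keeps the first representing placement
(`keep_placements="first"`), one network per weighting group;
`keep_placements="all"` retains every distinct placement (bounded by
`placement_cap`, default 256) and is used when the non-selected candidate
pool itself is of interest.  Final selection minimizes `(r, c, canonical
form)`; the canonical-form tie-break keeps `build` a pure function of its
input.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `mode` | `"frin"` | greedy scored removal vs depth-first baseline |
| `max_k` | 6 | cap on the per-group level search `k = 0, 1, …` |
| `weight_step` | 0.1 | spacing of the `(p, q)` sweep (ten weightings) |
| `tie_break` | `"lexicographic"` | score-tie rule, see above |
| `degree_method` | `"shared"` | `d(x)` semantics |
| `keep_placements` | `"first"` | networks kept per removal trace |
| `reticulation_cap` | 20 | soft-wired enumeration guard (2^r switchings) |

The level search is per group; the reported `k` of a result is the level of
the assembled network, not the search bound.

## Synthetic data

`fixtures.make_fixture` emulates the conflicting-gene-trees setting
directly: one uniform-attachment random rooted binary tree, plus derived
trees obtained by random subtree-prune-and-regraft moves (the tree-space
signature of a transfer event).  Defaults are 2 trees and 1 move — one
reticulate event between two loci, the smallest realistic conflict — and
the property suite runs 100 seeds at 8 taxa.  The generator produces
binary trees on a shared taxon set with uniform random topology; real gene
trees are non-binary, unevenly sampled, and have estimation error, so
passing tests demonstrate correctness of the construction on genuine
topological conflict, not robustness to inference noise.  Output is
bit-identical for a fixed seed.

## Numerical and degenerate-input choices

Compatibility, ST-set detection and cluster arithmetic are exact set
operations; the only floating-point quantities are the scores (ties are
exact because `f` and `d` are integers and the weights are one-decimal
rationals), the tripartition distance (a multiple of 0.5), and the reported
mean distance (rounded to two decimals).  Degenerate inputs: a compatible
input returns its unique tree (`r = c = 0`); an empty cluster list with a
declared universe returns the star tree; taxa in no cluster become leaves
under the root; duplicate clusters are merged; clusters equal to the
universe are ignored for representation (every network displays them).
A group for which no representing simple network exists within `max_k`
raises a `ResourceError` naming the group.

## Known limitations

* The removal/reinsertion search is heuristic and, like the original
  algorithms, incomplete: for high-conflict inputs (e.g. three 10-taxon
  trees with multiple transfers each) a representing network within
  `max_k` may not be found even though one exists.
* Reinsertion builds in-degree-2 reticulations only; metrics accept
  arbitrary in-degree.
* The exhaustive baseline's first-found network depends on enumeration
  minutiae, so its distinct-network sets are comparable across runs of this
  package but not guaranteed to coincide with other implementations.
* `canonical_form` resolves reticulation numbering by iterative refinement
  of an unfolding encoding; symmetric reticulations with identical refined
  encodings are assumed automorphic.
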