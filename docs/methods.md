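# Methods

This note documents the models, algorithms, numerical choices, and
known limitations behind `treelens`, in the spirit of a software
methods appendix. Nothing here reports an empirical claim that the
test suite or `scripts/acceptance.py` does not itself compute.

## Trees and splits

A tree on $n = m+3$ tips is stored as its set of internal *splits*
(bipartitions of the tip set) with non-negative lengths, plus one
pendant length per tip. Splits are canonically oriented (the stored
side excludes the lexicographically smallest tip) and canonically
ordered (sorted side tuples), so coordinate indices, CSV columns, and
Newick output are bit-stable across runs. Trees are unrooted
throughout: rooted Newick input is unrooted on parse (a degree-2 root
is suppressed and its two incident lengths summed), degree-2 internal
nodes are contracted, internal node labels (support values) are
ignored, and comments in `[]` are stripped. Zero-length internal edges
are *retained* — they place a tree on an orthant boundary, which is
exactly the property that distinguishes binary from non-binary trees
here — but can be collapsed on request. Negative branch lengths are an
error by default (`clamp_negative` replaces them with 0 and warns).
Branch-length units are whatever the Newick encodes (substitutions per
site for typical inputs); no conversion is applied.

## BHV geodesics (GTP)

The geodesic between trees $T, T'$ is computed by the standard
polynomial-time scheme:

1. **Common edges** — splits present in both trees, or present in one
   and compatible with every split of the other (treated as common
   with partner length 0) — are peeled off; they travel linearly and
   contribute $(\ell - \ell')^2$ to the squared distance.
2. The remaining disjoint splits are decomposed into **connected
   components of the bipartite incompatibility graph**. Splits in
   different components are mutually compatible, so tree space factors
   locally as a product and each component's geodesic is computed
   independently. (This refines the usual decomposition at common
   edges, which always separates components.)
3. Each component starts from the single-pair **cone path** and is
   successively refined: for a support pair $(A, B)$, vertex weights
   are $|e|^2/\|A\|^2$ on the $A$ side and $|e|^2/\|B\|^2$ on the $B$
   side, with an edge wherever two splits are incompatible. The exact
   minimum-weight vertex cover is found by max-flow/min-cut (König
   duality; networkx, float capacities). If the cover weighs less than
   $1 - 10^{-12}$, the pair splits and both halves recurse. The
   $10^{-12}$ slack prevents infinite refinement from floating-point
   noise at weight exactly 1.
4. Component supports are merged in non-decreasing order of
   $\|A_i\|/\|B_i\|$; the squared length is
   $\sum_i (\|A_i\| + \|B_i\|)^2$ plus the common-edge terms.

Zero-length splits contribute nothing to any norm; they are kept out
of the refinement and re-attached afterwards (to the first drop block
or last grow block, or reported as common when compatible with all
positive splits of the other side), so the support still accounts for
every input edge without perturbing the length.

Correctness is checked against an independent brute-force oracle that
enumerates all ordered partition-pair supports satisfying the two
geodesic conditions — later-dropped splits compatible with
earlier-grown ones, and non-decreasing drop/grow ratios — and takes
the minimum of the length formula. The ratio condition is essential:
a support with inverted ratios does not describe an achievable path
length (the infimum in that path space corresponds to merged blocks),
and omitting it makes the "oracle" underestimate the distance.

External branch lengths are not part of tree space and never enter the
distance; points along a geodesic interpolate them linearly.

## Log maps

With a binary base tree $T^*$ (all $m$ internal lengths positive), the
plain log map assigns, per base edge $e$:

* $e$ common to both trees (including compatible-but-absent, partner
  length 0): coordinate $|e|_T - |e|_{T^*}$;
* $e$ in drop block $A_i$: coordinate
  $-|e|_{T^*} (\|A_i\| + \|B_i\|)/\|A_i\|$.

By construction the vector's norm equals $\gamma(T^*, T)$ exactly, and
the squared coordinates within one drop block sum to
$(\|A_i\|+\|B_i\|)^2$. Splits of $T$ absent from the base contribute
only through the block norms — the map is many-to-one, and the test
suite includes a constructed collision to document this. The modified
variant adds $t^*$; the augmented variant appends the pendant lengths.
A non-binary base is a hard error (it sits in a low-dimensional
stratum and compresses the chart); the error message points to the
base-selection rules.

## Base trees and the Fréchet mean

`select_base_tree` either minimizes $\sum_s \gamma(s,t)^2$ over the
*binary* members of the collection (phylogenomic tree included among
candidates when supplied; ties broken by input order) or takes the
phylogenomic tree directly, which must be binary. When both rules are
available the CLI prints both criterion values so users can see
whether they coincide.

The Fréchet mean is approximated by the iterative proximal scheme:
from an initial tree, step $k$ moves the iterate $1/(k+1)$ of the way
along its geodesic to the next tree. The default visitation order is a
**cyclic sweep** of the collection: inside a single orthant the
iterate is then the exact running mean, so after full sweeps it lands
on the coordinate-wise mean with no Monte-Carlo error, and for the
two-tree mirrored configuration it contracts the contested edge
*exactly* at even iteration counts. Uniformly random draws (the
classical stochastic scheme) are available via `order="random"` with a
seed; they converge like $1/\sqrt{k}$ and are only preferable as a
sanity check against order effects. Default budget: `n_iter=1000`,
early stop when every step in a 50-step window moves the iterate less
than `tol=1e-6`. The mean of discordant collections is typically
non-binary (near-zero or absent internal edges); callers report edges
below $10^{-8}$ as unresolved.

## Dimension reduction

PCA mean-centers but does not standardize columns: all coordinates
share branch-length units, and standardizing would inflate
near-constant coordinates into noise directions. Variance shares are
reported over all components (they sum to 1); because the log map is
many-to-one, these shares overstate the fraction of *tree-space*
variation explained. Loading signs are fixed by making each
component's largest-magnitude loading positive, so scores are
deterministic. Classical MDS double-centers the squared distance
matrix and keeps the top-$q$ non-negative eigenpairs; negative
eigenvalue mass — expected for BHV/RF matrices, which are not
Euclidean — is truncated and its spectrum fraction reported. Nonmetric
MDS runs SMACOF with isotonic regression from the classical solution
and reports Kruskal stress-1.

Tree rescaling divides every branch (internal and external) by the
tree's total branch length, so rescaled trees have total length 1 and
contrasts reflect the distribution of length rather than overall rate.
`tree_contrast_stats` reports BHV, RF, the absolute difference in
$\sum \ell^2$ over all branches, and per-tree mean/median branch
lengths — together these separate topology-driven from length-driven
separation between two trees.

## Outlier diagnosis: two screens

`flag_outliers` scores each tree per plotted embedding component with
a robust z-score $|x - \mathrm{med}|/(1.4826\,\mathrm{MAD})$ and flags
any score above 3.5 (components with zero MAD are skipped with a
warning). This is the conservative, visualization-consistent screen:
on quiet collections its false-flag rate is small, and a flag means
the point visibly separates in the plot.

`flag_outlier_features` applies the same statistic per log-map
*coordinate* and ranks trees by their maximum feature score. Because
each coordinate is scaled by its own spread across genes, a branch
that is 10× its typical length stands out even when the branch is
short in absolute terms — a direction that principal components, which
chase absolute variance, can bury far down the spectrum. The pipeline
therefore uses the feature screen for its *outlier ranking* (a
threshold-free triage list) and the component screen for the `flagged`
column. The two disagree by design on collections with strong
topological discordance: a gene that crossed an orthant boundary at a
long edge is a genuine topological outlier to the feature screen even
though it may sit inside the main cloud of the 2-D plot, and the
feature screen's raw scores are not calibrated for a fixed threshold
under multiplicative (right-skewed) length noise — hence ranking, not
flagging, is its contract.

## Synthetic collections

The generator emulates the inputs the tool is built for: a shared
binary "species" topology drawn uniformly (sequential attachment of
tips to uniformly chosen edges), i.i.d. exponential branch lengths
(default mean 0.1 substitutions/site, a typical scale for single-copy
microbial protein genes), per-gene discordance as a Poisson number of
NNI moves at uniformly chosen internal edges (NNI is the orthant
adjacency of BHV space, so discordance is local in exactly the
geometry under study; swapped edges keep their lengths), multiplicative
lognormal(0, σ) noise on every branch, and injected outliers that
multiply one pendant or one internal branch by a factor (default 10) —
the two archetypes of anomalous gene phylogenies: a single divergent
genome for one gene, and a deep split dividing the genomes for one
gene. Default study conditions: 20 genomes, 50 genes, NNI rate 1,
σ = 0.3.

What the generator does *not* emulate: phylogenetic estimation error
correlated with alignment length, horizontal transfer of clades
(discordance here is NNI-local), rate heterogeneity across lineages,
and any connection between topological discordance and branch length
(real discordance concentrates on short branches; the generator picks
edges uniformly, which makes its topological noise *heavier*-tailed
than real collections). Passing the recovery tests therefore shows the
screens work against a harsher topological background than typical
real data, but says nothing about estimation artifacts such as
alignment errors.

All randomness flows from integer seeds through independent child
streams, so any sub-result can be regenerated alone and repeated runs
are byte-identical.

## Numerical conventions and degenerate inputs

Distances and log maps are exact up to float arithmetic (no iterative
tolerance); the refinement threshold is the only numeric knob. Points
at exact geodesic breakpoints drop float-residue edges below
$10^{-15}(\|A_i\|+\|B_i\|)$. PCA on an all-identical collection raises
(no variance to decompose); rescaling an all-zero-length tree raises;
collections with mismatched tip sets raise naming the offending trees
and the label symmetric difference — trees missing taxa are out of
scope by the geometry itself (BHV space is defined for a fixed tip
set). Newick writing uses `%.17g`, so parse∘write is the identity on
split sets and lengths.

## Problem sizes

Default test and acceptance runs use 5–7-tip trees for brute-force
oracle comparisons (the enumeration is exponential in the number of
disjoint splits), 20-genome × 50-gene collections for the simulation
studies, and 100 seeded replicates for recovery/false-flag rates;
these sizes make the full suite run in about a minute while keeping
every estimate's Monte-Carlo error well inside the margins being
asserted.
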