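# treelens

Collections of phylogenetic trees as data objects.

`treelens` is for microbial phylogenomics practitioners who estimate one
tree per gene across a set of genomes — plus, usually, a single
*phylogenomic* tree from a concatenated alignment — and want to see the
whole collection at once: which genes agree, which are anomalous, and
how robust the phylogenomic tree is to the choice of genes. Instead of
comparing trees only through pairwise dissimilarities, each tree is
mapped to a Euclidean vector and the collection is analyzed with
ordinary multivariate tools.

## The method

Trees with the same $m+3$ tips live in Billera–Holmes–Vogtmann (BHV)
tree space: one non-negative Euclidean orthant per binary topology,
with coordinates the internal branch lengths, orthants glued along
shared boundary (NNI-adjacent) topologies. The geodesic distance
$\gamma(T, T')$ in this space accounts for differences in both topology
and internal branch lengths; it is computed here with the
polynomial-time GTP algorithm (successive support refinement via exact
minimum-weight vertex covers on bipartite incompatibility graphs).

Around a **binary base tree** $T^*$, the collection is linearized with
the log map

$$\log_{T^*}(T) = \gamma(T^*, T)\, v_{T^*}(T) \in \mathbb{R}^m,$$

where $v_{T^*}(T)$ is the unit direction of the first geodesic segment
out of $T^*$. The *modified* log map adds $t^*$ (the base's internal
lengths), so edges shared with the base keep their own length as the
coordinate; the *augmented* log map appends the $m+3$ external
(pendant) branch lengths in alphabetical tip order, giving one vector
in $\mathbb{R}^{2m+3}$ per tree that preserves geodesic distance and
local direction from the base plus all pendant lengths.

The base tree is chosen either as the **binary tree minimizing**
$\sum_s \gamma(s, t)^2$ over the collection (necessarily binary by
construction) or as the supplied **phylogenomic tree**. The Fréchet
mean — the unconstrained minimizer of the same criterion — is computed
for diagnostics but deliberately not used as a base: for real gene-tree
collections it is almost always non-binary and sits in a
low-dimensional stratum of tree space, which distorts the chart.

The vectors are then reduced with PCA (no column standardization) for
scatterplots; metric (Torgerson) and nonmetric (Kruskal) MDS on BHV or
Robinson–Foulds distance matrices are available as alternatives.
Outliers are diagnosed at two levels: a conservative robust z-score
screen on the plotted components (`flag_outliers`), and a scale-aware
per-coordinate ranking on the log-map features themselves
(`flag_outlier_features`) that catches anomalies on short branches
which absolute-variance components bury.

## Worked example

Simulate a gene-tree collection — 50 genes on 20 genomes, Poisson(1)
NNI discordance, lognormal(0, 0.3) branch noise — with two planted
anomalies: one gene whose pendant branch is multiplied by 10 and one
with a 10× internal branch. Then embed and screen it:

```bash
treelens simulate --tips 20 --genes 50 --nni-rate 1 --sigma 0.3 \
    --outliers external:10,internal:10 --seed 7 -o demo
treelens embed --trees demo/genes --plot embedding.png -o demo_out
```

The run log and report (abridged, as printed):

```
[treelens +  0.01s] validate: n_trees=50 n_leaves=20
[treelens +  0.33s] embed: method=pca q=2 shape=[50, 2]
[treelens +  0.34s] flag: n_flagged=8 top=['gene_02', 'gene_03', 'gene_08']
  "base_tree": "gene_41",
  "variance_explained": [0.29107918277759554, 0.1980899187258184],
  "outlier_ranking": [
    {"tree": "gene_02", "score": 33.0682},
    {"tree": "gene_03", "score": 31.5929},
    {"tree": "gene_08", "score": 10.308},
    ...
```

Reading the numbers: the most central binary gene tree (`gene_41`) was
selected as the base; PC1 and PC2 explain 29% and 20% of the log-map
variance; and the outlier ranking puts the two planted genes far ahead
of the field (scores 33.1 and 31.6 against 10.3 for the next gene) —
`demo/truth.csv` confirms `gene_02` carries the long pendant branch and
`gene_03` the long internal branch. `coords.csv` holds one row per tree
with its PC coordinates, ranking score, and component-screen flag;
`embedding.png` (or `.html`, with hover tree thumbnails) shows the
scatter with outliers labeled and any phylogenomic tree in red.

To check robustness of a summary tree to gene choice, re-run with
`--drop gene_02,gene_03` and supply a re-estimated reduced-set tree via
`--phylo-reduced`; the report then includes the BHV and RF distances
between the two phylogenomic trees alongside both embedded points.

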