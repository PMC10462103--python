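"""Synthetic gene-tree collections with controllable discordance.

The generator emulates what a set of single-copy gene trees from a
microbial genus looks like to the embedding pipeline: one shared binary
"species" topology; per-gene topological discordance as a Poisson number
of nearest-neighbor-interchange (NNI) moves — NNI is the orthant
adjacency of BHV space, so discordance is local in exactly the geometry
being analyzed; multiplicative lognormal branch-length noise standing in
for per-gene rate variation; and injected outlier trees carrying one
anomalously long external or internal branch, the two archetypes of
outlying gene phylogenies (a single divergent genome for one gene, and a
deep split dividing the genomes into two clades for that gene).

Everything is reproducible from integer seeds: each operation derives an
independent child RNG stream so sub-results can be regenerated alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .tree import PhyloTree, Split, make_split, write_newick


@dataclass
class OutlierSpec:
    kind: str  # "external" | "internal"
    factor: float = 10.0
    target: str | None = None  # tip label (external); unset = random

    def __post_init__(self):
        if self.kind not in ("external", "internal"):
            raise ValueError(f"unknown outlier kind {self.kind!r}")
        if self.factor <= 1:
            raise ValueError("outlier factor must be > 1")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic collection.

    Defaults are a desk-scale analogue of a single-genus analysis:
    20 genomes, 50 single-copy genes, on average one NNI of discordance
    per gene, 0.3 lognormal sigma of branch-length noise, and mean
    branch length 0.1 substitutions/site.
    """

    n_tips: int = 20
    n_genes: int = 50
    nni_rate: float = 1.0
    length_sigma: float = 0.3
    base_length_mean: float = 0.1
    outliers: list = field(default_factory=list)  # list[OutlierSpec]
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        self.outliers = [o if isinstance(o, OutlierSpec) else OutlierSpec(**o)
                         for o in self.outliers]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _tip_labels(n_tips: int) -> list:
    width = len(str(n_tips))
    return [f"t{str(i + 1).zfill(width)}" for i in range(n_tips)]


def random_binary_tree(n_tips: int, seed=0, base_length_mean: float = 0.1,
                       labels=None, name: str = "") -> PhyloTree:
    """Uniform random unrooted binary labeled topology.

    Built by sequential attachment: each next leaf subdivides a
    uniformly chosen edge, which yields the uniform distribution over
    the (2n-5)!! labeled topologies.  Branch lengths are i.i.d.
    exponential with mean ``base_length_mean``.
    """
    if n_tips < 4:
        raise ValueError("n_tips must be >= 4")
    rng = _as_rng(seed)
    labels = list(labels) if labels is not None else _tip_labels(n_tips)
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")

    # leaves are nodes 0..n-1; internal nodes follow
    edges = [(0, n_tips), (1, n_tips), (2, n_tips)]
    next_node = n_tips + 1
    for leaf in range(3, n_tips):
        k = int(rng.integers(len(edges)))
        u, v = edges.pop(k)
        w = next_node
        next_node += 1
        edges.extend([(u, w), (w, v), (leaf, w)])

    adj: dict[int, list] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    # leafset below each directed edge, rooted at leaf 0
    below: dict[tuple, set] = {}

    def walk(node, parent):
        if node < n_tips:
            below[(parent, node)] = {node}
            return {node}
        acc = set()
        for nb in adj[node]:
            if nb != parent:
                acc |= walk(nb, node)
        below[(parent, node)] = acc
        return acc

    walk(adj[0][0], 0)

    internal_sides = []
    for (parent, node), leafset in below.items():
        if 2 <= len(leafset) <= n_tips - 2:
            internal_sides.append(frozenset(labels[i] for i in leafset))

    sorted_labels = sorted(labels)
    external = {}
    for lab in sorted_labels:
        external[lab] = float(rng.exponential(base_length_mean))
    internal = {}
    splits = sorted((make_split(side, labels) for side in internal_sides),
                    key=lambda s: s.sort_key())
    for s in splits:
        internal[s] = float(rng.exponential(base_length_mean))
    return PhyloTree(tuple(labels), internal, external, name=name)


# ---------------------------------------------------------------------------
# NNI moves on the split representation
# ---------------------------------------------------------------------------

def _maximal_items(region: frozenset, sides: list, leaves) -> list:
    """Maximal split sides / single leaves properly inside ``region``."""
    inside = [s for s in sides if s < region]
    maximal = [s for s in inside if not any(s < t for t in inside)]
    covered = set().union(*maximal) if maximal else set()
    items = maximal + [frozenset([leaf]) for leaf in region - covered]
    return sorted(items, key=lambda x: tuple(sorted(x)))


def nni_move(tree: PhyloTree, split: Split, rng) -> PhyloTree:
    """One nearest-neighbor interchange across ``split``.

    The edge's two incident node neighborhoods each carry two subtrees;
    swapping one from each side crosses into an adjacent orthant of BHV
    space.  The moved edge keeps its branch length.
    """
    leaves = frozenset(tree.leaf_labels)
    sides = [s.side for s in tree.internal_edges]
    children = _maximal_items(split.side, sides, leaves)
    parents = [s for s in sides if split.side < s]
    if parents:
        p = min(parents, key=len)
        siblings = [x for x in _maximal_items(p, sides, leaves) if x != split.side]
    else:
        # split's far endpoint is the root trifurcation: siblings are the
        # other maximal subtrees hanging off it
        siblings = [x for x in _maximal_items(leaves, sides, leaves)
                    if x != split.side]
    c = children[int(rng.integers(len(children)))]
    w = siblings[int(rng.integers(len(siblings)))]
    new_side = (split.side - c) | w
    new_split = make_split(new_side, tree.leaf_labels)
    internal = dict(tree.internal_edges)
    length = internal.pop(split)
    internal[new_split] = internal.get(new_split, 0.0) + length
    return PhyloTree(tree.leaf_labels, internal, dict(tree.external_edges),
                     name=tree.name)


def perturb_gene_tree(base: PhyloTree, nni_rate: float = 1.0,
                      length_sigma: float = 0.3, seed=0,
                      name: str = "") -> PhyloTree:
    """Gene tree = species tree + Poisson(nni_rate) NNIs + lognormal noise.

    Each branch is multiplied by an independent lognormal(0, sigma)
    factor; with ``length_sigma=0`` and ``nni_rate=0`` the gene tree
    equals the species tree.
    """
    rng = _as_rng(seed)
    tree = base.copy(name=name or base.name)
    k = int(rng.poisson(nni_rate)) if nni_rate > 0 else 0
    for _ in range(k):
        splits = sorted(tree.internal_edges, key=lambda s: s.sort_key())
        s = splits[int(rng.integers(len(splits)))]
        tree = nni_move(tree, s, rng)
        tree.name = name or base.name
    if length_sigma > 0:
        internal = {}
        for s in sorted(tree.internal_edges, key=lambda s: s.sort_key()):
            internal[s] = tree.internal_edges[s] * float(rng.lognormal(0.0, length_sigma))
        external = {}
        for leaf in tree.leaf_labels:
            external[leaf] = tree.external_edges[leaf] * float(rng.lognormal(0.0, length_sigma))
        tree = PhyloTree(tree.leaf_labels, internal, external, name=tree.name)
    return tree


def inject_outlier(tree: PhyloTree, kind: str, factor: float,
                   target=None, seed=0) -> PhyloTree:
    """Multiply exactly one branch length by ``factor``.

    ``kind='external'``: a pendant branch (one anomalously divergent
    genome for this gene).  ``kind='internal'``: an internal branch (a
    deep split separating two clades for this gene).  Random target when
    unset.
    """
    rng = _as_rng(seed)
    out = tree.copy()
    if kind == "external":
        if target is None:
            target = tree.leaf_labels[int(rng.integers(len(tree.leaf_labels)))]
        if target not in out.external_edges:
            raise ValueError(f"tip {target!r} not in tree")
        out.external_edges[target] = out.external_edges[target] * factor
    elif kind == "internal":
        splits = sorted(out.internal_edges, key=lambda s: s.sort_key())
        if not splits:
            raise ValueError("tree has no internal edges")
        if target is None:
            target = splits[int(rng.integers(len(splits)))]
        if target not in out.internal_edges:
            raise ValueError(f"split {target!r} not in tree")
        out.internal_edges[target] = out.internal_edges[target] * factor
    else:
        raise ValueError(f"unknown outlier kind {kind!r}")
    return out


def simulate_collection(cfg: SimulationConfig):
    """Generate (species_tree, gene_trees, truth) from a config.

    ``truth`` is a list of dict records naming each injected outlier
    gene, the kind of anomaly, the multiplier, and the affected branch.
    """
    if len(cfg.outliers) > cfg.n_genes:
        raise ValueError("more outliers requested than genes")
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(2 ** 31, size=2 * cfg.n_genes + 2)

    species = random_binary_tree(cfg.n_tips, seed=int(seeds[0]),
                                 base_length_mean=cfg.base_length_mean,
                                 name="species")
    width = len(str(cfg.n_genes))
    genes = []
    for i in range(cfg.n_genes):
        gname = f"gene_{str(i).zfill(width)}"
        genes.append(perturb_gene_tree(species, cfg.nni_rate, cfg.length_sigma,
                                       seed=int(seeds[1 + i]), name=gname))

    truth = []
    pick_rng = np.random.default_rng(int(seeds[1 + cfg.n_genes]))
    idx = pick_rng.choice(cfg.n_genes, size=len(cfg.outliers), replace=False)
    for j, (gi, spec) in enumerate(zip(idx, cfg.outliers)):
        seed_j = int(seeds[2 + cfg.n_genes + j])
        target = spec.target
        tree = inject_outlier(genes[gi], spec.kind, spec.factor,
                              target=target, seed=seed_j)
        # recover which branch was hit for the truth table
        if spec.kind == "external":
            hit = next(lab for lab in tree.leaf_labels
                       if tree.external_edges[lab] != genes[gi].external_edges[lab])
        else:
            hit = "|".join(sorted(next(
                s for s in tree.internal_edges
                if tree.internal_edges[s] != genes[gi].internal_edges[s]).side))
        genes[int(gi)] = tree
        truth.append({"gene": tree.name, "kind": spec.kind,
                      "factor": spec.factor, "branch": str(hit)})
    return species, genes, truth


def write_collection(species: PhyloTree, genes, truth, outdir,
                     cfg: SimulationConfig | None = None) -> None:
    """Write Newick files plus truth.csv / config.json to a directory.

    Gene trees go under ``genes/`` so the directory can be fed straight
    to the embedding commands; the species tree sits alongside (it plays
    the role of a separately-supplied summary tree).
    """
    outdir = Path(outdir)
    (outdir / "genes").mkdir(parents=True, exist_ok=True)
    (outdir / "species.nwk").write_text(write_newick(species) + "\n")
    for g in genes:
        (outdir / "genes" / f"{g.name}.nwk").write_text(write_newick(g) + "\n")
    lines = ["gene,kind,factor,branch"]
    lines += [f"{r['gene']},{r['kind']},{r['factor']},{r['branch']}" for r in truth]
    (outdir / "truth.csv").write_text("\n".join(lines) + "\n")
    if cfg is not None:
        payload = asdict(cfg)
        (outdir / "config.json").write_text(json.dumps(payload, indent=2) + "\n")
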