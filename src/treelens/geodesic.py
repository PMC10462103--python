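"""BHV geodesics between trees via the polynomial-time GTP algorithm.

The Billera-Holmes-Vogtmann distance between two trees on the same leaf
set is the length of the unique shortest path through the orthant
complex of tree space.  Following Owen & Provan's geodesic
characterization, the path is described by a *support*: an ordered list
of pairs (A_i, B_i), where the A_i partition the source-tree edges that
must shrink to zero and the B_i partition the target-tree edges that
grow, with

    length^2 = sum_i (||A_i|| + ||B_i||)^2 + sum_common (l_src - l_tgt)^2,

||.|| the Euclidean norm of the branch lengths in a block.  Edges shared
by both trees (or present in one tree and compatible with every split of
the other) travel linearly and contribute the squared length difference.

The support starts from the single-pair *cone path* and is iteratively
refined: a pair splits whenever the minimum-weight vertex cover of its
bipartite incompatibility graph (vertex weights |e|^2 normalized by the
block's squared norm) weighs less than 1.  Covers are solved exactly by
max-flow / min-cut (König duality).  Only internal edges participate;
external branch lengths are not part of tree space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .tree import (LeafSetMismatchError, PhyloTree, Split, splits_compatible,
                   validate_collection)

_COVER_TOL = 1e-12  # split a pair only when min cover weight < 1 - tol


@dataclass
class SupportPair:
    """One leg of a geodesic support: edges dropped (A) and grown (B)."""

    A: dict  # Split -> source-tree length
    B: dict  # Split -> target-tree length

    @property
    def norm_A(self) -> float:
        return math.sqrt(sum(v * v for v in self.A.values()))

    @property
    def norm_B(self) -> float:
        return math.sqrt(sum(v * v for v in self.B.values()))

    @property
    def ratio(self) -> float:
        na, nb = self.norm_A, self.norm_B
        return na / nb if nb > 0 else math.inf


@dataclass
class GeodesicResult:
    """A BHV geodesic: support legs, common edges, and total length."""

    support: list  # list[SupportPair], in traversal order
    common_edges: list  # list[(Split, length_in_source, length_in_target)]
    length: float
    source_name: str = ""
    target_name: str = ""
    source: PhyloTree | None = field(default=None, repr=False)
    target: PhyloTree | None = field(default=None, repr=False)


def _check_leafsets(t1: PhyloTree, t2: PhyloTree) -> None:
    if t1.leaf_labels != t2.leaf_labels:
        raise LeafSetMismatchError(
            f"trees {t1.name!r} and {t2.name!r} have different leaf sets")


def _peel_common(t1: PhyloTree, t2: PhyloTree):
    """Separate common edges from the disjoint remainders.

    An edge is *common* if its split occurs in both trees, or if it is
    compatible with every split of the other tree (then it is common
    with partner length 0, per the standard GTP decomposition).
    """
    s1, s2 = t1.internal_edges, t2.internal_edges
    common = []
    A, B = {}, {}
    for s, l1 in s1.items():
        if s in s2:
            common.append((s, l1, s2[s]))
        elif all(splits_compatible(s, t) for t in s2):
            common.append((s, l1, 0.0))
        else:
            A[s] = l1
    for s, l2 in s2.items():
        if s in s1:
            continue
        if all(splits_compatible(s, t) for t in s1):
            common.append((s, 0.0, l2))
        else:
            B[s] = l2
    return common, A, B


def _min_vertex_cover(A: dict, B: dict, edges: list):
    """Exact min-weight vertex cover of the bipartite incompatibility graph.

    Vertex weights are |e|^2 normalized by the squared norm of the
    containing block, so the full A side (or B side) always weighs 1.
    Solved via max-flow/min-cut; returns (cover_weight, C1, D2) with
    C1 the covered A-vertices and D2 the covered B-vertices.
    """
    wa = sum(v * v for v in A.values())
    wb = sum(v * v for v in B.values())
    G = nx.DiGraph()
    for a, la in A.items():
        G.add_edge("s", ("a", a), capacity=la * la / wa)
    for b, lb in B.items():
        G.add_edge(("b", b), "t", capacity=lb * lb / wb)
    for a, b in edges:
        G.add_edge(("a", a), ("b", b), capacity=math.inf)
    cut_value, (S, _) = nx.minimum_cut(G, "s", "t")
    C1 = {a: A[a] for a in A if ("a", a) not in S}
    D2 = {b: B[b] for b in B if ("b", b) in S}
    return cut_value, C1, D2


def _refine(A: dict, B: dict) -> list:
    """Owen-Provan successive refinement starting from the cone pair.

    Precondition: every split in A is incompatible with at least one in
    B and vice versa (guaranteed by peeling), and all lengths > 0.
    """
    final: list[SupportPair] = []
    stack = [(A, B)]
    # depth-first, left leg first, keeps traversal order
    while stack:
        curA, curB = stack.pop()
        edges = [(a, b) for a in curA for b in curB
                 if not splits_compatible(a, b)]
        weight, C1, D2 = _min_vertex_cover(curA, curB, edges)
        proper = (0 < len(C1) < len(curA)) and (0 <= len(D2) < len(curB)) and D2
        if weight < 1.0 - _COVER_TOL and proper:
            C2 = {a: v for a, v in curA.items() if a not in C1}
            D1 = {b: v for b, v in curB.items() if b not in D2}
            # order matters: (C1, D1) precedes (C2, D2) on the path
            stack.append((C2, D2))
            stack.append((C1, D1))
        else:
            final.append(SupportPair(dict(curA), dict(curB)))
    # re-walk in path order: the stack discipline above emits pairs in
    # order because we push the right leg first and pop the left
    return final


def _components(A: dict, B: dict):
    """Connected components of the incompatibility graph.

    Splits in different components are mutually compatible, so tree
    space factors locally as a product and the geodesic decomposes; this
    refines the decomposition at common edges.
    """
    G = nx.Graph()
    G.add_nodes_from(("a", a) for a in A)
    G.add_nodes_from(("b", b) for b in B)
    for a in A:
        for b in B:
            if not splits_compatible(a, b):
                G.add_edge(("a", a), ("b", b))
    out = []
    for comp in nx.connected_components(G):
        subA = {a: A[a] for side, a in comp if side == "a"}
        subB = {b: B[b] for side, b in comp if side == "b"}
        out.append((subA, subB))
    return out


def gtp_geodesic(t1: PhyloTree, t2: PhyloTree) -> GeodesicResult:
    """Geodesic between two trees on the same leaf set (GTP algorithm)."""
    _check_leafsets(t1, t2)
    common, A, B = _peel_common(t1, t2)

    # zero-length splits sit on orthant boundaries and contribute nothing
    # to any norm; keep them out of the refinement, re-attach afterwards
    zeroA = {s: v for s, v in A.items() if v == 0.0}
    zeroB = {s: v for s, v in B.items() if v == 0.0}
    A = {s: v for s, v in A.items() if v > 0.0}
    B = {s: v for s, v in B.items() if v > 0.0}
    # a positive split whose only incompatibilities were with zero-length
    # splits is effectively common (compatible with everything of weight);
    # moving one can free up others, so iterate to a fixpoint
    changed = True
    while changed:
        changed = False
        for s in list(A):
            if all(splits_compatible(s, t) for t in B):
                common.append((s, A.pop(s), 0.0))
                changed = True
        for s in list(B):
            if all(splits_compatible(s, t) for t in A):
                common.append((s, 0.0, B.pop(s)))
                changed = True

    support: list[SupportPair] = []
    for subA, subB in _components(A, B):
        support.extend(_refine(subA, subB))
    support.sort(key=lambda p: p.ratio)

    if zeroA or zeroB:
        if support:
            support[0].A.update(zeroA)
            support[-1].B.update(zeroB)
        elif zeroA and zeroB:
            support.append(SupportPair(dict(zeroA), dict(zeroB)))
        elif zeroA:
            common.extend((s, 0.0, 0.0) for s in zeroA)
        else:
            common.extend((s, 0.0, 0.0) for s in zeroB)

    sq = sum((p.norm_A + p.norm_B) ** 2 for p in support)
    sq += sum((l1 - l2) ** 2 for _, l1, l2 in common)
    return GeodesicResult(support=support, common_edges=common,
                          length=math.sqrt(sq),
                          source_name=t1.name, target_name=t2.name,
                          source=t1, target=t2)


def bhv_distance(t1: PhyloTree, t2: PhyloTree) -> float:
    """BHV distance: length of the geodesic (internal edges only)."""
    return gtp_geodesic(t1, t2).length


def cone_path_length(t1: PhyloTree, t2: PhyloTree) -> float:
    """Length of the two-segment path through the origin (star tree).

    Always an upper bound on the BHV distance; tight exactly when every
    disjoint source split is incompatible with every disjoint target
    split (complete bipartite incompatibility graph).
    """
    _check_leafsets(t1, t2)
    common, A, B = _peel_common(t1, t2)
    na = math.sqrt(sum(v * v for v in A.values()))
    nb = math.sqrt(sum(v * v for v in B.values()))
    sq = (na + nb) ** 2 + sum((l1 - l2) ** 2 for _, l1, l2 in common)
    return math.sqrt(sq)


def rf_distance(t1: PhyloTree, t2: PhyloTree, collapse_zero: bool = False) -> int:
    """Robinson-Foulds distance: |symmetric difference of internal splits|.

    Topology only; zero-length splits count unless ``collapse_zero``.
    """
    _check_leafsets(t1, t2)
    if collapse_zero:
        t1, t2 = t1.collapsed(), t2.collapsed()
    return len(set(t1.internal_edges) ^ set(t2.internal_edges))


def geodesic_point(geo: GeodesicResult, lam: float) -> PhyloTree:
    """The tree at fraction ``lam`` along a geodesic.

    With ratio breakpoints lambda_i = ||A_i|| / (||A_i|| + ||B_i||), the
    tree between breakpoints i and i+1 holds the not-yet-dropped A_j
    (j > i) with lengths shrunk proportionally and the already-grown B_j
    (j <= i) with lengths grown proportionally; common and external
    edges interpolate linearly.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    t1, t2 = geo.source, geo.target
    if t1 is None or t2 is None:
        raise ValueError("geodesic lacks endpoint trees")
    if lam == 0.0:
        return t1.copy()
    if lam == 1.0:
        return t2.copy()

    internal: dict[Split, float] = {}
    for s, l1, l2 in geo.common_edges:
        length = (1 - lam) * l1 + lam * l2
        if length > 0:
            internal[s] = length
    for pair in geo.support:
        na, nb = pair.norm_A, pair.norm_B
        if na + nb == 0:
            continue
        eps = 1e-15 * (na + nb)  # float residue at exact breakpoints
        if lam < na / (na + nb):  # leg not yet crossed: A edges persist
            scale = ((1 - lam) * na - lam * nb) / na
            for s, l in pair.A.items():
                if scale * l > eps:
                    internal[s] = scale * l
        else:  # leg crossed: B edges have grown
            if nb == 0:
                continue
            scale = (lam * nb - (1 - lam) * na) / nb
            for s, l in pair.B.items():
                if scale * l > eps:
                    internal[s] = scale * l
    external = {leaf: (1 - lam) * t1.external_edges[leaf] + lam * t2.external_edges[leaf]
                for leaf in t1.leaf_labels}
    return PhyloTree(t1.leaf_labels, internal, external,
                     name=f"geodesic({t1.name},{t2.name},{lam:g})")


def distance_matrix(trees, metric: str = "bhv", collapse_zero: bool = False) -> np.ndarray:
    """Symmetric pairwise distance matrix (``bhv`` or ``rf``)."""
    trees = validate_collection(trees)
    n = len(trees)
    D = np.zeros((n, n))
    fn = bhv_distance if metric == "bhv" else \
        (lambda a, b: float(rf_distance(a, b, collapse_zero)))
    if metric not in ("bhv", "rf"):
        raise ValueError(f"unknown metric {metric!r}")
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fn(trees[i], trees[j])
    return D
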