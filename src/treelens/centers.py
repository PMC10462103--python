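"""Central trees: base-tree selection and the Fréchet mean.

The log map chart needs a *binary* base tree.  Two selection rules are
supported: the binary tree in the collection minimizing the sum of
squared BHV distances to all trees (the most central binary tree, binary
by construction), or a user-supplied phylogenomic summary tree.  The
Fréchet mean — the global minimizer of the same criterion over all of
tree space — is computed for diagnostics only: for real microbial
gene-tree collections it is almost always non-binary (it sits on orthant
boundaries), which is exactly why it is avoided as a base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geodesic import bhv_distance, distance_matrix, geodesic_point, gtp_geodesic
from .tree import PhyloTree, is_binary, validate_collection


@dataclass
class BaseSelection:
    base: PhyloTree
    criterion_value: float  # sum of squared BHV distances over the collection
    candidate_scores: dict  # tree name -> criterion value (all candidates)
    rule: str  # min_sq_bhv | phylogenomic | user


def sum_squared_distances(trees, t: PhyloTree, dist_row=None) -> float:
    """Sum over the collection of squared BHV distances to ``t``."""
    if dist_row is not None:
        return float(np.sum(np.asarray(dist_row) ** 2))
    return float(sum(bhv_distance(s, t) ** 2 for s in trees))


def select_base_tree(trees, rule: str = "min_sq_bhv",
                     phylo: PhyloTree | None = None,
                     dist: np.ndarray | None = None) -> BaseSelection:
    """Choose the base tree for log maps.

    ``min_sq_bhv``: candidates are the gene trees plus the phylogenomic
    tree when supplied; among the *binary* candidates, pick the one
    minimizing the sum of squared BHV distances to every tree in the
    collection (ties broken by input order).  ``phylogenomic``: use the
    supplied summary tree, which must be binary.
    """
    trees = list(trees)
    collection = trees + ([phylo] if phylo is not None else [])
    collection = validate_collection(collection)
    if rule == "phylogenomic":
        if phylo is None:
            raise ValueError("rule='phylogenomic' requires a phylogenomic tree")
        if not is_binary(phylo):
            raise ValueError(
                "the phylogenomic tree is not binary; a non-binary base sits "
                "on orthant boundaries and distorts the log map chart — "
                "use rule='min_sq_bhv' instead")
        value = sum_squared_distances(collection, phylo)
        return BaseSelection(phylo, value, {phylo.name: value}, rule)
    if rule != "min_sq_bhv":
        raise ValueError(f"unknown base selection rule {rule!r}")

    if dist is None:
        dist = distance_matrix(collection, metric="bhv")
    scores = {}
    best = None
    for i, cand in enumerate(collection):
        value = float(np.sum(dist[i] ** 2))
        scores[cand.name or f"tree_{i}"] = value
        if is_binary(cand) and (best is None or value < best[1]):
            best = (i, value)
    if best is None:
        raise ValueError("no binary candidate tree: cannot select a base")
    return BaseSelection(collection[best[0]], best[1], scores, rule)


def frechet_mean(trees, n_iter: int = 1000, seed: int = 0, tol: float = 1e-6,
                 order: str = "cyclic"):
    """Iterative Fréchet mean (Sturm's proximal-point scheme).

    Starting from one tree, step k moves the iterate a fraction
    1/(k+1) along its geodesic toward the next tree of the collection.
    ``order='cyclic'`` sweeps the collection in input order — in a single
    orthant the iterate is then the exact running mean, so full sweeps
    land on the arithmetic mean of branch lengths — while
    ``order='random'`` draws uniformly with the given seed.  Stops after
    ``n_iter`` steps or once every step over a 50-step window moves the
    iterate less than ``tol``.

    Returns ``(mean_tree, trace)`` where ``trace`` lists the BHV length
    moved at each step.  The mean is frequently non-binary (near-zero
    internal edges), which is reported by downstream checks.
    """
    trees = validate_collection(trees)
    n = len(trees)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    if order == "random":
        current = trees[int(rng.integers(n))].copy(name="frechet_mean")
    elif order == "cyclic":
        current = trees[0].copy(name="frechet_mean")
    else:
        raise ValueError(f"unknown order {order!r}")

    trace = []
    for k in range(1, n_iter):
        target = trees[int(rng.integers(n))] if order == "random" else trees[k % n]
        geo = gtp_geodesic(current, target)
        lam = 1.0 / (k + 1)
        trace.append(lam * geo.length)
        if geo.length > 0:
            current = geodesic_point(geo, lam)
            current.name = "frechet_mean"
        if k >= 50 and max(trace[-50:]) < tol:
            break
    return current, trace
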