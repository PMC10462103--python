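"""Log maps: Euclidean charts of tree space around a binary base tree.

The log map of a tree T from a base tree T* is gamma(T*, T) times the
unit direction of the first geodesic segment out of T*, expressed in the
base tree's orthant coordinates (one per internal edge of T*).  Its norm
equals the BHV distance, and trees near the base are distorted little.

Three variants are provided:

* ``plain``     — log_{T*}(T) in R^m (m = #tips - 3);
* ``modified``  — plain + t*, where t* holds the base tree's internal
  branch lengths, so a common edge's coordinate is simply its length in
  T;
* ``augmented`` — modified followed by the m+3 external (pendant) branch
  lengths in alphabetical leaf order, giving a vector in R^{2m+3} that
  also preserves pendant-length variation.

The map is many-to-one: trees whose geodesics leave the base in the same
direction at the same distance collide.  That information loss is
inherent to any linear chart of tree space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodesic import gtp_geodesic
from .tree import PhyloTree, Split, is_binary, validate_collection

VARIANTS = ("plain", "modified", "augmented")


@dataclass(frozen=True)
class CoordinateIndex:
    """Fixed coordinate order: canonical base splits, then leaf labels."""

    internal_order: tuple  # m canonical Splits of the base tree
    external_order: tuple  # m+3 leaf labels, lexicographic

    @classmethod
    def for_base(cls, base: PhyloTree) -> "CoordinateIndex":
        internal = tuple(sorted(base.internal_edges, key=lambda s: s.sort_key()))
        return cls(internal, tuple(base.leaf_labels))

    @property
    def m(self) -> int:
        return len(self.internal_order)

    def dim(self, variant: str) -> int:
        return self.m if variant in ("plain", "modified") else 2 * self.m + 3

    def labels(self, variant: str) -> list:
        """Column labels for CSV output: split encodings, then leaves."""
        cols = ["|".join(sorted(s.side)) for s in self.internal_order]
        if variant == "augmented":
            cols += list(self.external_order)
        return cols


@dataclass
class LogmapVector:
    values: np.ndarray
    index: CoordinateIndex
    base_name: str
    tree_name: str
    variant: str


def _require_binary_base(base: PhyloTree) -> None:
    if not is_binary(base):
        raise ValueError(
            f"base tree {base.name!r} is not binary: log maps require a fully "
            "resolved base with positive internal branch lengths (non-binary "
            "trees sit in low-dimensional strata of tree space and distort "
            "the chart); pick a base with select_base_tree")


def _plain_values(base: PhyloTree, tree: PhyloTree, index: CoordinateIndex) -> np.ndarray:
    geo = gtp_geodesic(base, tree)
    coord: dict[Split, float] = {}
    for s, l_base, l_tree in geo.common_edges:
        if s in base.internal_edges:
            # includes base edges absent from the tree but compatible with
            # all of it (partner length 0): coordinate -l_base
            coord[s] = l_tree - l_base
    for pair in geo.support:
        na, nb = pair.norm_A, pair.norm_B
        for s, l in pair.A.items():
            # dropped base edge: shrinks at rate (||A_i||+||B_i||)/||A_i||
            coord[s] = -l * (na + nb) / na
    return np.array([coord[s] for s in index.internal_order], dtype=float)


def log_map(base: PhyloTree, tree: PhyloTree, variant: str = "plain",
            index: CoordinateIndex | None = None) -> LogmapVector:
    """Log map of ``tree`` with respect to a binary ``base`` tree."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    _require_binary_base(base)
    if index is None:
        index = CoordinateIndex.for_base(base)
    values = _plain_values(base, tree, index)
    if variant in ("modified", "augmented"):
        t_star = np.array([base.internal_edges[s] for s in index.internal_order])
        values = values + t_star
    if variant == "augmented":
        ext = np.array([tree.external_edges[leaf] for leaf in index.external_order])
        values = np.concatenate([values, ext])
    return LogmapVector(values=values, index=index, base_name=base.name,
                        tree_name=tree.name, variant=variant)


def modified_log_map(base: PhyloTree, tree: PhyloTree) -> LogmapVector:
    return log_map(base, tree, variant="modified")


def augmented_log_map(base: PhyloTree, tree: PhyloTree) -> LogmapVector:
    return log_map(base, tree, variant="augmented")


def logmap_matrix(trees, base: PhyloTree, variant: str = "augmented",
                  rescale: bool = False):
    """Row-stack the log maps of a collection (input order preserved).

    Returns ``(matrix, index)`` with one row per tree.  With ``rescale``
    each tree (and the base) is first normalized to total branch length
    1, removing overall rate differences between genes.
    """
    from .reduce import rescale_tree  # local import to avoid a cycle

    trees = validate_collection(list(trees) + [base])[:-1]
    if rescale:
        base = rescale_tree(base)
        trees = [rescale_tree(t) for t in trees]
    _require_binary_base(base)
    index = CoordinateIndex.for_base(base)
    rows = [log_map(base, t, variant=variant, index=index).values for t in trees]
    return np.vstack(rows), index
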