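"""Dimension reduction and descriptive statistics for tree collections.

PCA operates on (augmented) log map vectors; classical (Torgerson) and
nonmetric (Kruskal) MDS operate on BHV or RF distance matrices.  Also
here: per-tree rescaling to unit total branch length, pairwise contrast
statistics used to judge whether an embedding separation is driven by
topology or by branch lengths, and robust outlier flagging on embedding
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import MDS as _SkMDS

from .geodesic import bhv_distance, rf_distance
from .tree import PhyloTree


@dataclass
class EmbeddingResult:
    """Low-dimensional coordinates for a collection of trees."""

    coords: np.ndarray  # (n_trees, q)
    method: str  # pca | mds_metric | mds_nonmetric
    metric: str  # logmap_euclidean | bhv | rf
    q: int
    var_explained: np.ndarray | None = None  # all components, sums to 1 (PCA)
    tree_names: list = field(default_factory=list)
    tree_categories: list = field(default_factory=list)
    base_name: str | None = None
    stress: float | None = None  # Kruskal stress-1 (nonmetric MDS)
    neg_eigen_fraction: float | None = None  # dropped mass (classical MDS)

    @property
    def n_trees(self) -> int:
        return self.coords.shape[0]


def pca_embed(vectors: np.ndarray, q: int = 2) -> EmbeddingResult:
    """PCA of row vectors: mean-centered, unscaled, via SVD.

    Columns share branch-length units, so no variance scaling is
    applied.  ``var_explained`` covers all components and sums to 1.
    Sign convention: each loading vector is flipped so its
    largest-magnitude entry is positive, making scores deterministic.
    """
    X = np.asarray(vectors, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 trees")
    if not (1 <= q <= min(n - 1, d)):
        raise ValueError(f"q={q} out of range for {n} x {d} input")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("all trees map to the same vector: no variance to "
                         "decompose (is the collection degenerate?)")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(Vt.shape[0]):
        k = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, k] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = s ** 2
    var_explained = var / var.sum()
    scores = U * s
    return EmbeddingResult(coords=scores[:, :q], method="pca",
                           metric="logmap_euclidean", q=q,
                           var_explained=var_explained)


def mds_embed(dist: np.ndarray, q: int = 2, flavor: str = "metric",
              seed: int = 0) -> EmbeddingResult:
    """MDS of a distance matrix.

    ``metric``: classical scaling (double-centering + top-q eigenpairs);
    negative eigenvalues — expected for non-Euclidean BHV/RF matrices —
    are truncated and their relative magnitude recorded.  ``nonmetric``:
    Kruskal stress-1 minimization (SMACOF with isotonic regression)
    started from the classical solution; the final stress-1 is reported.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    neg = float(np.abs(evals[evals < 0]).sum())
    total = float(np.abs(evals).sum())
    neg_frac = neg / total if total > 0 else 0.0
    if neg_frac > 1e-12:
        warnings.warn(f"classical MDS dropped negative eigenvalue mass "
                      f"({100 * neg_frac:.2f}% of spectrum): distances are "
                      "not exactly Euclidean", stacklevel=2)
    lam = np.clip(evals[:q], 0.0, None)
    coords = evecs[:, :q] * np.sqrt(lam)
    if flavor == "metric":
        return EmbeddingResult(coords=coords, method="mds_metric", metric="",
                               q=q, neg_eigen_fraction=neg_frac)
    if flavor != "nonmetric":
        raise ValueError(f"unknown MDS flavor {flavor!r}")
    mds = _SkMDS(n_components=q, metric="precomputed", metric_mds=False,
                 n_init=1, init="classical_mds", random_state=seed,
                 normalized_stress=True, eps=1e-9, max_iter=500)
    emb = mds.fit(D, init=coords).embedding_
    return EmbeddingResult(coords=emb, method="mds_nonmetric", metric="",
                           q=q, stress=float(mds.stress_),
                           neg_eigen_fraction=neg_frac)


def rescale_tree(tree: PhyloTree) -> PhyloTree:
    """Divide every branch length by the tree's total branch length.

    Removes overall evolutionary-rate differences between genes: after
    rescaling every tree has total length 1, so contrasts reflect the
    *distribution* of length along the tree, not its overall amount.
    """
    total = tree.total_length()
    if total <= 0:
        raise ValueError(f"tree {tree.name!r} has zero total branch length")
    return PhyloTree(tree.leaf_labels,
                     {s: v / total for s, v in tree.internal_edges.items()},
                     {k: v / total for k, v in tree.external_edges.items()},
                     name=tree.name)


def tree_contrast_stats(t1: PhyloTree, t2: PhyloTree) -> dict:
    """Descriptive contrasts between two trees on one leaf set.

    Reports BHV and RF distances, the absolute difference in the sum of
    squared branch lengths over ALL branches (a pure branch-length
    statistic, unlike the BHV distance which is internal-only), and each
    tree's mean/median branch length.  Used to diagnose whether a
    separation seen in an embedding is topological or length-driven.
    """
    def all_lengths(t):
        return np.array(list(t.internal_edges.values()) +
                        list(t.external_edges.values()))

    l1, l2 = all_lengths(t1), all_lengths(t2)
    return {
        "bhv": bhv_distance(t1, t2),
        "rf": rf_distance(t1, t2),
        "sum_sq_diff": abs(float(np.sum(l1 ** 2) - np.sum(l2 ** 2))),
        "mean_branch_length": {t1.name: float(l1.mean()), t2.name: float(l2.mean())},
        "median_branch_length": {t1.name: float(np.median(l1)),
                                 t2.name: float(np.median(l2))},
    }


def flag_outlier_features(matrix, names=None, threshold: float = 3.5):
    """Robust z-score outlier screen on log-map features.

    Same statistic as :func:`flag_outliers` but applied per *feature*
    (log-map coordinate) instead of per embedding component.  Because
    every coordinate is scaled by its own spread across genes, an
    anomalously long branch stands out even when the branch itself is
    short in absolute terms — a low-variance direction that top
    principal components, which chase absolute variance, can bury.  The
    pipeline therefore scores outliers here and uses the PCA scatter
    for display.

    Returns ``[(name, score, flagged)]`` sorted by score descending,
    with score the max robust z over features of nonzero MAD.
    """
    M = np.asarray(matrix, dtype=float)
    med = np.median(M, axis=0)
    mad = np.median(np.abs(M - med), axis=0)
    usable = mad > 0
    if not np.any(usable):
        warnings.warn("no usable features for outlier scoring", stacklevel=2)
        scores = np.zeros(M.shape[0])
    else:
        Z = np.abs(M[:, usable] - med[usable]) / (1.4826 * mad[usable])
        scores = Z.max(axis=1)
    if names is None:
        names = [f"tree_{i}" for i in range(M.shape[0])]
    out = [(names[i], float(scores[i]), bool(scores[i] > threshold))
           for i in range(M.shape[0])]
    out.sort(key=lambda r: (-r[1], r[0]))
    return out


def flag_outliers(emb: EmbeddingResult, threshold: float = 3.5):
    """Robust z-score outlier flagging on embedding components.

    Per retained component: |x - median| / (1.4826 * MAD).  A tree is
    flagged when any component score exceeds ``threshold``.  Returns
    ``[(tree_name, score, flagged)]`` for all trees, sorted by score
    descending (score = max over usable components).  Components with
    zero MAD are skipped with a warning.
    """
    if emb.q < 2:
        raise ValueError("outlier flagging expects a q >= 2 embedding")
    coords = emb.coords
    n = coords.shape[0]
    scores = np.zeros(n)
    any_component = False
    for j in range(coords.shape[1]):
        col = coords[:, j]
        med = np.median(col)
        mad = np.median(np.abs(col - med))
        if mad == 0:
            warnings.warn(f"component {j + 1} has zero MAD; skipped in "
                          "outlier scoring", stacklevel=2)
            continue
        any_component = True
        scores = np.maximum(scores, np.abs(col - med) / (1.4826 * mad))
    if not any_component:
        warnings.warn("no usable components for outlier scoring", stacklevel=2)
    names = emb.tree_names or [f"tree_{i}" for i in range(n)]
    out = [(names[i], float(scores[i]), bool(scores[i] > threshold))
           for i in range(n)]
    out.sort(key=lambda r: (-r[1], r[0]))
    return out
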