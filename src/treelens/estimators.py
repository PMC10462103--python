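"""Scikit-learn style estimators over tree collections.

``TreeVectorizer`` is a transformer from lists of :class:`PhyloTree` to
log-map vectors; ``TreeEmbedding`` composes vectorization (or distance
computation) with PCA/MDS into low-dimensional coordinates.  Both follow
sklearn conventions (``get_params``/``set_params``, ``fit``/``transform``,
fitted attributes with trailing underscores) so they clone and compose
with sklearn model selection; X is a sequence of trees rather than a
numeric array, as with text vectorizers.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .centers import select_base_tree
from .geodesic import distance_matrix
from .logmap import CoordinateIndex, logmap_matrix
from .reduce import EmbeddingResult, mds_embed, pca_embed
from .tree import PhyloTree, validate_collection


class TreeVectorizer(TransformerMixin, BaseEstimator):
    """Embed trees in Euclidean space via log maps around a base tree.

    Parameters
    ----------
    variant : {"augmented", "modified", "plain"}
        Which log map to compute; ``augmented`` (default) appends the
        external branch lengths, giving vectors in R^{2m+3}.
    base : {"min_sq_bhv", "phylogenomic"} or PhyloTree
        Base-tree rule: most central binary tree, the supplied
        phylogenomic tree, or an explicit user tree.
    phylogenomic : PhyloTree, optional
        Summary tree; joins the candidate set under ``min_sq_bhv`` and
        is the base under ``"phylogenomic"``.
    rescale : bool
        Rescale every tree (and the base) to total branch length 1
        before mapping.

    Attributes
    ----------
    base_tree_ : PhyloTree
    selection_ : BaseSelection or None
    index_ : CoordinateIndex
    n_features_out_ : int
    """

    def __init__(self, variant: str = "augmented", base="min_sq_bhv",
                 phylogenomic: PhyloTree | None = None, rescale: bool = False):
        self.variant = variant
        self.base = base
        self.phylogenomic = phylogenomic
        self.rescale = rescale

    def fit(self, X, y=None):
        X = validate_collection(list(X))
        if isinstance(self.base, PhyloTree):
            self.base_tree_ = self.base
            self.selection_ = None
        else:
            rule = {"min_sq_bhv": "min_sq_bhv",
                    "phylogenomic": "phylogenomic"}.get(self.base)
            if rule is None:
                raise ValueError(f"unknown base rule {self.base!r}")
            self.selection_ = select_base_tree(X, rule=rule,
                                               phylo=self.phylogenomic)
            self.base_tree_ = self.selection_.base
        self.index_ = CoordinateIndex.for_base(self.base_tree_)
        self.n_features_out_ = self.index_.dim(self.variant)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "base_tree_"):
            raise RuntimeError("TreeVectorizer is not fitted")
        M, _ = logmap_matrix(X, self.base_tree_, variant=self.variant,
                             rescale=self.rescale)
        return M

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.index_.labels(self.variant), dtype=object)


class TreeEmbedding(BaseEstimator):
    """Low-dimensional embedding of a tree collection.

    ``method="pca"`` runs PCA on (augmented) log-map vectors;
    ``method="mds_bhv"`` / ``"mds_rf"`` run metric or nonmetric MDS on
    the corresponding distance matrix.  ``fit_transform`` returns the
    (n_trees, q) coordinates.

    Attributes
    ----------
    embedding_ : EmbeddingResult
    coords_ : ndarray of shape (n_trees, q)
    explained_variance_ratio_ : ndarray (PCA only; all components)
    base_tree_ : PhyloTree (PCA only)
    stress_ : float (nonmetric MDS only)
    """

    def __init__(self, method: str = "pca", q: int = 2, variant: str = "augmented",
                 base="min_sq_bhv", phylogenomic: PhyloTree | None = None,
                 rescale: bool = False, nonmetric: bool = False,
                 random_state: int = 0):
        self.method = method
        self.q = q
        self.variant = variant
        self.base = base
        self.phylogenomic = phylogenomic
        self.rescale = rescale
        self.nonmetric = nonmetric
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        X = validate_collection(list(X))
        names = [t.name for t in X]
        if self.method == "pca":
            vec = TreeVectorizer(variant=self.variant, base=self.base,
                                 phylogenomic=self.phylogenomic,
                                 rescale=self.rescale)
            M = vec.fit(X).transform(X)
            emb = pca_embed(M, q=self.q)
            emb.base_name = vec.base_tree_.name
            self.vectorizer_ = vec
            self.base_tree_ = vec.base_tree_
            self.explained_variance_ratio_ = emb.var_explained
        elif self.method in ("mds_bhv", "mds_rf"):
            metric = self.method.split("_")[1]
            from .reduce import rescale_tree
            trees = [rescale_tree(t) for t in X] if self.rescale else X
            D = distance_matrix(trees, metric=metric)
            emb = mds_embed(D, q=self.q,
                            flavor="nonmetric" if self.nonmetric else "metric",
                            seed=self.random_state)
            emb.metric = metric
            if self.nonmetric:
                self.stress_ = emb.stress
        else:
            raise ValueError(f"unknown method {self.method!r}")
        emb.tree_names = names
        self.embedding_ = emb
        self.coords_ = emb.coords
        return emb.coords
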