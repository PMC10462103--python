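"""PCA/MDS embeddings, rescaling, contrasts, and outlier flagging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treelens import (EmbeddingResult, bhv_distance, flag_outlier_features,
                      flag_outliers, logmap_matrix, mds_embed, parse_newick,
                      pca_embed, random_binary_tree, rescale_tree,
                      rf_distance, tree_contrast_stats)


class TestPca:
    def test_three_points_rank_two(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 5))
        emb = pca_embed(X, q=2)
        assert emb.var_explained[:2].sum() == pytest.approx(1.0)

    def test_duplicated_rows_identical_scores(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        X[3] = X[0]
        emb = pca_embed(X, q=2)
        assert np.allclose(emb.coords[0], emb.coords[3])

    def test_full_rank_scores_preserve_distances(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 7))
        emb = pca_embed(X, q=7)
        Xc = X - X.mean(axis=0)
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(emb.coords), pdist(Xc), atol=1e-8)

    def test_var_explained_sums_to_one_and_sorted(self):
        rng = np.random.default_rng(3)
        emb = pca_embed(rng.normal(size=(15, 6)), q=2)
        v = emb.var_explained
        assert v.sum() == pytest.approx(1.0)
        assert np.all(np.diff(v) <= 1e-12)
        assert np.all((v >= 0) & (v <= 1))

    def test_row_permutation_invariance_of_variance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        v1 = pca_embed(X, q=2).var_explained
        v2 = pca_embed(X[::-1], q=2).var_explained
        assert np.allclose(v1, v2)

    def test_degenerate_input_errors(self):
        X = np.ones((5, 4))
        with pytest.raises(ValueError, match="same vector"):
            pca_embed(X, q=2)
        with pytest.raises(ValueError, match="out of range"):
            pca_embed(np.random.default_rng(0).normal(size=(3, 4)), q=3)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 6))
        e1, e2 = pca_embed(X, q=3), pca_embed(X.copy(), q=3)
        assert np.array_equal(e1.coords, e2.coords)

    def test_shared_topology_reduces_to_length_pca(self):
        """With all trees in the base orthant, augmented log maps are just
        (internal lengths, external lengths): PCA must match the direct
        computation on those length vectors."""
        from treelens import perturb_gene_tree
        base = random_binary_tree(8, seed=6, name="b")
        trees = [perturb_gene_tree(base, 0.0, 0.4, seed=s, name=f"g{s}")
                 for s in range(10)]
        M, idx = logmap_matrix(trees, base)
        direct = np.array([
            [t.internal_edges[s] for s in idx.internal_order] +
            [t.external_edges[l] for l in idx.external_order]
            for t in trees])
        assert np.allclose(M, direct, atol=1e-12)
        assert np.allclose(pca_embed(M, q=2).coords,
                           pca_embed(direct, q=2).coords)


class TestMds:
    def test_collinear_exact_recovery(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        D = np.abs(pts - pts.T)
        emb = mds_embed(D, q=1)
        rec = np.abs(emb.coords[:, 0][:, None] - emb.coords[:, 0][None, :])
        assert np.allclose(rec, D, atol=1e-10)

    def test_zero_matrix(self):
        emb = mds_embed(np.zeros((4, 4)), q=2)
        assert np.allclose(emb.coords, 0.0)

    def test_euclidean_exactness_in_r3(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 3))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(pts))
        emb = mds_embed(D, q=3)
        assert np.allclose(squareform(pdist(emb.coords)), D, atol=1e-6)

    def test_non_symmetric_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mds_embed(D, q=1)

    def test_negative_eigenvalue_warning_on_non_euclidean_input(self):
        # 4-cycle path metric: provably not Euclidean-embeddable
        D = np.array([[0, 1, 2, 1],
                      [1, 0, 1, 2],
                      [2, 1, 0, 1],
                      [1, 2, 1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="negative eigenvalue"):
            emb = mds_embed(D, q=2)
        assert emb.neg_eigen_fraction > 0

    def test_nonmetric_reports_stress(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(pts))
        emb = mds_embed(D, q=2, flavor="nonmetric", seed=0)
        assert emb.stress is not None and emb.stress < 0.05


class TestRescale:
    def test_total_becomes_one(self):
        t = random_binary_tree(7, seed=1)
        r = rescale_tree(t)
        assert r.total_length() == pytest.approx(1.0, abs=1e-12)

    def test_fixed_point(self):
        r = rescale_tree(random_binary_tree(7, seed=2))
        r2 = rescale_tree(r)
        for s in r.internal_edges:
            assert r2.internal_edges[s] == pytest.approx(r.internal_edges[s])

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        t = random_binary_tree(6, seed=3)
        scaled = t.copy()
        scaled.internal_edges = {s: c * v for s, v in t.internal_edges.items()}
        scaled.external_edges = {k: c * v for k, v in t.external_edges.items()}
        r1, r2 = rescale_tree(t), rescale_tree(scaled)
        for s in r1.internal_edges:
            assert r2.internal_edges[s] == pytest.approx(r1.internal_edges[s])

    def test_zero_total_errors(self):
        t = parse_newick("(A:0,B:0,C:0,D:0);")
        with pytest.raises(ValueError, match="zero total"):
            rescale_tree(t)


class TestContrastStats:
    def test_identical(self):
        t = random_binary_tree(6, seed=4, name="t")
        stats = tree_contrast_stats(t, t.copy(name="u"))
        assert stats["bhv"] == 0 and stats["rf"] == 0
        assert stats["sum_sq_diff"] == 0

    def test_doubled_lengths(self):
        t = random_binary_tree(6, seed=5, name="t")
        norm = np.sqrt(t.sum_squared_lengths())
        t1 = rescale_tree(t)  # arbitrary normalization for clean numbers
        t1.internal_edges = {s: v / norm for s, v in t.internal_edges.items()}
        t1.external_edges = {k: v / norm for k, v in t.external_edges.items()}
        t2 = t1.copy(name="u")
        t2.internal_edges = {s: 2 * v for s, v in t1.internal_edges.items()}
        t2.external_edges = {k: 2 * v for k, v in t1.external_edges.items()}
        stats = tree_contrast_stats(t1, t2)
        assert stats["rf"] == 0
        assert stats["sum_sq_diff"] == pytest.approx(3.0)  # 4x - 1x of unit
        internal = np.array(list(t1.internal_edges.values()))
        assert stats["bhv"] == pytest.approx(np.linalg.norm(internal))

    def test_incompatible_single_edges(self):
        a = parse_newick("((A:1,C:1):0.3,B:1,D:1);", name="a")
        b = parse_newick("((A:1,B:1):0.4,C:1,D:1);", name="b")
        stats = tree_contrast_stats(a, b)
        assert stats["rf"] == 2
        assert stats["bhv"] == pytest.approx(0.7)


class TestFlagOutliers:
    def _emb(self, coords, names=None):
        coords = np.asarray(coords, dtype=float)
        return EmbeddingResult(coords=coords, method="pca", metric="",
                               q=coords.shape[1],
                               tree_names=names or
                               [f"t{i}" for i in range(len(coords))])

    def test_single_far_point_flagged(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(scale=0.01, size=(30, 2))
        coords[7] = [5.0, 0.0]
        flags = flag_outliers(self._emb(coords))
        assert flags[0][0] == "t7" and flags[0][2]
        assert sum(f for _, _, f in flags) == 1

    def test_zero_mad_component_skipped(self):
        coords = np.zeros((10, 2))
        coords[:, 1] = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero MAD"):
            flags = flag_outliers(self._emb(coords))
        assert all(np.isfinite(s) for _, s, _ in flags)

    def test_q1_rejected(self):
        with pytest.raises(ValueError):
            flag_outliers(self._emb(np.zeros((5, 1))))

    def test_gaussian_cloud_false_flag_rate(self):
        """Tight Gaussian clouds should flag < 5% at threshold 3.5."""
        rng = np.random.default_rng(42)
        flagged = total = 0
        for _ in range(100):
            coords = rng.normal(size=(50, 2))
            flags = flag_outliers(self._emb(coords))
            flagged += sum(f for _, _, f in flags)
            total += len(flags)
        assert flagged / total < 0.05

    def test_injected_external_outlier_attains_max_score(self):
        """One x10 pendant-branch outlier tops the outlier ranking in a
        quiet collection in >= 95/100 seeded runs."""
        from treelens import (SimulationConfig, OutlierSpec,
                              select_base_tree, simulate_collection)
        hits = 0
        for seed in range(100):
            cfg = SimulationConfig(n_tips=10, n_genes=20, nni_rate=0.0,
                                   length_sigma=0.3,
                                   outliers=[OutlierSpec("external", 10.0)],
                                   seed=seed)
            _, genes, truth = simulate_collection(cfg)
            sel = select_base_tree(genes)
            M, _ = logmap_matrix(genes, sel.base)
            ranking = flag_outlier_features(M, [t.name for t in genes])
            hits += ranking[0][0] == truth[0]["gene"]
        assert hits >= 95

    def test_feature_screen_ranks_scale_relative_anomaly(self):
        """A bump huge relative to its own coordinate's spread outranks
        larger absolute variation elsewhere under the feature screen."""
        rng = np.random.default_rng(1)
        M = np.hstack([rng.normal(0, 1.0, size=(40, 3)),  # loud features
                       rng.normal(0, 0.001, size=(40, 1))])  # quiet feature
        M[5, 3] += 0.05  # 50x the quiet feature's sd, tiny absolutely
        ranking = flag_outlier_features(M)
        assert ranking[0][0] == "tree_5"
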