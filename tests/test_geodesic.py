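"""GTP geodesics: spec examples, oracle equivalence, metric axioms."""

import math

import numpy as np
import pytest

from treelens import (bhv_distance, cone_path_length, distance_matrix,
                      geodesic_point, gtp_geodesic, parse_newick,
                      random_binary_tree, rf_distance)
from treelens.tree import LeafSetMismatchError

from _oracle import brute_force_bhv
from conftest import random_pair


class TestBhvDistance:
    def test_same_topology_is_l2_on_internal_lengths(self, four_leaf_pair):
        a, b = four_leaf_pair
        assert bhv_distance(a, b) == pytest.approx(0.2, abs=1e-12)

    def test_incompatible_edges_cone_path(self):
        c = parse_newick("((A:1,C:1):0.3,B:1,D:1);")
        d = parse_newick("((A:1,B:1):0.4,C:1,D:1);")
        assert bhv_distance(c, d) == pytest.approx(0.7, abs=1e-12)
        assert cone_path_length(c, d) == pytest.approx(0.7, abs=1e-12)

    def test_two_leg_support_beats_cone(self, sqrt2_pair):
        T, Tp = sqrt2_pair
        geo = gtp_geodesic(T, Tp)
        assert geo.length == pytest.approx(math.sqrt(2), abs=1e-12)
        assert cone_path_length(T, Tp) == pytest.approx(1.8110770276, abs=1e-9)
        assert len(geo.support) == 2

    def test_shared_edge_decomposition(self):
        E = parse_newick("((L1:1,L2:1):0.3,L3:1,(L4:1,L5:1):0.5);")
        Ep = parse_newick("((L2:1,L3:1):0.4,L1:1,(L4:1,L5:1):0.1);")
        assert bhv_distance(E, Ep) == pytest.approx(math.sqrt(0.65), abs=1e-12)

    def test_leafset_mismatch(self):
        a = parse_newick("((A:1,B:1):0.5,C:1,D:1);")
        b = parse_newick("((A:1,B:1):0.5,C:1,E:1);")
        with pytest.raises(LeafSetMismatchError):
            bhv_distance(a, b)


class TestGeodesicStructure:
    def test_identical_trees(self):
        t = random_binary_tree(8, seed=3)
        geo = gtp_geodesic(t, t)
        assert geo.length == 0.0
        assert geo.support == []
        assert len(geo.common_edges) == len(t.internal_edges)

    @pytest.mark.parametrize("seed", range(30))
    def test_invariants_on_random_pairs(self, seed):
        t1, t2 = random_pair(7, seed)
        geo = gtp_geodesic(t1, t2)
        # length formula consistency
        sq = sum((p.norm_A + p.norm_B) ** 2 for p in geo.support)
        sq += sum((l1 - l2) ** 2 for _, l1, l2 in geo.common_edges)
        assert geo.length ** 2 == pytest.approx(sq, rel=1e-10)
        # support partitions the disjoint edges; union + common = sources
        a_union = set().union(*[set(p.A) for p in geo.support]) if geo.support else set()
        b_union = set().union(*[set(p.B) for p in geo.support]) if geo.support else set()
        common_src = {s for s, l1, _ in geo.common_edges if s in t1.internal_edges}
        common_tgt = {s for s, _, l2 in geo.common_edges if s in t2.internal_edges}
        assert a_union | common_src == set(t1.internal_edges)
        assert b_union | common_tgt == set(t2.internal_edges)
        # (P2): non-decreasing ratios
        ratios = [p.ratio for p in geo.support]
        assert all(r1 <= r2 * (1 + 1e-9) for r1, r2 in zip(ratios, ratios[1:]))
        # (P1): B_i compatible with A_j for i < j; common compatible with all
        from treelens import splits_compatible
        for i, pi in enumerate(geo.support):
            for pj in geo.support[i + 1:]:
                for b in pi.B:
                    for a in pj.A:
                        assert splits_compatible(b, a)
        for s, _, _ in geo.common_edges:
            for p in geo.support:
                for x in list(p.A) + list(p.B):
                    assert splits_compatible(s, x)

    def test_zero_length_edge_on_orthant_boundary(self):
        # zero-length split: distance as if the edge were absent
        a = parse_newick("(((A:1,B:1):0.0,C:1):0.2,D:1,E:1);")
        b = parse_newick("(((A:1,C:1):0.3,B:1):0.2,D:1,E:1);")
        assert bhv_distance(a, b) == pytest.approx(0.3, abs=1e-12)
        # but it still counts for RF unless collapsed
        assert rf_distance(a, b) == 2
        assert rf_distance(a, b, collapse_zero=True) == 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(120))
    def test_gtp_matches_brute_force(self, seed):
        n = 5 + seed % 3
        t1, t2 = random_pair(n, seed)
        assert bhv_distance(t1, t2) == pytest.approx(
            brute_force_bhv(t1, t2), abs=1e-9)


class TestMetricAxioms:
    def test_symmetry_identity_triangle(self):
        trees = [random_binary_tree(6, seed=s, name=f"t{s}") for s in range(12)]
        D = distance_matrix(trees, metric="bhv")
        assert np.allclose(D, D.T, atol=1e-10)
        assert np.allclose(np.diag(D), 0.0)
        n = len(trees)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    @pytest.mark.parametrize("seed", range(40))
    def test_cone_path_upper_bound(self, seed):
        t1, t2 = random_pair(6, seed)
        assert bhv_distance(t1, t2) <= cone_path_length(t1, t2) + 1e-12


class TestGeodesicPoint:
    def test_endpoints(self, sqrt2_pair):
        T, Tp = sqrt2_pair
        geo = gtp_geodesic(T, Tp)
        assert geodesic_point(geo, 0.0) == T
        assert geodesic_point(geo, 1.0) == Tp

    def test_breakpoint_is_star_tree(self):
        c = parse_newick("((A:1,C:1):0.3,B:1,D:1);")
        d = parse_newick("((A:1,B:1):0.4,C:1,D:1);")
        pt = geodesic_point(gtp_geodesic(c, d), 0.3 / 0.7)
        assert pt.internal_edges == {}

    def test_same_topology_midpoint_is_mean(self, four_leaf_pair):
        a, b = four_leaf_pair
        mid = geodesic_point(gtp_geodesic(a, b), 0.5)
        (s, v), = mid.internal_edges.items()
        assert v == pytest.approx(0.4, abs=1e-12)
        for leaf in a.leaf_labels:
            expected = (a.external_edges[leaf] + b.external_edges[leaf]) / 2
            assert mid.external_edges[leaf] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(50))
    def test_additivity_contract(self, seed):
        rng = np.random.default_rng(seed)
        t1, t2 = random_pair(6, seed + 500)
        geo = gtp_geodesic(t1, t2)
        lam = float(rng.uniform())
        pt = geodesic_point(geo, lam)
        assert bhv_distance(t1, pt) == pytest.approx(lam * geo.length, abs=1e-8)
        assert bhv_distance(pt, t2) == pytest.approx((1 - lam) * geo.length,
                                                     abs=1e-8)

    def test_lambda_out_of_range(self, four_leaf_pair):
        a, b = four_leaf_pair
        with pytest.raises(ValueError):
            geodesic_point(gtp_geodesic(a, b), 1.5)


class TestRfDistance:
    def test_identical(self):
        t = random_binary_tree(10, seed=0)
        assert rf_distance(t, t) == 0

    def test_shared_one_of_two(self):
        a = parse_newick("(((A:1,B:1):0.1,C:1):0.2,D:1,E:1);")
        b = parse_newick("(((A:1,C:1):0.1,B:1):0.2,D:1,E:1);")
        assert rf_distance(a, b) == 2

    def test_even_on_binary_trees(self):
        # symmetric differences between equally-resolved trees have even size
        for seed in range(20):
            t1, t2 = random_pair(8, seed)
            assert rf_distance(t1, t2) % 2 == 0

    def test_dendropy_cross_check(self):
        dendropy = pytest.importorskip("dendropy")
        for seed in range(10):
            t1, t2 = random_pair(7, seed)
            from treelens import write_newick
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                                   taxon_namespace=tns)
            ref = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert rf_distance(t1, t2) == ref


class TestDistanceMatrix:
    def test_single_tree(self):
        t = random_binary_tree(6, seed=1)
        assert distance_matrix([t]).shape == (1, 1)

    def test_duplicate_rows(self):
        t1, t2 = random_pair(6, 3)
        D = distance_matrix([t1, t1, t2])
        assert np.allclose(D[0], D[1])

    def test_rf_metric(self):
        trees = [random_binary_tree(6, seed=s) for s in range(4)]
        D = distance_matrix(trees, metric="rf")
        assert np.all(D == D.astype(int))
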