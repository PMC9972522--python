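from itertools import combinations
from math import comb, inf, isinf

import numpy as np
import pandas as pd
import pytest

from contrastnet import (
    GeneSetCollection,
    WeightedNetwork,
    benjamini_hochberg,
    cohens_d,
    degree_distribution_test,
    enrich,
    expression_protein_agreement,
    fisher_overlap,
    jaccard_index,
    mann_whitney_u,
    upregulated_genes,
)

from conftest import random_weighted_network


def _enumerated_mwu_p(x, y):
    """Independent oracle: exact two-sided p by enumerating group labels.

    Uses pairwise win counting (not rank sums) so it shares no code path
    with the implementation under test.
    """
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(group):
        rest = [pooled[i] for i in range(len(pooled)) if i not in group]
        vals = [pooled[i] for i in group]
        return sum((a > b) + 0.5 * (a == b) for a in vals for b in rest)

    u_obs = u_of(range(n))
    mn = n * len(y)
    lo = min(u_obs, mn - u_obs)
    hits = total = 0
    for group in combinations(range(len(pooled)), n):
        u = u_of(group)
        if u <= lo + 1e-9 or u >= mn - lo - 1e-9:
            hits += 1
        total += 1
    return min(1.0, hits / total)


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        # (1,2,3) vs (10,11,12): U = 0, two-sided p = 2/C(6,3) = 0.1
        u, p = mann_whitney_u(np.array([1, 2, 3]), np.array([10, 11, 12]))
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        x = np.array([5.0, 5.0, 5.0, 5.0])
        _, p = mann_whitney_u(x, x)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n,m", [(3, 3), (4, 5), (6, 6), (5, 7)])
    def test_exact_matches_enumeration(self, n, m, rng):
        for _ in range(4):
            x = rng.integers(0, 6, size=n).astype(float)  # ties likely
            y = rng.integers(0, 6, size=m).astype(float)
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(_enumerated_mwu_p(x, y), abs=1e-12)

    def test_tie_free_exact_matches_enumeration(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(_enumerated_mwu_p(x, y), abs=1e-12)

    def test_power_grows_with_shift(self, rng):
        # shifting one group further up cannot make rejection harder
        base = rng.normal(size=25)
        other = rng.normal(size=25)
        p_small = mann_whitney_u(base, other + 0.5)[1]
        p_large = mann_whitney_u(base, other + 3.0)[1]
        assert p_large <= p_small

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u(np.array([]), np.array([1.0]))


class TestDegreeDistributionTest:
    def test_identical_networks(self, rng):
        net = random_weighted_network(8, rng)
        s = list(net.nodes)[:5]
        da, db, _, p = degree_distribution_test(s, net, net)
        assert (da == db).all()
        assert p == pytest.approx(1.0)

    def test_degrees_are_within_induced_subgraph(self, rng):
        net_a = random_weighted_network(8, rng)
        net_b = random_weighted_network(8, rng)
        s = sorted(net_a.nodes)[:4]
        da, _, _, _ = degree_distribution_test(s, net_a, net_b)
        for v in s:
            expected = sum(net_a.weight(v, u) for u in s if u != v)
            assert da[v] == pytest.approx(expected)

    def test_full_network_degrees_option(self, rng):
        net_a = random_weighted_network(8, rng)
        net_b = random_weighted_network(8, rng)
        s = sorted(net_a.nodes)[:4]
        da, _, _, _ = degree_distribution_test(s, net_a, net_b, induced=False)
        for v in s:
            expected = sum(net_a.weight(v, u) for u in net_a.nodes if u != v)
            assert da[v] == pytest.approx(expected)

    def test_too_small_set_rejected(self, rng):
        net = random_weighted_network(5, rng)
        with pytest.raises(ValueError, match="2 nodes"):
            degree_distribution_test([net.nodes[0]], net, net)


class TestJaccard:
    def test_identical_disjoint_and_half(self):
        assert jaccard_index({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard_index({"a"}, {"b"}) == 0.0
        assert jaccard_index({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_symmetry_and_identity(self, rng):
        for _ in range(10):
            s1 = set(rng.choice(20, rng.integers(1, 10), replace=False).tolist())
            s2 = set(rng.choice(20, rng.integers(1, 10), replace=False).tolist())
            assert jaccard_index(s1, s2) == jaccard_index(s2, s1)
            assert (jaccard_index(s1, s2) == 1.0) == (s1 == s2)

    def test_two_empty_sets_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            jaccard_index(set(), set())


class TestFisherOverlap:
    def test_sets_equal_to_universe(self):
        u = {f"g{i}" for i in range(10)}
        odds, p, expected = fisher_overlap(u, u, u)
        assert p == pytest.approx(1.0)
        assert expected == pytest.approx(10.0)

    def test_full_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(40)}
        s = {f"g{i}" for i in range(10)}
        _, p, _ = fisher_overlap(s, s, universe)
        # closed form: P(overlap >= 10) = C(10,10)·C(30,0)/C(40,10)
        assert p == pytest.approx(comb(10, 10) * comb(30, 0) / comb(40, 10))

    def test_expected_overlap_product_formula(self):
        universe = {f"g{i}" for i in range(2000)}
        s1 = {f"g{i}" for i in range(204)}
        s2 = {f"g{i}" for i in range(1700, 2000)}
        _, _, expected = fisher_overlap(s1, s2, universe)
        assert expected == pytest.approx(204 * 300 / 2000) == pytest.approx(30.6)

    def test_matches_hypergeometric_tail_exhaustively(self):
        # one-sided Fisher p == sum_{j>=k} C(K,j) C(N-K,n-j) / C(N,n)
        genes = [f"g{i}" for i in range(12)]
        universe = set(genes)
        for k1 in (2, 5, 9):
            for k2 in (3, 6):
                s1 = set(genes[:k1])
                for shift in range(0, 12 - k2 + 1, 3):
                    s2 = set(genes[shift:shift + k2])
                    k = len(s1 & s2)
                    _, p, _ = fisher_overlap(s1, s2, universe)
                    tail = sum(
                        comb(k1, j) * comb(12 - k1, k2 - j) / comb(12, k2)
                        for j in range(k, min(k1, k2) + 1)
                    )
                    assert p == pytest.approx(tail, rel=1e-9)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_overlap({"x"}, {"y"}, {"y"})


class TestBenjaminiHochberg:
    def _stepup(self, p):
        # independent oracle: literal step-up definition
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        prev = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            prev = min(prev, p[idx] * m / rank)
            adj[idx] = prev
        return adj

    @pytest.mark.parametrize("pvec", [
        [0.01, 0.02, 0.03, 0.5],
        [0.04, 0.04, 0.04],
        [1.0, 0.5, 0.001, 0.02, 0.02],
        [0.9],
    ])
    def test_matches_stepup_definition(self, pvec):
        np.testing.assert_allclose(benjamini_hochberg(pvec), self._stepup(pvec), atol=1e-12)

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.uniform(size=30)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestEnrich:
    def _collection(self):
        universe = [f"g{i:03d}" for i in range(100)]
        sets = {f"set{j}": universe[10 * j:10 * (j + 1)] for j in range(10)}
        return GeneSetCollection.from_dict(sets, universe)

    def test_planted_set_ranks_first(self):
        coll = self._collection()
        query = {f"g{i:03d}" for i in range(10)}  # exactly set0
        significant, full = enrich(query, coll)
        assert full[0].set_name == "set0"
        assert full[0].overlap == 10
        # closed form: P(X >= 10) with N=100, K=10, n=10
        assert full[0].p_value == pytest.approx(1.0 / comb(100, 10))
        assert significant and significant[0].set_name == "set0"
        assert full[0].gene_ratio == 1.0

    def test_disjoint_set_has_p_one(self):
        coll = self._collection()
        _, full = enrich({f"g{i:03d}" for i in range(10)}, coll)
        by_name = {r.set_name: r for r in full}
        assert by_name["set5"].overlap == 0
        assert by_name["set5"].p_value == 1.0

    def test_gene_set_order_does_not_matter(self):
        universe = [f"g{i:03d}" for i in range(100)]
        sets = {f"set{j}": universe[10 * j:10 * (j + 1)] for j in range(10)}
        coll1 = GeneSetCollection.from_dict(sets, universe)
        coll2 = GeneSetCollection.from_dict(dict(reversed(list(sets.items()))), universe)
        q = set(universe[:15])
        _, full1 = enrich(q, coll1)
        _, full2 = enrich(q, coll2)
        assert [(r.set_name, r.p_value, r.adjusted_p) for r in full1] == \
               [(r.set_name, r.p_value, r.adjusted_p) for r in full2]

    def test_adding_nonoverlapping_set_never_lowers_adjusted_p(self):
        universe = [f"g{i:03d}" for i in range(100)]
        sets = {f"set{j}": universe[10 * j:10 * (j + 1)] for j in range(5)}
        q = set(universe[:12])
        _, before = enrich(q, GeneSetCollection.from_dict(sets, universe))
        sets["cannot_overlap"] = universe[90:]
        _, after = enrich(q, GeneSetCollection.from_dict(sets, universe))
        before_adj = {r.set_name: r.adjusted_p for r in before}
        after_adj = {r.set_name: r.adjusted_p for r in after}
        for name, adj in before_adj.items():
            assert after_adj[name] >= adj - 1e-12

    def test_query_outside_universe_rejected(self):
        coll = self._collection()
        with pytest.raises(ValueError, match="universe"):
            enrich({"not_a_gene"}, coll)


class TestUpregulation:
    def test_boundary_is_strict(self):
        a = pd.Series({"g1": 3.0, "g2": 7.0})
        b = pd.Series({"g1": 1.0, "g2": 1.0})
        up = upregulated_genes(a, b)  # log2FC: g1 exactly 1, g2 exactly 2
        assert up == frozenset({"g2"})

    def test_swapped_arguments_mirror(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(50)]
        a = pd.Series(rng.uniform(0, 100, 50), index=genes)
        b = pd.Series(rng.uniform(0, 100, 50), index=genes)
        up_a = upregulated_genes(a, b)
        down_a = upregulated_genes(b, a)
        assert not up_a & down_a
        lfc = np.log2(a + 1) - np.log2(b + 1)
        assert up_a == frozenset(lfc.index[lfc > 1])
        assert down_a == frozenset(lfc.index[lfc < -1])

    def test_label_mismatch_reported(self):
        a = pd.Series({"g1": 1.0, "g2": 1.0})
        b = pd.Series({"g1": 1.0, "g3": 1.0})
        with pytest.raises(ValueError, match="g2"):
            upregulated_genes(a, b)


class TestAgreement:
    def test_identical_matrices_give_unit_correlation(self, rng):
        genes = [f"g{i}" for i in range(6)]
        x = pd.DataFrame(rng.uniform(1, 5, (6, 8)), index=genes)
        r, d = expression_protein_agreement(
            x, x, groups={"grp1": genes[:3], "grp2": genes[3:]}
        )
        np.testing.assert_allclose(r.values, 1.0, atol=1e-12)
        assert d[("grp1", "grp2")] == 0.0

    def test_hand_computed_pearson(self):
        mrna = pd.DataFrame([[1.0, 2.0, 4.0, 3.0]], index=["g"], columns=list("abcd"))
        prot = pd.DataFrame([[2.0, 1.0, 5.0, 4.0]], index=["g"], columns=list("abcd"))
        r, _ = expression_protein_agreement(mrna, prot)
        x, y = np.array([1, 2, 4, 3.0]), np.array([2, 1, 5, 4.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert r["g"] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_zero_spread_gives_infinite_d(self, caplog):
        with caplog.at_level("WARNING"):
            d = cohens_d(np.array([0.5, 0.5, 0.5]), np.array([0.1, 0.1, 0.1]))
        assert isinf(d) and d > 0
        assert any("infinite" in r.message for r in caplog.records)

    def test_cohens_d_pooled_sd(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.0])
        pooled = np.sqrt(((2) * 1.0 + (2) * 4.0) / 4)
        assert cohens_d(x, y) == pytest.approx((2.0 - 4.0) / pooled)

    def test_too_few_shared_samples_rejected(self, rng):
        x = pd.DataFrame(rng.uniform(1, 5, (3, 2)), index=list("abc"))
        with pytest.raises(ValueError, match="3 shared samples"):
            expression_protein_agreement(x, x)
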