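"""Hierarchical AMOVA: brute-force oracle, invariances and permutation machinery."""

import numpy as np
import pytest
from scipy import stats

from genecult.errors import ValidationError
from genecult.fstats import allele_count_fst, amova, fst_components, pairwise_fst, within_group_fst
from genecult.popdata import PopulationRecord, PopulationTable


def make_table(specs):
    """specs: list of (name, group, n, n_rr, n_ra, n_aa)."""
    return PopulationTable(
        [PopulationRecord(nm, g, n, a, b, c) for nm, g, n, a, b, c in specs]
    )


def brute_force_components(groups):
    """Nested ANOVA components computed from explicitly enumerated alleles.

    ``groups``: per group, a list of (n_alleles, alt_count) populations.
    Sums of squares are accumulated allele by allele from 0/1 vectors, and
    the unequal-size coefficients recomputed from first principles.
    """
    alleles = [
        [np.array([1] * a + [0] * (n - a), float) for n, a in grp] for grp in groups
    ]
    pooled = np.concatenate([x for grp in alleles for x in grp])
    grand = pooled.mean()
    ss_wp = sum(((x - x.mean()) ** 2).sum() for grp in alleles for x in grp)
    ss_ap = sum(
        sum(len(x) * (x.mean() - np.concatenate(grp).mean()) ** 2 for x in grp)
        for grp in alleles
    )
    ss_ag = sum(
        len(np.concatenate(grp)) * (np.concatenate(grp).mean() - grand) ** 2
        for grp in alleles
    )
    N = len(pooled)
    G = len(groups)
    P = sum(len(g) for g in groups)
    sizes = [[len(x) for x in grp] for grp in alleles]
    s_n2_over_ng = sum(sum(n**2 for n in grp) / sum(grp) for grp in sizes)
    s_ng2 = sum(sum(grp) ** 2 for grp in sizes)
    s_n2 = sum(n**2 for grp in sizes for n in grp)
    sc = ss_wp / (N - P)
    n1 = (N - s_n2_over_ng) / (P - G)
    sb = (ss_ap / (P - G) - sc) / n1
    n2 = (s_n2_over_ng - s_n2 / N) / (G - 1)
    n3 = (N - s_ng2 / N) / (G - 1)
    sa = (ss_ag / (G - 1) - sc - n2 * sb) / n3
    return sa, sb, sc


class TestAgainstBruteForce:
    @pytest.mark.parametrize(
        "specs",
        [
            [("A", "g1", 10, 2, 5, 3), ("B", "g1", 8, 5, 2, 1), ("C", "g2", 12, 6, 4, 2)],
            [
                ("A", "g1", 10, 9, 1, 0),
                ("B", "g1", 15, 4, 6, 5),
                ("C", "g2", 7, 2, 3, 2),
                ("D", "g2", 20, 10, 8, 2),
            ],
        ],
    )
    def test_components_match_explicit_allele_enumeration(self, specs):
        table = make_table(specs)
        res = amova(table, n_permutations=0)
        groups = {}
        for nm, g, n, a, b, c in specs:
            groups.setdefault(g, []).append((2 * n, b + 2 * c))
        sa, sb, sc = brute_force_components(list(groups.values()))
        assert res.sigma_among_groups == pytest.approx(sa, abs=1e-12)
        assert res.sigma_among_pops_within == pytest.approx(sb, abs=1e-12)
        assert res.sigma_within_pops == pytest.approx(sc, abs=1e-12)
        tot = sa + sb + sc
        assert res.fct == pytest.approx(sa / tot)
        assert res.fst == pytest.approx((sa + sb) / tot)


class TestLimitingCases:
    def test_fixed_opposite_alleles_give_complete_differentiation(self):
        t = make_table([("A", "g1", 10, 10, 0, 0), ("B", "g2", 10, 0, 0, 10)])
        res = amova(t, n_permutations=0)
        assert res.fct == pytest.approx(1.0)
        assert res.fst == pytest.approx(1.0)

    def test_identical_populations_have_no_structure(self):
        t = make_table([(nm, g, 20, 10, 8, 2) for nm, g in
                        [("A", "g1"), ("B", "g1"), ("C", "g2"), ("D", "g2")]])
        res = amova(t, n_permutations=0)
        assert res.sigma_among_groups <= 1e-12
        assert res.sigma_among_pops_within <= 1e-12
        assert res.percent_variance[0] == 0.0
        assert res.percent_variance[1] == 0.0

    def test_monomorphic_locus_flagged(self):
        t = make_table([("A", "g1", 5, 5, 0, 0), ("B", "g2", 5, 5, 0, 0)])
        res = amova(t)
        assert res.monomorphic
        assert np.isnan(res.fct)

    def test_single_group_fct_undefined_fst_matches_within(self, table1):
        grouping = {r.name: "only" for r in table1.subset("sa_hunter_gatherer")}
        res = amova(table1.subset("sa_hunter_gatherer"), grouping, n_permutations=0)
        fst, _ = within_group_fst(table1, "sa_hunter_gatherer", n_permutations=0)
        assert np.isnan(res.fct)
        assert res.fst == pytest.approx(fst)


class TestWithinGroup:
    def test_hand_computed_two_population_value(self):
        # p = 0.1 vs 0.9 with 2n = 20 each: independent arithmetic oracle
        n = np.array([20.0, 20.0])
        a = np.array([2.0, 18.0])
        ms_ap = float((n * (a / n - 0.5) ** 2).sum())  # df = 1
        ms_wp = float((n * (a / n) * (1 - a / n)).sum()) / 38
        nc = (40 - (400 + 400) / 40) / 1
        sb = (ms_ap - ms_wp) / nc
        expected = sb / (sb + ms_wp)
        t = make_table([("A", "g", 10, 8, 2, 0), ("B", "g", 10, 0, 2, 8)])
        fst, _ = within_group_fst(t, "g", n_permutations=0)
        assert fst == pytest.approx(expected)
        assert fst == pytest.approx(0.76893, abs=1e-4)

    def test_identical_populations_give_zero(self):
        t = make_table([("A", "g", 20, 10, 8, 2), ("B", "g", 20, 10, 8, 2)])
        fst, _ = within_group_fst(t, "g", n_permutations=0)
        assert fst <= 1e-12

    def test_needs_two_populations(self, table1):
        single = PopulationTable([table1.get("Cora")])
        with pytest.raises(ValidationError):
            within_group_fst(single, "mesoamerican_agriculturalist", n_permutations=0)


class TestInvariances:
    def test_allele_relabeling_leaves_indices_unchanged(self, table1):
        swapped = PopulationTable(
            [
                PopulationRecord(r.name, r.subdivision, r.n, r.n_aa, r.n_ra, r.n_rr)
                for r in table1
            ],
            locus_id="swapped",
        )
        a = amova(table1, n_permutations=0)
        b = amova(swapped, n_permutations=0)
        assert a.fct == pytest.approx(b.fct)
        assert a.fsc == pytest.approx(b.fsc)
        assert a.fst == pytest.approx(b.fst)

    def test_row_order_invariance(self, table1):
        shuffled = PopulationTable(list(reversed(table1.records)), locus_id="rev")
        a = amova(table1, n_permutations=0)
        b = amova(shuffled, n_permutations=0)
        assert a.fct == pytest.approx(b.fct)
        assert a.fst == pytest.approx(b.fst)

    def test_permutation_p_values_reproducible_by_seed(self, table1):
        sub = table1.subset("andean_agriculturalist")
        r1 = within_group_fst(sub, "andean_agriculturalist", n_permutations=300, seed=7)
        r2 = within_group_fst(sub, "andean_agriculturalist", n_permutations=300, seed=7)
        assert r1 == r2


class TestPermutationCalibration:
    def test_p_values_uniform_under_exchangeable_null(self):
        """Under a true null (all populations drawn from one binomial pool),
        permutation p-values are uniform on the achievable grid."""
        rng = np.random.default_rng(42)
        pvals = []
        for rep in range(200):
            specs = []
            for i in range(4):
                g = rng.multinomial(20, [0.49, 0.42, 0.09])
                specs.append((f"P{i}", "g", 20, int(g[0]), int(g[1]), int(g[2])))
            try:
                t = make_table(specs)
                _, p = within_group_fst(t, "g", n_permutations=99, seed=int(rng.integers(2**31)))
            except ValidationError:
                continue
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestPairwise:
    def test_identical_and_opposite(self):
        t = make_table([("A", "g", 10, 5, 4, 1), ("B", "g", 10, 5, 4, 1),
                        ("C", "g", 10, 10, 0, 0), ("D", "g", 10, 0, 0, 10)])
        m = pairwise_fst(t)
        assert m.loc["A", "B"] <= 1e-12
        assert m.loc["C", "D"] == pytest.approx(1.0)
        assert np.allclose(np.diag(m), 0.0)
        assert np.allclose(m, m.T)

    def test_two_population_estimator_matches_direct_evaluation(self):
        # p = (0.2, 0.4) with 2n = (100, 100): direct one-level ANOVA arithmetic
        n = np.array([100.0, 100.0])
        a = np.array([20.0, 40.0])
        s_a, s_w = fst_components(n, a)
        expected = s_a / (s_a + s_w)
        assert allele_count_fst(n, a) == pytest.approx(expected)
        # and against a from-scratch evaluation of the same design
        pbar = 0.3
        ms_ap = 100 * (0.2 - pbar) ** 2 + 100 * (0.4 - pbar) ** 2
        ms_wp = (100 * 0.16 + 100 * 0.24) / 198
        nc = (200 - 20000 / 200) / 1
        sb = (ms_ap - ms_wp) / nc
        assert expected == pytest.approx(sb / (sb + ms_wp))
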