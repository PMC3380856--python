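"""Coalescent simulators: textbook expectations, conditioning and summaries."""

import random

import numpy as np
import pytest
from scipy import stats

from genecult.coalescent import (
    Genealogy,
    IslandModelConfig,
    LocusSet,
    SettlementDemography,
    migration_for_target_fst,
    place_mutations,
    simulate_island_genealogy,
    simulate_island_snp,
    simulate_settlement_region,
    summarize_loci,
)
from genecult.errors import DomainError, ValidationError
from genecult.fstats import fst_components


class TestConfig:
    def test_groups_must_divide_demes(self):
        with pytest.raises(ValidationError):
            IslandModelConfig(n_demes=10, n_groups=3, m_within=0.01)

    def test_target_fst_solves_migration(self):
        cfg = IslandModelConfig(n_demes=100, n_groups=1, deme_size=50, target_fst=0.2)
        m = migration_for_target_fst(0.2, 50, 100)
        assert cfg.m_within == pytest.approx(m)

    def test_hierarchy_requires_ordered_rates(self):
        with pytest.raises(ValidationError):
            IslandModelConfig(n_demes=10, n_groups=2, m_within=0.001, m_between=0.01)

    def test_zero_migration_multi_deme_sample_rejected(self):
        cfg = IslandModelConfig(
            n_demes=4, n_groups=1, deme_size=10, m_within=0.0,
            sample_spec=((0, 2), (1, 2)),
        )
        with pytest.raises(DomainError):
            simulate_island_genealogy(cfg, 1)


class TestSingleDeme:
    def test_mean_pairwise_coalescence_time_is_2N(self):
        cfg = IslandModelConfig(
            n_demes=1, n_groups=1, deme_size=100, m_within=0.0, sample_spec=((0, 1),)
        )
        rng = random.Random(1)
        tmrca = [simulate_island_genealogy(cfg, rng).time[-1] for _ in range(1500)]
        assert np.mean(tmrca) == pytest.approx(200, rel=0.15)


class TestMutationPlacement:
    def test_positions_proportional_to_branch_lengths(self):
        # 3-leaf caricature: tips 0,1 join at t=1 (node 3), then 2 at t=4 (node 4)
        gen = Genealogy(
            parent=np.array([3, 3, 4, 4, -1]),
            time=np.array([0.0, 0.0, 0.0, 1.0, 4.0]),
            tip_deme=np.array([0, 0, 0]),
        )
        lengths = gen.branch_lengths()
        assert list(lengths) == [1.0, 1.0, 4.0, 3.0]
        rng = random.Random(5)
        hits = np.zeros(4)
        for tips in place_mutations(gen, 4000, rng):
            # identify the branch by its carrier set
            key = tuple(tips)
            idx = {(0,): 0, (1,): 1, (2,): 2, (0, 1): 3}[key]
            hits[idx] += 1
        chi = stats.chisquare(hits, 4000 * lengths / lengths.sum())
        assert chi.pvalue > 0.01

    def test_every_island_locus_polymorphic_in_pooled_sample(self):
        cfg = IslandModelConfig(
            n_demes=10, n_groups=1, deme_size=20, m_within=0.05,
            sample_spec=((0, 5), (1, 5)),
        )
        rng = random.Random(3)
        for _ in range(100):
            loc = simulate_island_snp(cfg, rng)
            tot = loc.derived.sum()
            assert 0 < tot < loc.n_alleles.sum()


class TestIslandEquilibrium:
    def test_same_seed_reproduces_locus(self):
        cfg = IslandModelConfig(
            n_demes=10, n_groups=1, deme_size=20, m_within=0.05,
            sample_spec=((0, 5), (1, 5)),
        )
        a = simulate_island_snp(cfg, 42)
        b = simulate_island_snp(cfg, 42)
        assert np.array_equal(a.derived, b.derived)

    def test_exchangeability_of_demes_within_group(self):
        """Swapping which deme gets the larger sample leaves the summary
        distribution unchanged (seed-matched comparison of means)."""
        def mean_fst(spec, seed):
            cfg = IslandModelConfig(
                n_demes=10, n_groups=1, deme_size=25, m_within=0.02, sample_spec=spec
            )
            rng = random.Random(seed)
            num = den = 0.0
            for _ in range(400):
                loc = simulate_island_snp(cfg, rng)
                s_a, s_w = fst_components(loc.n_alleles, loc.derived)
                num += s_a
                den += s_a + s_w
            return num / den

        a = mean_fst(((0, 10), (1, 5)), 9)
        b = mean_fst(((0, 5), (1, 10)), 9)
        assert a == pytest.approx(b, abs=0.05)


class TestSettlement:
    def test_each_region_has_exactly_n_snps(self):
        ls = simulate_settlement_region(SettlementDemography(), n_snps=20, seed=1)
        assert ls.derived.shape == (20, 3)
        tot = ls.derived.sum(axis=1)
        assert np.all((tot > 0) & (tot < ls.n_alleles.sum()))

    def test_panmixia_limit_gives_no_differentiation(self):
        demo = SettlementDemography(
            ancestral_size_range=(830, 830), split_time_range_years=(25, 25)
        )
        num = den = 0.0
        for i in range(400):
            ls = simulate_settlement_region(demo, sample_sizes=(15, 15, 15), seed=i)
            s = summarize_loci(ls)
            for k in range(ls.n_loci):
                s_a, s_w = fst_components(ls.n_alleles, ls.derived[k])
                num += s_a
                den += s_a + s_w
        assert num / den == pytest.approx(0.0, abs=0.01)

    def test_differentiation_grows_with_split_time(self):
        means = []
        for years in (1_000, 6_350, 18_000, 40_000):
            demo = SettlementDemography(
                split_time_range_years=(years, years),
                ancestral_size_range=(400, 400),
            )
            num = den = 0.0
            for i in range(200):
                ls = simulate_settlement_region(demo, sample_sizes=(15, 15, 15), seed=i)
                for k in range(ls.n_loci):
                    s_a, s_w = fst_components(ls.n_alleles, ls.derived[k])
                    num += s_a
                    den += s_a + s_w
            means.append(num / den)
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_oversized_sample_still_coalesces(self):
        demo = SettlementDemography(present_size=5)
        ls = simulate_settlement_region(demo, sample_sizes=(10, 10, 10), seed=2)
        assert ls.derived.shape[0] == 20


class TestSummaries:
    def test_hand_evaluated_single_locus(self):
        ls = LocusSet(
            deme_ids=np.array([0, 1]),
            n_alleles=np.array([20, 20]),
            derived=np.array([[10, 2]]),
        )
        s = summarize_loci(ls)
        s_a, s_w = fst_components(np.array([20.0, 20.0]), np.array([10.0, 2.0]))
        assert s.global_fst == pytest.approx(s_a / (s_a + s_w))
        he0 = 2 * 0.5 * 0.5 * 20 / 19
        he1 = 2 * 0.1 * 0.9 * 20 / 19
        assert s.mean_he == pytest.approx((he0 + he1) / 2)
        assert s.pairwise_fst[0] == pytest.approx(s.global_fst)

    def test_unbiased_he_at_half(self):
        ls = LocusSet(
            deme_ids=np.array([0, 1]),
            n_alleles=np.array([20, 20]),
            derived=np.array([[10, 10], [10, 10]]),
        )
        s = summarize_loci(ls)
        assert s.mean_he == pytest.approx((20 / 19) * 0.5)

    def test_identical_demes_give_nonpositive_fst(self):
        ls = LocusSet(
            deme_ids=np.array([0, 1, 2]),
            n_alleles=np.array([30, 30, 30]),
            derived=np.array([[6, 6, 6], [12, 12, 12]]),
        )
        s = summarize_loci(ls)
        assert s.global_fst <= 0

    def test_vector_layout_is_documented_order(self):
        ls = LocusSet(
            deme_ids=np.array([0, 1, 2]),
            n_alleles=np.array([10, 10, 10]),
            derived=np.array([[2, 5, 7]]),
        )
        s = summarize_loci(ls, deme_names=["a", "b", "c"])
        assert s.vector_labels() == [
            "mean_he", "global_fst", "fst_a_b", "fst_a_c", "fst_b_c",
        ]
        v = s.as_vector()
        assert v[0] == s.mean_he
        assert v[1] == s.global_fst
        assert np.allclose(v[2:], s.pairwise_fst)
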