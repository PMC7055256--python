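"""Meiosis, DH production, selection and the two breeding schemes."""

import numpy as np
import pytest

from heteropool import (
    GeneticMap,
    Population,
    SchemeConfig,
    dh_progeny,
    gca_scores,
    make_inbred_founders,
    meiosis_gamete,
    population_from_founders,
    random_matings,
    run_perse_scheme,
    run_rrs_cycle,
    run_scenario,
    sample_effects,
    select_loci,
    simulate_founder_haplotypes,
    tracked_loci,
    truncation_select,
    DominanceConfig,
    calibrate_trait,
)
from heteropool.breeding_cycle import sample_crossovers
from heteropool.trait_architecture import TraitArchitecture, tgv_inbred

from conftest import TINY_GENOME, make_toy_inputs, random_panel_engine


def uniform_map(n_loci: int, length: float = 1.0) -> GeneticMap:
    pos = np.linspace(0.0, length, n_loci, endpoint=False)
    return GeneticMap(positions=(pos,), lengths=np.array([length]),
                      snp_cols=np.arange(0), qtn_cols=np.arange(n_loci))


class TestMeiosis:
    def test_homozygous_parent_gives_parental_gamete(self):
        gmap = uniform_map(50)
        hap = np.random.default_rng(0).integers(0, 2, 50).astype(np.uint8)
        rng = np.random.default_rng(1)
        for _ in range(20):
            np.testing.assert_array_equal(meiosis_gamete(hap, hap, gmap, rng), hap)

    def test_crossover_count_is_poisson_of_map_length(self):
        # 1-Morgan chromosome: mean crossover count 1.0 within 3 SE
        rng = np.random.default_rng(2)
        n = 10_000
        counts = np.array([sample_crossovers(1.0, rng).size for _ in range(n)])
        assert abs(counts.mean() - 1.0) < 3 * np.sqrt(1.0 / n)

    def test_two_locus_recombination_matches_haldane(self):
        # loci 0.1 Morgan apart on an F1: recombinant fraction (1-e^-0.2)/2
        gmap = GeneticMap(positions=(np.array([0.3, 0.4]),), lengths=np.array([1.0]),
                          snp_cols=np.arange(0), qtn_cols=np.arange(2))
        h1 = np.array([0, 0], dtype=np.uint8)
        h2 = np.array([1, 1], dtype=np.uint8)
        rng = np.random.default_rng(3)
        n = 10_000
        rec = sum(g[0] != g[1] for g in
                  (meiosis_gamete(h1, h2, gmap, rng) for _ in range(n)))
        expected = (1.0 - np.exp(-0.2)) / 2.0
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec / n - expected) < 3 * se

    def test_gamete_alleles_come_from_parents(self):
        gmap = uniform_map(40)
        rng = np.random.default_rng(4)
        h1 = rng.integers(0, 2, 40).astype(np.uint8)
        h2 = rng.integers(0, 2, 40).astype(np.uint8)
        for _ in range(50):
            g = meiosis_gamete(h1, h2, gmap, rng)
            assert np.all((g == h1) | (g == h2))


class TestDhProgeny:
    def test_identical_parents_give_clone(self):
        gmap = uniform_map(30)
        hap = np.random.default_rng(5).integers(0, 2, 30).astype(np.uint8)
        rng = np.random.default_rng(6)
        np.testing.assert_array_equal(dh_progeny(hap, hap, gmap, rng), hap)

    def test_single_locus_segregates_one_to_one(self):
        gmap = uniform_map(1)
        rng = np.random.default_rng(7)
        n = 10_000
        draws = np.array([dh_progeny(np.array([0], np.uint8), np.array([1], np.uint8),
                                     gmap, rng)[0] for _ in range(n)])
        assert abs(draws.mean() - 0.5) < 3 * np.sqrt(0.25 / n)


class TestRandomMatings:
    def test_no_selfs_and_requested_count(self):
        rng = np.random.default_rng(8)
        pairs = random_matings(50, 500, rng)
        assert pairs.shape == (500, 2)
        assert np.all(pairs[:, 0] != pairs[:, 1])

    def test_two_parents_always_the_same_pair(self):
        pairs = random_matings(2, 20, np.random.default_rng(9))
        assert set(map(tuple, np.sort(pairs, axis=1))) == {(0, 1)}

    def test_parent_usage_uniform(self):
        # each parent expected in 2*m/n matings; multinomial bound
        n, m = 10, 2000
        pairs = random_matings(n, m, np.random.default_rng(10))
        usage = np.bincount(pairs.ravel(), minlength=n)
        expected = 2 * m / n
        se = np.sqrt(2 * m * (1 / n) * (1 - 1 / n))
        assert np.all(np.abs(usage - expected) < 4 * se)

    def test_fewer_than_two_parents_rejected(self):
        with pytest.raises(ValueError):
            random_matings(1, 5, np.random.default_rng(0))


class TestSelection:
    def test_top_fraction_selected(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=500)
        sel = truncation_select(scores, 0.10)
        assert sel.size == 50
        assert scores[sel].min() >= np.delete(scores, sel).max()

    def test_ties_resolved_by_lower_index(self):
        sel = truncation_select(np.zeros(500), 0.10)
        np.testing.assert_array_equal(sel, np.arange(50))

    def test_proportion_one_selects_everyone(self):
        np.testing.assert_array_equal(truncation_select(np.arange(7), 1.0), np.arange(7))


class TestGcaScores:
    def test_single_tester_equals_single_hybrid(self, toy_inputs):
        founders, loci, arch = toy_inputs
        hap = founders.haplotypes_at(loci, "qtn")
        scores, hybrids = gca_scores(hap[:5], hap[5:6], arch)
        np.testing.assert_allclose(scores, hybrids[:, 0])

    def test_progeny_identical_to_tester_gives_line_tgv(self, toy_inputs):
        founders, loci, arch = toy_inputs
        hap = founders.haplotypes_at(loci, "qtn")
        _, hybrids = gca_scores(hap[:1], hap[:1], arch)
        assert hybrids[0, 0] == pytest.approx(tgv_inbred(hap[:1], arch)[0])

    def test_additive_gca_is_half_line_value_plus_tester_mean(self):
        founders, loci, arch = make_toy_inputs(dom_mean=0.0, dom_var=0.0)
        hap = founders.haplotypes_at(loci, "qtn")
        progeny, testers = hap[:10], hap[10:]
        scores, _ = gca_scores(progeny, testers, arch)
        line = tgv_inbred(progeny, arch)
        tester_mean = tgv_inbred(testers, arch).mean()
        np.testing.assert_allclose(scores, (line + tester_mean) / 2.0)

    def test_empty_testers_rejected(self, toy_inputs):
        founders, loci, arch = toy_inputs
        hap = founders.haplotypes_at(loci, "qtn")
        with pytest.raises(ValueError):
            gca_scores(hap[:2], hap[:0], arch)


SMALL_SCHEME = SchemeConfig(n_matings_per_pool=100, n_matings_control=200,
                            selection_proportion=0.10, n_cycles=3)


class TestRrsCycle:
    def test_census_and_selection_bookkeeping(self, toy_inputs):
        founders, loci, arch = toy_inputs
        base = population_from_founders(founders, loci)
        pool_a, pool_b = base.subset(np.arange(10), pool="A"), base.subset(
            np.arange(10, 20), pool="B")
        a, b, rec = run_rrs_cycle(pool_a, pool_b, arch, SMALL_SCHEME,
                                  np.random.default_rng(1))
        assert a.n == b.n == 10  # 10% of 100 matings per pool
        assert rec.cycle == 1
        assert rec.selected_parent_ids["A"].size == 10

    def test_degenerate_single_genotype_pools_are_static(self, toy_inputs):
        founders, loci, arch = toy_inputs
        base = population_from_founders(founders, loci)
        clone = np.tile(base.haplotypes[0], (10, 1))
        pa = Population(haplotypes=clone.copy(), gmap=base.gmap, pool="A")
        pb = Population(haplotypes=clone.copy(), gmap=base.gmap, pool="B")
        a, b, rec = run_rrs_cycle(pa, pb, arch, SMALL_SCHEME, np.random.default_rng(2))
        line = tgv_inbred(base.haplotypes[0][base.gmap.qtn_cols][None, :], arch)[0]
        assert rec.inbred_mean == pytest.approx(line)
        assert rec.hybrid_mean == pytest.approx(line)
        assert rec.inbred_var == pytest.approx(0.0)
        np.testing.assert_array_equal(rec.selected_parent_ids["A"], np.arange(10))

    def test_progeny_homozygous_and_alleles_contained(self, toy_inputs):
        founders, loci, arch = toy_inputs
        base = population_from_founders(founders, loci)
        pool_a = base.subset(np.arange(10), pool="A")
        pool_b = base.subset(np.arange(10, 20), pool="B")
        rng = np.random.default_rng(3)
        for _ in range(3):
            new_a, new_b, _ = run_rrs_cycle(pool_a, pool_b, arch, SMALL_SCHEME, rng)
            for parents, progeny in ((pool_a, new_a), (pool_b, new_b)):
                assert np.isin(progeny.dosages(), (0, 2)).all()
                pf = parents.haplotypes.mean(axis=0)
                cf = progeny.haplotypes.mean(axis=0)
                # no allele appears that was absent from the parents
                assert np.all(cf[pf == 0] == 0) and np.all(cf[pf == 1] == 1)
            pool_a, pool_b = new_a, new_b


class TestPerseScheme:
    def test_census_and_hybrid_counts(self, toy_inputs):
        founders, loci, arch = toy_inputs
        base = population_from_founders(founders, loci)
        records = run_perse_scheme(base, arch, SMALL_SCHEME, np.random.default_rng(4))
        assert len(records) == SMALL_SCHEME.n_cycles
        assert records[0].selected_parent_ids["control"].size == 20

    def test_additive_hybrid_mean_equals_selected_line_mean(self):
        """Midparent identity: under pure additivity the half-diallel hybrid
        mean equals the mean TGV of the selected lines exactly."""
        from heteropool.breeding_cycle import _make_progeny

        founders, loci, arch = make_toy_inputs(dom_mean=0.0, dom_var=0.0)
        base = population_from_founders(founders, loci)
        scheme = SchemeConfig(100, 200, 0.10, 1)
        records = run_perse_scheme(base, arch, scheme, np.random.default_rng(5))
        # replay the cycle's RNG stream to recover the progeny
        rng = np.random.default_rng(5)
        matings = random_matings(base.n, scheme.n_matings_control, rng)
        progeny_hap = _make_progeny(base, matings, rng)
        line = tgv_inbred(progeny_hap[:, base.gmap.qtn_cols], arch)
        sel = truncation_select(line, scheme.selection_proportion)
        assert records[0].hybrid_mean == pytest.approx(line[sel].mean())


class TestScenario:
    def test_thirty_cycle_contract_at_reduced_scale(self, toy_inputs):
        founders, loci, arch = toy_inputs
        records = run_scenario(founders, loci, arch, "random", SMALL_SCHEME, 7)
        assert [r.cycle for r in records] == [1, 2, 3]
        assert all(r.inbred_var >= 0 and r.hybrid_var >= 0 for r in records)
        assert all({"A", "B"} <= set(r.pool_pc1) for r in records)

    def test_identical_seed_gives_bit_identical_trajectories(self, toy_inputs):
        founders, loci, arch = toy_inputs
        r1 = run_scenario(founders, loci, arch, "control", SMALL_SCHEME, 13)
        r2 = run_scenario(founders, loci, arch, "control", SMALL_SCHEME, 13)
        assert [(r.inbred_mean, r.hybrid_mean) for r in r1] == \
               [(r.inbred_mean, r.hybrid_mean) for r in r2]

    def test_unknown_strategy_rejected(self, toy_inputs):
        founders, loci, arch = toy_inputs
        with pytest.raises(ValueError, match="strategy"):
            run_scenario(founders, loci, arch, "tandem", SMALL_SCHEME, 1)

    def test_perse_selection_gains_over_cycles(self):
        """Mean selected TGV rises: final-cycle inbred mean beats cycle 1 in
        every one of 20 replicate seeds (monotone-trend property)."""
        founders, loci, arch = make_toy_inputs(n_founders=20, n_qtn=16, n_snp=20)
        wins = 0
        for seed in range(20):
            rec = run_scenario(founders, loci, arch, "control", SMALL_SCHEME, seed,
                               track_diversity=False)
            wins += rec[-1].inbred_mean > rec[0].inbred_mean
        assert wins >= 19

    def test_variance_erodes_under_selection(self):
        founders, loci, arch = make_toy_inputs(n_founders=20, n_qtn=16, n_snp=20)
        scheme = SchemeConfig(100, 200, 0.10, 6)
        losses = 0
        for seed in range(10):
            rec = run_scenario(founders, loci, arch, "random", scheme, seed,
                               track_diversity=False)
            losses += rec[-1].inbred_var < rec[0].inbred_var
        assert losses >= 9

    def test_pools_diverge_in_allele_frequency(self):
        """Mean |freq_A - freq_B| over tracked loci grows from cycle 1 to the
        final cycle under RRS-TGV (heterotic pools drift apart)."""
        founders, loci, arch = make_toy_inputs(n_founders=20, n_qtn=16, n_snp=20)
        base = population_from_founders(founders, loci)
        scheme = SchemeConfig(100, 200, 0.10, 8)
        diverged = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pa = base.subset(np.arange(10), pool="A")
            pb = base.subset(np.arange(10, 20), pool="B")
            first = last = None
            for cycle in range(scheme.n_cycles):
                pa, pb, _ = run_rrs_cycle(pa, pb, arch, scheme, rng)
                gap = np.abs(pa.haplotypes.mean(0) - pb.haplotypes.mean(0)).mean()
                if cycle == 0:
                    first = gap
                last = gap
            diverged += last > first
        assert diverged >= 9

    def test_additive_null_rrs_matches_perse_gain(self):
        """With all dominance degrees zero, RRS-TGV and per se selection give
        statistically indistinguishable inbred means (paired across seeds)."""
        founders, loci, arch = make_toy_inputs(n_founders=20, n_qtn=16, n_snp=20,
                                               dom_mean=0.0, dom_var=0.0)
        rrs, perse = [], []
        for seed in range(20):
            rrs.append(run_scenario(founders, loci, arch, "random", SMALL_SCHEME,
                                    seed, track_diversity=False)[-1].inbred_mean)
            perse.append(run_scenario(founders, loci, arch, "control", SMALL_SCHEME,
                                      seed, track_diversity=False)[-1].inbred_mean)
        rrs, perse = np.asarray(rrs), np.asarray(perse)
        se = np.sqrt(rrs.var(ddof=1) / rrs.size + perse.var(ddof=1) / perse.size)
        assert abs(rrs.mean() - perse.mean()) < 3 * se
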