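import numpy as np
import pytest

from caprapop.genotype_io import MISSING
from caprapop.qc import call_rates, mendelian_error_matrix
from caprapop.simdata import (
    SimConfig,
    add_trios,
    simulate_dataset,
    simulate_frequencies,
    simulate_genotypes,
    true_pairwise_fst,
    wright_fisher_forward,
)


class TestFrequencies:
    def test_zero_f_collapses_to_parent(self):
        cfg = SimConfig(seed=1, f_ct=0.0, f_st_within=0.0, n_chromosomes=1,
                        snps_per_chromosome=100)
        fr = simulate_frequencies(cfg)
        for g in range(cfg.n_groups):
            assert np.array_equal(fr["group"][g], fr["ancestral"])
            for p in range(cfg.pops_per_group):
                assert np.array_equal(fr["population"][g, p], fr["ancestral"])

    def test_law_of_total_expectation(self):
        cfg = SimConfig(seed=2, n_chromosomes=1, snps_per_chromosome=10_000,
                        f_ct=0.1)
        fr = simulate_frequencies(cfg)
        assert fr["group"].mean() == pytest.approx(
            fr["ancestral"].mean(), abs=0.01
        )

    def test_beta_variance_identity(self):
        # constant ancestral frequency isolates the Balding-Nichols variance
        cfg = SimConfig(
            seed=3, n_groups=1, pops_per_group=1,
            n_chromosomes=1, snps_per_chromosome=20_000,
            f_ct=0.0, f_st_within=0.15,
            ancestral_maf_low=0.3, ancestral_maf_high=0.3,
        )
        fr = simulate_frequencies(cfg)
        dev = fr["population"][0, 0] - fr["ancestral"]
        var = float((dev**2).mean())
        want = 0.15 * 0.3 * 0.7
        assert var == pytest.approx(want, rel=0.10)

    def test_monomorphic_fraction_planted(self):
        cfg = SimConfig(seed=4, n_chromosomes=1, snps_per_chromosome=200,
                        monomorphic_fraction=0.1)
        ds = simulate_dataset(cfg)
        nonmiss = ds.calls != MISSING
        b = np.where(nonmiss, ds.calls, 0).sum(axis=0)
        assert (b == 0).sum() >= 20


class TestGenotypes:
    def test_hwe_heterozygosity(self):
        cfg = SimConfig(
            seed=5, n_groups=1, pops_per_group=1, inds_per_pop=200,
            n_chromosomes=1, snps_per_chromosome=2000, f_is=0.0,
            f_ct=0.0, f_st_within=0.0,
        )
        fr = simulate_frequencies(cfg)
        ds = simulate_genotypes(fr, cfg)
        p = fr["population"][0, 0]
        het = (ds.calls == 1).mean(axis=0)
        expected = 2 * p * (1 - p)
        assert np.mean(het - expected) == pytest.approx(0.0, abs=0.005)

    def test_inbreeding_reduces_heterozygosity(self):
        base = dict(
            n_groups=1, pops_per_group=1, inds_per_pop=200,
            n_chromosomes=1, snps_per_chromosome=2000,
            f_ct=0.0, f_st_within=0.0,
        )
        h0 = (simulate_dataset(SimConfig(seed=6, f_is=0.0, **base)).calls == 1).mean()
        h1 = (simulate_dataset(SimConfig(seed=6, f_is=0.3, **base)).calls == 1).mean()
        assert h1 == pytest.approx(0.7 * h0, rel=0.05)

    def test_no_missing_gives_full_call_rates(self):
        ds = simulate_dataset(SimConfig(seed=7, n_chromosomes=1,
                                        snps_per_chromosome=50))
        s, v = call_rates(ds)
        assert (s == 1.0).all() and (v == 1.0).all()

    def test_missing_rate_applied(self):
        ds = simulate_dataset(
            SimConfig(seed=8, n_chromosomes=1, snps_per_chromosome=500,
                      missing_rate=0.05)
        )
        assert (ds.calls == MISSING).mean() == pytest.approx(0.05, abs=0.01)

    def test_seed_determinism(self):
        cfg = SimConfig(seed=9, n_chromosomes=1, snps_per_chromosome=100,
                        n_trios=2)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.equals(b)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_haplotypes_consistent_with_calls(self):
        ds = simulate_dataset(SimConfig(seed=10, n_chromosomes=1,
                                        snps_per_chromosome=100,
                                        haplotype_pool_size=20))
        ds.validate()


class TestTrios:
    def _with_trios(self, n_trios=3, loci=5000):
        cfg = SimConfig(
            seed=12, n_groups=1, pops_per_group=2, inds_per_pop=15,
            n_chromosomes=1, snps_per_chromosome=loci,
        )
        ds = simulate_dataset(cfg)
        return add_trios(ds, n_trios, seed=99)

    def test_children_are_mendelian_consistent(self):
        ds, trios = self._with_trios()
        ids = ds.sample_ids
        me = mendelian_error_matrix(ds)
        for pa, pb, child in trios:
            assert me[ids.index(pa), ids.index(child)] == 0
            assert me[ids.index(pb), ids.index(child)] == 0

    def test_opposite_homozygote_parents_force_heterozygote(self):
        ds, trios = self._with_trios()
        ids = ds.sample_ids
        pa, pb, child = trios[0]
        ga = ds.calls[ids.index(pa)]
        gb = ds.calls[ids.index(pb)]
        gc = ds.calls[ids.index(child)]
        forced = (ga == 0) & (gb == 2) | (ga == 2) & (gb == 0)
        assert forced.any()
        assert (gc[forced] == 1).all()

    def test_unrelated_pairs_exceed_threshold(self):
        ds, trios = self._with_trios()
        me = mendelian_error_matrix(ds)
        ids = ds.sample_ids
        related = {
            frozenset((t[0], t[2])) for t in trios
        } | {frozenset((t[1], t[2])) for t in trios}
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 1000:
            i, j = rng.integers(ds.n_samples, size=2)
            if i == j or frozenset((ids[i], ids[j])) in related:
                continue
            assert me[i, j] >= 100
            checked += 1

    def test_too_small_population_rejected(self):
        cfg = SimConfig(seed=13, n_groups=1, pops_per_group=1, inds_per_pop=1,
                        n_chromosomes=1, snps_per_chromosome=20)
        ds = simulate_dataset(cfg)
        with pytest.raises(ValueError, match="too small"):
            add_trios(ds, 1, seed=0)


class TestWrightFisher:
    def test_heterozygosity_decay_law(self):
        ne, gens, reps = 50, 60, 20
        ratios = []
        for seed in range(reps):
            ds0 = wright_fisher_forward(ne, 0, seed=seed, n_chromosomes=1,
                                        snps_per_chromosome=300)
            ds1 = wright_fisher_forward(ne, gens, seed=seed, n_chromosomes=1,
                                        snps_per_chromosome=300)

            def h_exp(ds):
                p = ds.haplotypes.reshape(-1, ds.n_variants).mean(axis=0)
                return (2 * p * (1 - p)).mean()

            ratios.append(h_exp(ds1) / h_exp(ds0))
        want = (1 - 1 / (2 * ne)) ** gens
        se = np.std(ratios, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(ratios) - want) < 3 * se + 1e-9

    def test_huge_ne_drift_free(self):
        ds0 = wright_fisher_forward(500, 0, seed=1, n_chromosomes=1,
                                    snps_per_chromosome=200)
        ds1 = wright_fisher_forward(500, 3, seed=1, n_chromosomes=1,
                                    snps_per_chromosome=200)
        p0 = ds0.haplotypes.reshape(-1, 200).mean(axis=0)
        p1 = ds1.haplotypes.reshape(-1, 200).mean(axis=0)
        assert np.abs(p0 - p1).mean() < 0.05

    def test_seed_determinism(self):
        a = wright_fisher_forward(20, 10, seed=5, n_chromosomes=1,
                                  snps_per_chromosome=50)
        b = wright_fisher_forward(20, 10, seed=5, n_chromosomes=1,
                                  snps_per_chromosome=50)
        assert a.equals(b)

    def test_tiny_ne_rejected(self):
        with pytest.raises(ValueError):
            wright_fisher_forward(1, 10, seed=0)


class TestTruth:
    def test_true_mean_pairwise_fst(self):
        cfg = SimConfig(seed=1, n_groups=2, pops_per_group=2,
                        f_ct=0.1, f_st_within=0.2)
        # 2 within-group pairs at 0.2; 4 cross-group pairs at 0.1+0.2*0.9
        want = (2 * 0.2 + 4 * (0.1 + 0.2 * 0.9)) / 6
        assert true_pairwise_fst(cfg) == pytest.approx(want)
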