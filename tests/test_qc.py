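import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caprapop.genotype_io import MISSING
from caprapop.qc import (
    QCThresholds,
    apply_qc,
    call_rates,
    filter_call_rate,
    mendelian_error_count,
    mendelian_error_matrix,
    minor_allele_frequencies,
    pairwise_ibs,
    relatedness_prune,
    remove_ibs_duplicates,
    remove_monomorphic,
    apply_population_rules,
    representative_subsample,
)
from caprapop.simdata import SimConfig, add_trios, simulate_dataset

from conftest import make_dataset


class TestCallRates:
    def test_no_missing_gives_ones(self, tiny_ds):
        s, v = call_rates(tiny_ds)
        assert (s == 1.0).all() and (v == 1.0).all()

    def test_direct_count(self):
        ds = make_dataset([[0, 1, MISSING, 2], [0, 0, 0, 0]])
        s, _ = call_rates(ds)
        assert s[0] == pytest.approx(0.75)

    def test_total_nonmissing_conserved(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([0, 1, 2, MISSING], size=(7, 13)).astype(np.int8)
        ds = make_dataset(calls)
        s, v = call_rates(ds)
        assert s.mean() * ds.n_samples * ds.n_variants == pytest.approx(
            v.mean() * ds.n_variants * ds.n_samples
        )
        assert s.sum() * ds.n_variants == pytest.approx(v.sum() * ds.n_samples)


class TestMaf:
    def test_direct_count(self):
        ds = make_dataset([[0], [0], [1]])
        maf = minor_allele_frequencies(ds)["maf"].iloc[0]
        assert maf == pytest.approx(1 / 6)

    def test_monomorphic_zero_and_all_missing_nan(self):
        ds = make_dataset([[0, MISSING], [0, MISSING]])
        tab = minor_allele_frequencies(ds)
        assert tab["maf"].iloc[0] == 0.0
        assert np.isnan(tab["maf"].iloc[1])

    def test_relabel_invariance(self):
        ds = make_dataset([[0, 2], [1, 1], [2, 2]])
        flipped = make_dataset(2 - np.asarray([[0, 2], [1, 1], [2, 2]]))
        a = minor_allele_frequencies(ds)["maf"]
        b = minor_allele_frequencies(flipped)["maf"]
        assert np.allclose(a, b)

    def test_by_population_stratifies(self):
        ds = make_dataset([[0], [2]], populations=["A", "B"])
        tab = minor_allele_frequencies(ds, by_population=True)
        assert set(tab["population"]) == {"A", "B"}
        assert (tab["maf"] == 0.0).all()


class TestCallRateFilter:
    def _with_rates(self):
        # 25 loci: sample S1 misses 2 (rate .92), S2 misses 1 (rate .96 exactly)
        calls = np.ones((4, 25), dtype=np.int8)
        calls[0, :2] = MISSING
        calls[1, 0] = MISSING
        calls[2, :] = [0, 1] * 12 + [0]
        return make_dataset(calls)

    def test_boundary_kept_below_removed(self):
        ds = self._with_rates()
        out, report = filter_call_rate(ds, QCThresholds())
        removed = dict(report.removed_samples)
        assert "S1" in removed and removed["S1"] == "low_call_rate"
        assert "S2" not in removed  # rate exactly 0.96 kept (>= convention)

    def test_strict_mode_removes_boundary(self):
        ds = self._with_rates()
        out, _ = filter_call_rate(ds, QCThresholds(strict_call_rate=True))
        assert "S2" not in out.sample_ids

    def test_variant_rate_recomputed_after_samples(self):
        # 50 samples; variant v1 missing in 2 retained samples -> rate .96 < .98
        calls = np.ones((50, 30), dtype=np.int8)
        calls[0, 1] = MISSING
        calls[1, 0] = MISSING
        calls[2, 0] = MISSING
        ds = make_dataset(calls)
        out, report = filter_call_rate(ds, QCThresholds())
        removed_v = dict(report.removed_variants)
        assert "v1" in removed_v
        assert "v2" not in removed_v  # 49/50 = 0.98 exactly, kept

    def test_all_removed_is_an_error(self):
        calls = np.full((3, 4), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="threshold"):
            filter_call_rate(make_dataset(calls), QCThresholds())


class TestMonomorphic:
    def test_examples(self):
        ds = make_dataset(
            [[0, 0, 0], [0, 1, 0], [0, 0, 2]],
            populations=["A", "A", "B"],
        )
        out, report = remove_monomorphic(ds)
        assert dict(report.removed_variants) == {"v1": "monomorphic"}
        # v3 is monomorphic within A but polymorphic overall: kept
        assert out.variant_ids == ["v2", "v3"]


class TestIbs:
    def test_hand_computed_pair(self):
        ds = make_dataset([[0, 1, 2], [2, 1, 0]])
        ibs = pairwise_ibs(ds)
        assert ibs[0, 1] == pytest.approx(1 / 3)
        assert ibs[0, 1] == ibs[1, 0]

    def test_duplicate_detected_and_lower_rate_member_removed(self):
        calls = np.ones((3, 20), dtype=np.int8)
        calls[1, 0] = MISSING  # duplicate with lower call rate
        calls[2, :] = [0, 2] * 10
        ds = make_dataset(calls)
        assert pairwise_ibs(ds)[0, 1] == pytest.approx(1.0)
        out, report = remove_ibs_duplicates(ds, QCThresholds())
        assert dict(report.removed_samples) == {"S2": "ibs_duplicate"}

    def test_tie_removes_later_sample(self):
        calls = np.ones((2, 10), dtype=np.int8)
        out, report = remove_ibs_duplicates(make_dataset(calls), QCThresholds())
        assert dict(report.removed_samples) == {"S2": "ibs_duplicate"}

    def test_no_joint_loci_flagged_nan(self):
        ds = make_dataset([[1, MISSING], [MISSING, 1]])
        assert np.isnan(pairwise_ibs(ds)[0, 1])


class TestMendelianErrors:
    def test_examples(self):
        assert mendelian_error_count([0, 2, 1], [0, 2, 1]) == 0
        assert mendelian_error_count([0, 2, 1, 2], [2, 2, 1, 0]) == 2

    @given(st.integers(0, 10_000))
    def test_locus_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.choice([0, 1, 2, MISSING], size=30)
        b = rng.choice([0, 1, 2, MISSING], size=30)
        perm = rng.permutation(30)
        assert mendelian_error_count(a, b) == mendelian_error_count(a[perm], b[perm])

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1, 2, MISSING], size=(5, 40)).astype(np.int8)
        ds = make_dataset(calls)
        me = mendelian_error_matrix(ds)
        for i in range(5):
            for j in range(5):
                assert me[i, j] == mendelian_error_count(calls[i], calls[j])


class TestRelatednessPrune:
    def _star(self):
        # one parent, three offspring sharing a parental allele everywhere;
        # offspring built from independent second gametes so they are
        # mutually unrelated at these allele frequencies
        rng = np.random.default_rng(7)
        L = 2000
        parent = rng.choice([0, 1, 2], size=L, p=[0.25, 0.5, 0.25]).astype(np.int8)

        def child():
            from_parent = np.where(
                parent == 1, rng.integers(0, 2, L), parent // 2
            )
            other = rng.random(L) < 0.5
            return (from_parent + other).astype(np.int8)

        others = rng.choice([0, 1, 2], size=(4, L), p=[0.25, 0.5, 0.25])
        calls = np.vstack([parent, child(), child(), child(), others]).astype(np.int8)
        return make_dataset(calls)

    def test_boundary_count(self):
        thr = QCThresholds(me_related_max=100)
        a = np.zeros(99, dtype=np.int8)
        b = np.full(99, 2, dtype=np.int8)
        assert mendelian_error_count(a, b) == 99  # < 100 -> related
        pair = make_dataset(np.vstack([a, b]))
        _, report = relatedness_prune(pair, thr)
        assert len(report.removed_samples) == 1
        c = np.zeros(100, dtype=np.int8)
        d = np.full(100, 2, dtype=np.int8)
        _, report = relatedness_prune(make_dataset(np.vstack([c, d])), thr)
        assert report.removed_samples == []

    def test_star_pedigree_removes_exactly_the_parent(self):
        ds = self._star()
        me = mendelian_error_matrix(ds)
        # sanity on the construction: parent-offspring pairs are the only
        # related ones
        related = {(i, j) for i in range(8) for j in range(i + 1, 8)
                   if me[i, j] < 100}
        assert related == {(0, 1), (0, 2), (0, 3)}
        out, report = relatedness_prune(ds, QCThresholds())
        assert dict(report.removed_samples) == {"S1": "related"}
        assert out.n_samples == 7

    def test_no_related_pairs_is_identity(self):
        # unrelated pairs need thousands of polymorphic loci to clear the
        # opposing-homozygote threshold reliably
        cfg = SimConfig(
            seed=23, n_groups=1, pops_per_group=1, inds_per_pop=12,
            n_chromosomes=1, snps_per_chromosome=5000,
        )
        ds = simulate_dataset(cfg)
        out, report = relatedness_prune(ds, QCThresholds())
        assert out.n_samples == 12 and report.removed_samples == []


class TestPopulationRules:
    def test_size_rules_and_exclusions(self):
        pops = ["A"] * 3 + ["B"] * 2 + ["C"] * 4
        ds = make_dataset(np.ones((9, 5), dtype=np.int8), populations=pops)
        out, report = apply_population_rules(ds, ["C"], QCThresholds())
        reasons = {r for _, r in report.removed_samples}
        assert reasons == {"excluded_population", "small_population"}
        assert sorted(out.population_indices()) == ["A"]  # B below 3, C excluded

    def test_boundary_population_of_three_kept(self):
        ds = make_dataset(np.ones((3, 5), dtype=np.int8), populations=["A"] * 3)
        out, _ = apply_population_rules(ds, [], QCThresholds())
        assert out.n_samples == 3

    def test_absent_exclusion_warns_not_errors(self):
        ds = make_dataset(np.ones((3, 5), dtype=np.int8), populations=["A"] * 3)
        _, report = apply_population_rules(ds, ["NOPE"], QCThresholds())
        assert any("NOPE" in n for n in report.notes)


class TestRepresentativeSubsample:
    def test_identity_when_not_larger(self, structured_ds):
        pop = next(iter(structured_ds.population_indices()))
        ids = representative_subsample(structured_ds, pop, 20, seed=1)
        assert len(ids) == 20

    def test_deterministic_given_seed(self, structured_ds):
        pop = next(iter(structured_ds.population_indices()))
        a = representative_subsample(structured_ds, pop, 10, seed=42)
        b = representative_subsample(structured_ds, pop, 10, seed=42)
        assert a == b

    def test_beats_median_random_draw(self, structured_ds):
        ds = structured_ds
        pop, idx = next(iter(ds.population_indices().items()))
        chosen = representative_subsample(ds, pop, 8, seed=9)
        full = ds.calls[idx].mean(axis=0)

        def dist(rows):
            return np.linalg.norm(ds.calls[rows].mean(axis=0) / 2 - full / 2)

        rows_chosen = [i for i in idx if ds.samples[i].sample_id in set(chosen)]
        rng = np.random.default_rng(100)
        rand = [
            dist(rng.choice(idx, size=8, replace=False)) for _ in range(200)
        ]
        assert dist(rows_chosen) <= np.median(rand)


class TestFullCascade:
    def test_clean_dataset_is_identity(self):
        cfg = SimConfig(
            seed=21, n_groups=1, pops_per_group=3, inds_per_pop=10,
            n_chromosomes=1, snps_per_chromosome=5000,
        )
        ds = simulate_dataset(cfg)
        # strip the loci that drifted to fixation so the input is fully clean
        ds, _ = remove_monomorphic(ds)
        out, report = apply_qc(ds, QCThresholds())
        assert out.n_samples == ds.n_samples
        assert report.removed_samples == []
        assert report.removed_variants == []

    def test_counts_reconcile_at_every_stage(self):
        cfg = SimConfig(
            seed=22, n_groups=1, pops_per_group=3, inds_per_pop=10,
            n_chromosomes=1, snps_per_chromosome=500, missing_rate=0.01,
            monomorphic_fraction=0.05,
        )
        ds = simulate_dataset(cfg)
        out, report = apply_qc(ds, QCThresholds())
        assert report.stages[0] == ("input", ds.n_samples, ds.n_variants)
        assert report.stages[-1][1] == out.n_samples
        assert ds.n_samples - len(report.removed_samples) == out.n_samples
        assert ds.n_variants - len(report.removed_variants) == out.n_variants
        for (s0, n0, v0), (s1, n1, v1) in zip(report.stages, report.stages[1:]):
            assert n1 <= n0 and v1 <= v0
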