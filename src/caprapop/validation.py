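"""Simulation-study protocols that exercise the pipeline end to end.

These are the package's own validation experiments: type-I error and power
of the permutation tests, recovery of the hierarchy parameters (F_CT,
pairwise F_ST, F_IS) from the Balding-Nichols generator, recovery of a
known effective population size from Wright-Fisher forward simulations,
the planted-offender QC experiment, and the LD-sharing-versus-divergence
experiment.  Both the test suite and the acceptance script drive them.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from .amova import HierarchyAssignment, amova
from .differentiation import fst_matrix
from .diversity import fis, fis_significance
from .genotype_io import MISSING, GenotypeDataset
from .ld import ld_scan, ne_from_ld, recent_ne, sharing_distribution
from .qc import QCThresholds, apply_qc
from .simdata import (
    SimConfig,
    add_trios,
    simulate_dataset,
    true_pairwise_fst,
    wright_fisher_forward,
)

RECOVERY_CONFIG = SimConfig(
    seed=0,
    n_groups=3,
    pops_per_group=3,
    inds_per_pop=30,
    n_chromosomes=2,
    snps_per_chromosome=2500,
    f_ct=0.08,
    f_st_within=0.10,
    f_is=0.05,
)


def parameter_recovery(n_seeds: int = 10, base_seed: int = 1000) -> dict[str, float]:
    """Mean recovered F_CT, pairwise F_ST and F_IS over simulator replicates.

    Uses the 3 groups x 3 populations x 30 individuals x 5000 SNP design
    with (F_CT, F_ST, F_IS) = (0.08, 0.10, 0.05); the returned dictionary
    also carries the model truths for comparison.
    """
    cfg0 = RECOVERY_CONFIG
    fcts, fsts, fiss = [], [], []
    for k in range(n_seeds):
        cfg = replace(cfg0, seed=base_seed + k)
        ds = simulate_dataset(cfg)
        res = amova(
            ds, HierarchyAssignment.from_dataset(ds, use_continent_groups=True),
            levels=4,
        )
        fcts.append(res.phi["F_CT"])
        pm = fst_matrix(ds)
        iu = np.triu_indices(len(pm.labels), 1)
        fsts.append(float(pm.values[iu].mean()))
        fiss.append(float(np.mean([fis(ds, p) for p in ds.population_indices()])))
    return {
        "fct_mean": float(np.mean(fcts)),
        "fst_mean": float(np.mean(fsts)),
        "fis_mean": float(np.mean(fiss)),
        "fct_truth": cfg0.f_ct,
        "fst_truth": true_pairwise_fst(cfg0),
        "fis_truth": cfg0.f_is,
    }


# ---------------------------------------------------------------------------
# permutation-test calibration
# ---------------------------------------------------------------------------

def _null_pair_config(seed: int, n_ind: int, n_loci: int) -> SimConfig:
    return SimConfig(
        seed=seed, n_groups=1, pops_per_group=2, inds_per_pop=n_ind,
        n_chromosomes=1, snps_per_chromosome=n_loci,
        f_ct=0.0, f_st_within=0.0, f_is=0.0,
    )


def fst_test_rejection_rate(
    f_st: float,
    n_sims: int,
    n_perm: int = 199,
    n_ind: int = 25,
    n_loci: int = 500,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> float:
    """Fraction of simulations where the pairwise F_ST test rejects.

    f_st = 0 measures the type-I error; f_st > 0 the power.
    """
    rejections = 0
    for k in range(n_sims):
        cfg = SimConfig(
            seed=base_seed + k, n_groups=1, pops_per_group=2, inds_per_pop=n_ind,
            n_chromosomes=1, snps_per_chromosome=n_loci,
            f_ct=0.0, f_st_within=f_st, f_is=0.0,
        )
        ds = simulate_dataset(cfg)
        pm = fst_matrix(ds, n_perm=n_perm, seed=base_seed + 7 * k + 1)
        if pm.pvalues[0, 1] <= alpha:
            rejections += 1
    return rejections / n_sims


def fis_test_type1_rate(
    n_sims: int,
    n_perm: int = 199,
    n_ind: int = 25,
    n_loci: int = 300,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> float:
    """Type-I error of the F_IS permutation test under random mating."""
    rejections = 0
    for k in range(n_sims):
        cfg = SimConfig(
            seed=base_seed + k, n_groups=1, pops_per_group=1, inds_per_pop=n_ind,
            n_chromosomes=1, snps_per_chromosome=n_loci, f_is=0.0,
        )
        ds = simulate_dataset(cfg)
        p = fis_significance(
            ds, "G1P1", n_perm=n_perm, seed=base_seed + 7 * k + 1
        )
        if p <= alpha:
            rejections += 1
    return rejections / n_sims


# ---------------------------------------------------------------------------
# QC planted-offender experiment
# ---------------------------------------------------------------------------

def planted_qc_dataset(seed: int = 0) -> tuple[GenotypeDataset, dict[str, set[str]]]:
    """Simulated dataset with known QC offenders planted.

    Plants parent-offspring trios (the relatedness filter's targets), two
    low-call-rate samples, one duplicated sample, low-call-rate variants
    and monomorphic variants; returns the dataset plus the planted truth.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        seed=seed + 1, n_groups=2, pops_per_group=2, inds_per_pop=20,
        n_chromosomes=1, snps_per_chromosome=4000,
    )
    ds = simulate_dataset(cfg)
    ds, trios = add_trios(ds, 5, seed=seed + 2)
    children = {t[2] for t in trios}
    calls = ds.calls.copy()
    n, m = calls.shape

    # monomorphic loci: overwrite 10 random columns with the zero dosage
    mono_cols = rng.choice(m, size=10, replace=False)
    calls[:, mono_cols] = 0
    mono_ids = {ds.variants[j].variant_id for j in mono_cols}

    # low-call-rate variants: > 2% missing (5 of n samples)
    pool = np.setdiff1d(np.arange(m), mono_cols)
    bad_var_cols = rng.choice(pool, size=6, replace=False)
    n_mask = int(np.ceil(0.025 * n)) + 1
    for j in bad_var_cols:
        rows = rng.choice(n, size=n_mask, replace=False)
        calls[rows, j] = MISSING
    bad_var_ids = {ds.variants[j].variant_id for j in bad_var_cols}

    # low-call-rate samples: > 4% missing; drawn outside the trios so the
    # planted offender categories stay disjoint
    trio_members = children | {t[0] for t in trios} | {t[1] for t in trios}
    non_trio = np.array(
        [i for i in range(n) if ds.samples[i].sample_id not in trio_members]
    )
    bad_rows = rng.choice(non_trio, size=2, replace=False)
    for i in bad_rows:
        cols = rng.choice(m, size=int(0.06 * m), replace=False)
        calls[i, cols] = MISSING
    bad_sample_ids = {ds.samples[i].sample_id for i in bad_rows}

    # duplicate: copy a clean sample's genotypes onto another clean sample
    clean = [
        i for i in non_trio if i not in set(bad_rows)
    ]
    src, dst = clean[0], clean[1]
    calls[dst] = calls[src]
    dup_id = ds.samples[dst].sample_id  # later in order, removed on tie

    out = GenotypeDataset(list(ds.samples), list(ds.variants), calls, None)
    # ground-truth monomorphic set: the planted columns plus any locus the
    # generator drifted to fixation, judged over the samples that survive
    # the earlier cascade stages (the filter's own working dataset) and
    # excluding the variants the call-rate stage removes first
    surviving = np.setdiff1d(np.arange(n), np.append(bad_rows, dst))
    sub = calls[surviving]
    nonmiss = sub != MISSING
    b = np.where(nonmiss, sub, 0).sum(axis=0)
    total = 2 * nonmiss.sum(axis=0)
    mono_all = {
        ds.variants[j].variant_id
        for j in np.flatnonzero((b == 0) | (b == total))
    } - bad_var_ids
    assert mono_ids <= mono_all
    truth = {
        "low_call_rate_samples": bad_sample_ids,
        "duplicate": {dup_id},
        "related": children,
        "low_call_rate_variants": bad_var_ids,
        "monomorphic": mono_all,
    }
    return out, truth


def qc_detection_errors(seed: int = 0) -> int:
    """Number of QC misclassifications on the planted dataset (0 = perfect)."""
    ds, truth = planted_qc_dataset(seed)
    _, report = apply_qc(ds, QCThresholds())
    by_reason: dict[str, set[str]] = {}
    for sid, reason in report.removed_samples:
        by_reason.setdefault(reason, set()).add(sid)
    for vid, reason in report.removed_variants:
        by_reason.setdefault(reason, set()).add(vid)
    expected = {
        "low_call_rate": truth["low_call_rate_samples"] | truth["low_call_rate_variants"],
        "ibs_duplicate": truth["duplicate"],
        "related": truth["related"],
        "monomorphic": truth["monomorphic"],
    }
    errors = 0
    for reason, want in expected.items():
        got = by_reason.get(reason, set())
        errors += len(got.symmetric_difference(want))
    for reason in by_reason:
        if reason not in expected:
            errors += len(by_reason[reason])
    return errors


# ---------------------------------------------------------------------------
# Ne recovery and LD sharing
# ---------------------------------------------------------------------------

def ne_recovery(
    n_reps: int = 10,
    ne: int = 100,
    generations: int = 200,
    base_seed: int = 0,
) -> float:
    """Mean recent LD-based Ne estimate over Wright-Fisher replicates."""
    estimates = []
    for k in range(n_reps):
        ds = wright_fisher_forward(ne=ne, generations=generations,
                                   seed=base_seed + k)
        traj = ne_from_ld(ds, "WF", sample_size=22, seed=base_seed + k + 1)
        estimates.append(recent_ne(traj))
    return float(np.mean(estimates))


SHARING_DIVERGENCE_LEVELS = (0.0, 0.01, 0.30)


def sharing_modes(
    divergences: tuple[float, ...] = SHARING_DIVERGENCE_LEVELS,
    seed: int = 0,
) -> list[int]:
    """Modal shared-population count at increasing divergence levels.

    Six populations draw from one shared founder pool; divergence flips
    each population's pool alleles independently.  With no divergence the
    same SNP pairs are in LD everywhere (mode = number of populations);
    divergence decorrelates the LD patterns and the mode collapses.
    """
    modes = []
    for div in divergences:
        cfg = SimConfig(
            seed=seed + 17, n_groups=1, pops_per_group=6, inds_per_pop=50,
            n_chromosomes=2, snps_per_chromosome=200,
            f_ct=0.0, f_st_within=0.0, f_is=0.0,
            haplotype_pool_size=6, shared_pool=True, pool_divergence=div,
        )
        ds = simulate_dataset(cfg)
        pair_sets = {
            pop: ld_scan(ds, pop, maf_min=0.05)
            for pop in ds.population_indices()
        }
        continent_of = {s.population: s.continent for s in ds.samples}
        modes.append(sharing_distribution(pair_sets, continent_of)["C1"].mode_k)
    return modes
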