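"""Per-population diversity: observed/expected heterozygosity and F_IS.

Statistics are computed over the population's *usable* loci (those with
less than 5% missing data within the population) that are polymorphic
within the population.  Expected heterozygosity uses the unbiased gene
diversity h = n/(n-1) (1 - p^2 - q^2) with n the number of non-missing
gene copies.  F_IS is the ratio-of-averages estimator 1 - mean(H_O)/mean(H_E),
with significance from a per-locus allele-permutation (randomised-mating)
null.

Corrected heterozygosities rescale the raw means by the fraction of
polymorphic-over-usable SNPs (H_O) and by (2N-1)/2N with N the number of
individuals in the whole working dataset (H_E) — the corrections applied to
the per-population summary tables this module mirrors.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

USABLE_MAX_MISSING = 0.05


@dataclass
class PopulationDiversity:
    population: str
    n_individuals: int
    n_polymorphic: int
    n_usable: int
    h_obs_uncorrected: float
    h_exp_uncorrected: float
    h_obs_corrected: float
    h_exp_corrected: float
    f_is: float
    f_is_pvalue: float | None = None


def _pop_calls(ds: GenotypeDataset, population: str) -> np.ndarray:
    idx = ds.population_indices().get(population)
    if idx is None:
        raise ValueError(f"population '{population}' not present")
    return ds.calls[idx]


def usable_variant_mask(ds: GenotypeDataset, population: str) -> np.ndarray:
    """True for variants with < 5% missing data within the population."""
    calls = _pop_calls(ds, population)
    missing_frac = (calls == MISSING).mean(axis=0)
    return missing_frac < USABLE_MAX_MISSING


def _polymorphic_mask(calls: np.ndarray) -> np.ndarray:
    nonmiss = calls != MISSING
    b = np.where(nonmiss, calls, 0).sum(axis=0)
    total = 2 * nonmiss.sum(axis=0)
    return (b > 0) & (b < total)


def _per_locus_h(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus observed het fraction and unbiased expected heterozygosity."""
    nonmiss = calls != MISSING
    n_ind = nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_obs = (calls == 1).sum(axis=0) / n_ind
        copies = 2.0 * n_ind
        p = np.where(copies > 0, np.where(nonmiss, calls, 0).sum(axis=0) / copies, np.nan)
        gd = 1.0 - p**2 - (1.0 - p) ** 2
        h_exp = np.where(copies > 1, copies / (copies - 1.0) * gd, np.nan)
    return h_obs, h_exp


def observed_heterozygosity(ds: GenotypeDataset, population: str) -> float:
    """Mean over usable polymorphic loci of the within-population het fraction."""
    calls = _pop_calls(ds, population)
    mask = usable_variant_mask(ds, population) & _polymorphic_mask(calls)
    if not mask.any():
        raise ValueError(f"population '{population}': no usable polymorphic loci")
    h_obs, _ = _per_locus_h(calls[:, mask])
    return float(h_obs.mean())


def expected_heterozygosity(ds: GenotypeDataset, population: str) -> float:
    """Mean unbiased gene diversity over usable polymorphic loci."""
    calls = _pop_calls(ds, population)
    mask = usable_variant_mask(ds, population) & _polymorphic_mask(calls)
    if not mask.any():
        raise ValueError(f"population '{population}': no usable polymorphic loci")
    _, h_exp = _per_locus_h(calls[:, mask])
    return float(h_exp.mean())


def unbiased_gene_diversity(p: float, n_copies: int) -> float:
    """h = n/(n-1) (1 - p^2 - q^2) for a single biallelic locus."""
    return n_copies / (n_copies - 1.0) * (1.0 - p**2 - (1.0 - p) ** 2)


def corrected_heterozygosities(
    h_obs_unc: float,
    h_exp_unc: float,
    n_polymorphic: int,
    n_usable: int,
    n_individuals_wd: int,
) -> tuple[float, float]:
    """Apply the summary-table corrections to raw multi-locus means.

    H_O is scaled by (polymorphic / usable) SNPs; H_E by (A-1)/A with
    A = 2 x the number of individuals in the whole working dataset.
    """
    if n_usable <= 0 or n_individuals_wd <= 0:
        raise ValueError("n_usable and n_individuals_wd must be positive")
    if n_polymorphic > n_usable:
        raise ValueError("n_polymorphic cannot exceed n_usable")
    n_alleles = 2 * n_individuals_wd
    h_obs_corr = h_obs_unc * (n_polymorphic / n_usable)
    h_exp_corr = h_exp_unc * (n_alleles - 1) / n_alleles
    return h_obs_corr, h_exp_corr


def fis(ds: GenotypeDataset, population: str) -> float:
    """Multi-locus F_IS = 1 - mean(H_O)/mean(H_E) over usable polymorphic loci."""
    calls = _pop_calls(ds, population)
    if calls.shape[0] < 2:
        raise ValueError("F_IS needs at least two individuals")
    mask = usable_variant_mask(ds, population) & _polymorphic_mask(calls)
    if not mask.any():
        raise ValueError(f"population '{population}': no usable polymorphic loci")
    h_obs, h_exp = _per_locus_h(calls[:, mask])
    mean_exp = float(np.nanmean(h_exp))
    if mean_exp == 0.0:
        raise ValueError("mean expected heterozygosity is zero")
    return 1.0 - float(np.nanmean(h_obs)) / mean_exp


def fis_significance(
    ds: GenotypeDataset, population: str, n_perm: int = 1000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for F_IS.

    Gene copies are permuted among individuals independently per locus
    (the randomised-mating null, which fixes allele counts and hence the
    expected heterozygosity); p is the smoothed exceedance proportion of
    |F_IS|.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    calls = _pop_calls(ds, population)
    mask = usable_variant_mask(ds, population) & _polymorphic_mask(calls)
    if not mask.any():
        raise ValueError(f"population '{population}': no usable polymorphic loci")
    calls = calls[:, mask]
    h_obs, h_exp = _per_locus_h(calls)
    mean_exp = float(np.nanmean(h_exp))
    obs = abs(1.0 - float(np.nanmean(h_obs)) / mean_exp)

    rng = np.random.default_rng(seed)
    n, loci = calls.shape
    exceed = 0
    if (calls != MISSING).all():
        # fast path: stack the two gene copies and shuffle each column
        copies = np.concatenate([(calls == 2), (calls >= 1)], axis=0).astype(np.int8)
        for _ in range(n_perm):
            perm = rng.permuted(copies, axis=0)
            het = (perm[:n] != perm[n:]).mean(axis=0)
            f_perm = 1.0 - float(het.mean()) / mean_exp
            if abs(f_perm) >= obs:
                exceed += 1
    else:
        for _ in range(n_perm):
            het_means = np.empty(loci)
            for j in range(loci):
                col = calls[:, j]
                col = col[col != MISSING]
                cps = np.concatenate([(col == 2), (col >= 1)]).astype(np.int8)
                rng.shuffle(cps)
                half = len(col)
                het_means[j] = (cps[:half] != cps[half:]).mean()
            f_perm = 1.0 - float(np.nanmean(het_means)) / mean_exp
            if abs(f_perm) >= obs:
                exceed += 1
    return (1.0 + exceed) / (n_perm + 1.0)


def population_diversity(
    ds: GenotypeDataset,
    population: str,
    n_individuals_wd: int | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> PopulationDiversity:
    """Full diversity record for one population."""
    calls = _pop_calls(ds, population)
    usable = usable_variant_mask(ds, population)
    poly = usable & _polymorphic_mask(calls)
    n_usable = int(usable.sum())
    n_poly = int(poly.sum())
    if n_poly == 0:
        raise ValueError(f"population '{population}': no usable polymorphic loci")
    h_obs, h_exp = _per_locus_h(calls[:, poly])
    h_obs_unc = float(h_obs.mean())
    h_exp_unc = float(np.nanmean(h_exp))
    n_wd = n_individuals_wd if n_individuals_wd is not None else ds.n_samples
    h_obs_c, h_exp_c = corrected_heterozygosities(
        h_obs_unc, h_exp_unc, n_poly, n_usable, n_wd
    )
    f = 1.0 - h_obs_unc / h_exp_unc
    pval = (
        fis_significance(ds, population, n_perm=n_perm, seed=seed) if n_perm else None
    )
    return PopulationDiversity(
        population=population,
        n_individuals=calls.shape[0],
        n_polymorphic=n_poly,
        n_usable=n_usable,
        h_obs_uncorrected=h_obs_unc,
        h_exp_uncorrected=h_exp_unc,
        h_obs_corrected=h_obs_c,
        h_exp_corrected=h_exp_c,
        f_is=f,
        f_is_pvalue=pval,
    )


def significance_stars(p: float | None) -> str:
    """Star coding used in the per-population table (* < .05, ** < .01, *** < .005)."""
    if p is None:
        return ""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def diversity_table(
    ds: GenotypeDataset,
    n_individuals_wd: int | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-population summary table (one row per population)."""
    rows = []
    for k, pop in enumerate(ds.population_indices()):
        d = population_diversity(
            ds, pop, n_individuals_wd=n_individuals_wd, n_perm=n_perm, seed=seed + k
        )
        rows.append(
            {
                "population": d.population,
                "n_individuals": d.n_individuals,
                "n_polymorphic": d.n_polymorphic,
                "n_usable": d.n_usable,
                "Ho_uncorrected": d.h_obs_uncorrected,
                "He_uncorrected": d.h_exp_uncorrected,
                "Ho_corrected": d.h_obs_corrected,
                "He_corrected": d.h_exp_corrected,
                "Fis": d.f_is,
                "Fis_pvalue": d.f_is_pvalue,
                "significance": significance_stars(d.f_is_pvalue),
            }
        )
    return pd.DataFrame(rows)
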