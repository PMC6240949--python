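"""Linkage disequilibrium: within-population r² scans, cross-population
LD-sharing distributions, and LD-based effective-population-size (Ne)
trajectories.

r² is computed from phased haplotypes when the dataset carries them
(D² / p_A q_A p_B q_B) and falls back to the squared Pearson correlation of
dosages otherwise; on phase-known data the two agree closely.  A scan keeps
same-chromosome pairs within 10 Mbp whose r² exceeds 0.3 (strict), the
selection behind the "number of populations sharing a pair in LD"
distribution.  Ne per distance bin inverts Sved's expectation
E[r²] = 1/(1 + 4 N c) after subtracting the 1/(2n) small-sample term:
Ne = (1/r²_adj - alpha) / (4 c), dated at t = 1/(2 c) generations ago.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset
from .qc import representative_subsample

MORGAN_PER_BP_PER_CM_MB = 1e-8  # 1 cM/Mbp expressed in Morgans per base pair


# ---------------------------------------------------------------------------
# pairwise r²
# ---------------------------------------------------------------------------

def r2_from_haplotype_counts(n_ab_both: int, n_a_only: int, n_b_only: int, n_neither: int) -> float:
    """r² from two-locus haplotype counts (carrier counts of allele B at each locus).

    Arguments are counts of the four haplotype classes: B at both loci, B at
    the first only, B at the second only, B at neither.
    """
    n = n_ab_both + n_a_only + n_b_only + n_neither
    if n == 0:
        raise ValueError("no haplotypes")
    p1 = (n_ab_both + n_a_only) / n
    p2 = (n_ab_both + n_b_only) / n
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("monomorphic locus: r² undefined")
    d = n_ab_both / n - p1 * p2
    return d * d / (p1 * (1 - p1) * p2 * (1 - p2))


def r2_haplotype(hap1: np.ndarray, hap2: np.ndarray) -> float:
    """r² between two loci given binary allele vectors over chromosomes."""
    hap1 = np.asarray(hap1, dtype=np.float64)
    hap2 = np.asarray(hap2, dtype=np.float64)
    p1, p2 = hap1.mean(), hap2.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("monomorphic locus: r² undefined")
    d = (hap1 * hap2).mean() - p1 * p2
    return float(d * d / (p1 * (1 - p1) * p2 * (1 - p2)))


def r2_genotype(dose1: np.ndarray, dose2: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over jointly non-missing entries."""
    dose1 = np.asarray(dose1)
    dose2 = np.asarray(dose2)
    ok = (dose1 != MISSING) & (dose2 != MISSING)
    x, y = dose1[ok].astype(np.float64), dose2[ok].astype(np.float64)
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance: r² undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_matrix(values: np.ndarray) -> np.ndarray:
    """Squared correlation matrix of columns; zero-variance columns give NaN."""
    v = values.astype(np.float64)
    v = v - v.mean(axis=0)
    sd = v.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = v / sd
        r = (v.T @ v) / v.shape[0]
    r[:, sd == 0] = np.nan
    r[sd == 0, :] = np.nan
    return r * r


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def ld_scan(
    ds: GenotypeDataset,
    population: str,
    max_dist_bp: int = 10_000_000,
    r2_min: float = 0.3,
    use_haplotypes: bool | None = None,
    maf_min: float = 0.0,
) -> pd.DataFrame:
    """All same-chromosome pairs within max_dist_bp with r² > r2_min (strict).

    Returns a table with chromosome, positions, variant ids and r².
    Unmapped variants (chromosome '0') and monomorphic loci are skipped.
    """
    idx = ds.population_indices().get(population)
    if idx is None:
        raise ValueError(f"population '{population}' not present")
    if use_haplotypes is None:
        use_haplotypes = ds.haplotypes is not None
    rows = []
    chroms: dict[str, list[int]] = {}
    for j, v in enumerate(ds.variants):
        if v.chromosome != "0":
            chroms.setdefault(v.chromosome, []).append(j)
    for chrom, cols in chroms.items():
        cols = np.asarray(cols, dtype=np.intp)
        pos = np.array([ds.variants[j].position_bp for j in cols])
        order = np.argsort(pos, kind="stable")
        cols, pos = cols[order], pos[order]
        if use_haplotypes:
            vals = ds.haplotypes[idx][:, :, cols].reshape(-1, len(cols))
        else:
            calls = ds.calls[idx][:, cols]
            if (calls == MISSING).any():
                vals = np.ma.masked_equal(calls, MISSING).astype(np.float64)
                r2 = np.asarray(np.ma.corrcoef(vals, rowvar=False)) ** 2
                r2 = _apply_maf_nan(ds, idx, cols, r2, maf_min)
                rows += _collect_pairs(ds, chrom, cols, pos, r2, max_dist_bp, r2_min)
                continue
            vals = calls
        r2 = _r2_matrix(vals)
        r2 = _apply_maf_nan(ds, idx, cols, r2, maf_min)
        rows += _collect_pairs(ds, chrom, cols, pos, r2, max_dist_bp, r2_min)
    return pd.DataFrame(
        rows, columns=["chromosome", "pos1", "pos2", "variant1", "variant2", "r2"]
    )


def _apply_maf_nan(ds, idx, cols, r2, maf_min):
    if maf_min <= 0:
        return r2
    calls = ds.calls[idx][:, cols]
    nonmiss = calls != MISSING
    copies = 2.0 * nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nonmiss, calls, 0).sum(axis=0) / copies
    maf = np.minimum(p, 1 - p)
    bad = ~(maf >= maf_min)
    r2[bad, :] = np.nan
    r2[:, bad] = np.nan
    return r2


def _collect_pairs(ds, chrom, cols, pos, r2, max_dist_bp, r2_min):
    rows = []
    n = len(cols)
    iu, ju = np.triu_indices(n, k=1)
    dist = pos[ju] - pos[iu]
    vals = r2[iu, ju]
    keep = (dist <= max_dist_bp) & np.isfinite(vals) & (vals > r2_min)
    for a, b, v in zip(iu[keep], ju[keep], vals[keep]):
        rows.append(
            (
                chrom,
                int(pos[a]),
                int(pos[b]),
                ds.variants[cols[a]].variant_id,
                ds.variants[cols[b]].variant_id,
                float(v),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# cross-population sharing
# ---------------------------------------------------------------------------

@dataclass
class SharingDistribution:
    continent: str
    histogram: pd.DataFrame  # columns: k, n_pairs, percentage
    mode_k: int
    total_pairs: int


def sharing_distribution(
    pair_sets: dict[str, pd.DataFrame],
    continent_of_population: dict[str, str],
) -> dict[str, SharingDistribution]:
    """Per continent: how many populations share each SNP pair in LD.

    Pairs are keyed by (chromosome, pos1, pos2); k counts the populations of
    the continent whose scan contains the key.  Percentages sum to 100 over
    the observed k values; the mode is the k with the largest pair count
    (smallest k on ties).
    """
    by_continent: dict[str, list[str]] = {}
    for pop in pair_sets:
        cont = continent_of_population.get(pop)
        if cont is None:
            raise ValueError(f"population '{pop}' has no continent assignment")
        by_continent.setdefault(cont, []).append(pop)
    out: dict[str, SharingDistribution] = {}
    for cont, pops in by_continent.items():
        counter: dict[tuple, int] = {}
        for pop in pops:
            tab = pair_sets[pop]
            keys = set(zip(tab["chromosome"], tab["pos1"], tab["pos2"]))
            for key in keys:
                counter[key] = counter.get(key, 0) + 1
        if not counter:
            out[cont] = SharingDistribution(
                cont, pd.DataFrame(columns=["k", "n_pairs", "percentage"]), 0, 0
            )
            continue
        ks = np.array(list(counter.values()))
        total = len(ks)
        uniq, counts = np.unique(ks, return_counts=True)
        hist = pd.DataFrame(
            {"k": uniq, "n_pairs": counts, "percentage": 100.0 * counts / total}
        )
        mode_k = int(uniq[np.argmax(counts)])
        out[cont] = SharingDistribution(cont, hist, mode_k, total)
    return out


# ---------------------------------------------------------------------------
# Ne from LD
# ---------------------------------------------------------------------------

def sved_ne(r2_adj: float, c: float, alpha: float = 1.0) -> tuple[float, float]:
    """Invert Sved's expectation: Ne = (1/r²_adj - alpha)/(4c), t = 1/(2c)."""
    if r2_adj <= 0:
        raise ValueError("adjusted r² must be positive")
    return (1.0 / r2_adj - alpha) / (4.0 * c), 1.0 / (2.0 * c)


def ne_from_ld(
    ds: GenotypeDataset,
    population: str,
    bin_edges_bp: list[int] | None = None,
    sample_size: int = 22,
    seed: int = 0,
    alpha: float = 1.0,
    cm_per_mb: float = 1.0,
    maf_min: float = 0.05,
    use_haplotypes: bool | None = None,
) -> pd.DataFrame | None:
    """LD-based Ne trajectory for one population; None if it is too small.

    The population is first reduced to ``sample_size`` individuals with the
    representative-subsampling procedure (populations below that size are
    skipped, mirroring the fixed-sample-size design).  Same-chromosome SNP
    pairs are binned by recombination distance c (uniform cm_per_mb map);
    each bin contributes Ne = (1/r²_adj - alpha)/(4 c̄) at t = 1/(2 c̄), where
    r²_adj is the bin's mean r² minus 1/(2 * sample_size).  Bins without
    pairs, or whose adjusted r² is non-positive, are omitted.
    """
    idx = ds.population_indices().get(population)
    if idx is None:
        raise ValueError(f"population '{population}' not present")
    if len(idx) < sample_size:
        return None
    if bin_edges_bp is None:
        bin_edges_bp = [int(e) for e in np.linspace(250_000, 10_000_000, 14)]
    chosen = representative_subsample(ds, population, sample_size, seed=seed)
    keep = [i for i in idx if ds.samples[i].sample_id in set(chosen)]
    sub = ds.subset_samples(keep)

    if use_haplotypes is None:
        use_haplotypes = sub.haplotypes is not None
    pairs = _all_pairs_r2(
        sub, max_dist_bp=max(bin_edges_bp), use_haplotypes=use_haplotypes,
        maf_min=maf_min,
    )
    if pairs.empty:
        return pd.DataFrame(columns=["c", "t_generations", "mean_r2", "r2_adj", "ne", "n_pairs"])
    dist = pairs["pos2"].to_numpy() - pairs["pos1"].to_numpy()
    c = dist * cm_per_mb * MORGAN_PER_BP_PER_CM_MB
    r2 = pairs["r2"].to_numpy()
    edges_c = np.asarray(bin_edges_bp, dtype=np.float64) * cm_per_mb * MORGAN_PER_BP_PER_CM_MB
    rows = []
    correction = 1.0 / (2.0 * sample_size)
    for lo, hi in zip(edges_c[:-1], edges_c[1:]):
        sel = (c > lo) & (c <= hi)
        if not sel.any():
            continue
        cbar = float(c[sel].mean())
        mean_r2 = float(r2[sel].mean())
        adj = mean_r2 - correction
        if adj <= 0:
            continue
        ne, t = sved_ne(adj, cbar, alpha=alpha)
        rows.append(
            {
                "c": cbar,
                "t_generations": t,
                "mean_r2": mean_r2,
                "r2_adj": adj,
                "ne": ne,
                "n_pairs": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def recent_ne(trajectory: pd.DataFrame, min_t_generations: float = 20.0) -> float:
    """Most recent well-conditioned Ne estimate of a trajectory.

    Bins at very small t (large c) have mean r² close to the 1/(2n)
    sampling floor, where inverting Sved's expectation is ill-conditioned;
    the most recent bin at or beyond ``min_t_generations`` is used instead.
    """
    ok = trajectory[trajectory["t_generations"] >= min_t_generations]
    if ok.empty:
        raise ValueError("no bin at or beyond the requested time depth")
    return float(ok.loc[ok["t_generations"].idxmin(), "ne"])


def _all_pairs_r2(
    ds: GenotypeDataset, max_dist_bp: int, use_haplotypes: bool, maf_min: float
) -> pd.DataFrame:
    """r² for all same-chromosome pairs within max_dist_bp (no r² threshold)."""
    idx = np.arange(ds.n_samples, dtype=np.intp)
    rows = []
    chroms: dict[str, list[int]] = {}
    for j, v in enumerate(ds.variants):
        if v.chromosome != "0":
            chroms.setdefault(v.chromosome, []).append(j)
    for chrom, cols in chroms.items():
        cols = np.asarray(cols, dtype=np.intp)
        pos = np.array([ds.variants[j].position_bp for j in cols])
        order = np.argsort(pos, kind="stable")
        cols, pos = cols[order], pos[order]
        if use_haplotypes:
            vals = ds.haplotypes[:, :, cols].reshape(-1, len(cols))
        else:
            vals = ds.calls[:, cols]
        r2 = _r2_matrix(np.asarray(vals))
        r2 = _apply_maf_nan(ds, idx, cols, r2, maf_min)
        n = len(cols)
        iu, ju = np.triu_indices(n, k=1)
        dist = pos[ju] - pos[iu]
        vals_r2 = r2[iu, ju]
        keep = (dist <= max_dist_bp) & np.isfinite(vals_r2)
        for a, b, v in zip(iu[keep], ju[keep], vals_r2[keep]):
            rows.append((chrom, int(pos[a]), int(pos[b]), float(v)))
    return pd.DataFrame(rows, columns=["chromosome", "pos1", "pos2", "r2"])
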