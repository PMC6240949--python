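"""Synthetic hierarchically structured SNP genotypes.

The generator emulates the statistical structure the analysis stages
assume: continental groups of populations whose allele frequencies drift
from a shared ancestral frequency under the Balding-Nichols Beta model
(group level parameterised by F_CT, population level by F_ST_within),
within-population inbreeding (F_IS), block LD induced by finite founder
haplotype pools, parent-offspring trios, monomorphic loci and missing
calls.  A separate discrete-generation Wright-Fisher forward simulator
with recombination provides ground truth for LD-based Ne estimation.

Every generator is a pure function of its configuration and seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genotype_io import MISSING, GenotypeDataset, SampleRecord, VariantRecord


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the hierarchical population model.

    F_CT is the between-group differentiation, F_ST_within the
    between-population differentiation within a group, F_IS the
    within-population inbreeding coefficient.  ``haplotype_pool_size``
    of None means an effectively infinite founder pool (no block LD);
    a finite pool of K founder haplotypes per population induces LD.
    With ``shared_pool`` the pool is drawn once per group and each
    population receives its own copy, diverged by ``pool_drift_rounds``
    rounds of founder resampling (drift on the founder pool, which shifts
    haplotype frequencies population-specifically) and/or by flipping each
    pool allele independently with probability ``pool_divergence`` — the
    knobs that decouple LD-pattern sharing from the frequency hierarchy.
    """

    seed: int
    n_groups: int = 3
    pops_per_group: int = 3
    inds_per_pop: int = 30
    n_chromosomes: int = 2
    snps_per_chromosome: int = 250
    chrom_length_bp: int = 50_000_000
    f_ct: float = 0.08
    f_st_within: float = 0.10
    f_is: float = 0.05
    ancestral_maf_low: float = 0.05
    ancestral_maf_high: float = 0.5
    haplotype_pool_size: int | None = None
    shared_pool: bool = False
    pool_divergence: float = 0.0
    pool_drift_rounds: int = 0
    n_trios: int = 0
    missing_rate: float = 0.0
    monomorphic_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f_ct", "f_st_within", "f_is", "missing_rate",
                     "monomorphic_fraction", "pool_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in ("n_groups", "pops_per_group", "inds_per_pop",
                     "n_chromosomes", "snps_per_chromosome", "chrom_length_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Draw descendant frequencies around p with differentiation f."""
    if f == 0.0:
        return p.copy()
    p = np.clip(p, 1e-6, 1.0 - 1e-6)
    scale = (1.0 - f) / f
    return rng.beta(p * scale, (1.0 - p) * scale)


def simulate_frequencies(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Ancestral, group and population allele-B frequencies.

    Returns arrays 'ancestral' (L,), 'group' (G, L) and 'population'
    (G, P, L); F = 0 at a level copies the parent frequencies exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    p0 = rng.uniform(cfg.ancestral_maf_low, cfg.ancestral_maf_high, size=L)
    # half the loci carry the minor allele as allele B, half as allele A,
    # so frequencies are not systematically below one half
    flip = rng.random(L) < 0.5
    p0 = np.where(flip, 1.0 - p0, p0)
    groups = np.stack(
        [_balding_nichols(rng, p0, cfg.f_ct) for _ in range(cfg.n_groups)]
    )
    pops = np.stack(
        [
            np.stack(
                [
                    _balding_nichols(rng, groups[g], cfg.f_st_within)
                    for _ in range(cfg.pops_per_group)
                ]
            )
            for g in range(cfg.n_groups)
        ]
    )
    if cfg.monomorphic_fraction > 0:
        n_mono = int(round(cfg.monomorphic_fraction * L))
        mono = rng.choice(L, size=n_mono, replace=False)
        pops[:, :, mono] = 0.0
        groups[:, mono] = 0.0
    return {"ancestral": p0, "group": groups, "population": pops}


def _variant_records(cfg: SimConfig) -> list[VariantRecord]:
    step = cfg.chrom_length_bp // (cfg.snps_per_chromosome + 1)
    out = []
    for ch in range(cfg.n_chromosomes):
        for s in range(cfg.snps_per_chromosome):
            out.append(
                VariantRecord(
                    variant_id=f"snp{ch + 1}_{s + 1}",
                    chromosome=str(ch + 1),
                    position_bp=(s + 1) * step,
                    allele_a="A",
                    allele_b="B",
                )
            )
    return out


def simulate_genotypes(
    frequencies: dict[str, np.ndarray], cfg: SimConfig
) -> GenotypeDataset:
    """Genotypes (and truth haplotypes) from the hierarchical frequencies.

    Heterozygote probability is 2pq(1 - F_IS).  With an infinite pool the
    two haplotypes are independent Bernoulli draws, inbreeding applied as
    per-entry identity-by-descent; with a finite pool each individual draws
    two founder haplotypes (the same one with probability F_IS).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    pops = frequencies["population"]
    groups_freq = frequencies["group"]
    G, P, L = pops.shape
    samples: list[SampleRecord] = []
    hap_blocks: list[np.ndarray] = []
    n = cfg.inds_per_pop
    for g in range(G):
        group_pool = None
        if cfg.haplotype_pool_size and cfg.shared_pool:
            group_pool = (
                rng.random((cfg.haplotype_pool_size, L)) < groups_freq[g]
            ).astype(np.int8)
        for p in range(P):
            freq = pops[g, p]
            if cfg.haplotype_pool_size:
                if cfg.shared_pool:
                    pool = group_pool.copy()
                    for _ in range(cfg.pool_drift_rounds):
                        pool = pool[rng.integers(len(pool), size=len(pool))]
                    if cfg.pool_divergence > 0:
                        flips = rng.random(pool.shape) < cfg.pool_divergence
                        pool = pool ^ flips
                else:
                    pool = (
                        rng.random((cfg.haplotype_pool_size, L)) < freq
                    ).astype(np.int8)
                f1 = rng.integers(cfg.haplotype_pool_size, size=n)
                f2 = rng.integers(cfg.haplotype_pool_size, size=n)
                ibd = rng.random(n) < cfg.f_is
                f2 = np.where(ibd, f1, f2)
                haps = np.stack([pool[f1], pool[f2]], axis=1)
            else:
                h1 = (rng.random((n, L)) < freq).astype(np.int8)
                h2 = (rng.random((n, L)) < freq).astype(np.int8)
                if cfg.f_is > 0:
                    ibd = rng.random((n, L)) < cfg.f_is
                    h2 = np.where(ibd, h1, h2)
                haps = np.stack([h1, h2], axis=1)
            hap_blocks.append(haps)
            pop_code = f"G{g + 1}P{p + 1}"
            lat = float(np.clip(-60 + 30 * g + 2 * p, -90, 90))
            lon = float(np.clip(-150 + 40 * g + 5 * p, -180, 180))
            samples += [
                SampleRecord(
                    sample_id=f"{pop_code}_I{i + 1:03d}",
                    population=pop_code,
                    continent=f"C{g + 1}",
                    country=f"K{g + 1}{p + 1}",
                    latitude=lat,
                    longitude=lon,
                )
                for i in range(n)
            ]
    haplotypes = np.concatenate(hap_blocks, axis=0)
    calls = haplotypes.sum(axis=1).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)
    ds = GenotypeDataset(samples, _variant_records(cfg), calls, haplotypes)
    ds.validate()
    return ds


def simulate_dataset(cfg: SimConfig) -> GenotypeDataset:
    """Convenience: frequencies + genotypes (+ trios when configured)."""
    ds = simulate_genotypes(simulate_frequencies(cfg), cfg)
    if cfg.n_trios:
        ds, _ = add_trios(ds, cfg.n_trios, seed=cfg.seed + 2)
    return ds


def add_trios(
    ds: GenotypeDataset, n_trios: int, seed: int, populations: list[str] | None = None
) -> tuple[GenotypeDataset, list[tuple[str, str, str]]]:
    """Append offspring of random parent pairs drawn within populations.

    Each gamete is one whole parental haplotype (Mendelian-exact and
    LD-preserving), so parent-child pairs have zero pairwise Mendelian
    errors by construction.  Returns the extended dataset and the list of
    (parent1, parent2, child) id triples.
    """
    if ds.haplotypes is None:
        raise ValueError("trios need haplotypes on the dataset")
    rng = np.random.default_rng(seed)
    pop_idx = ds.population_indices()
    pops = populations or list(pop_idx)
    new_samples = list(ds.samples)
    new_haps = [ds.haplotypes]
    new_calls = [ds.calls]
    trios: list[tuple[str, str, str]] = []
    for k in range(n_trios):
        pop = pops[k % len(pops)]
        idx = pop_idx[pop]
        if len(idx) < 2:
            raise ValueError(f"population '{pop}' too small to sample parents")
        pa, pb = rng.choice(idx, size=2, replace=False)
        gam_a = ds.haplotypes[pa, rng.integers(2)]
        gam_b = ds.haplotypes[pb, rng.integers(2)]
        child_h = np.stack([gam_a, gam_b])[None]
        new_haps.append(child_h)
        new_calls.append(child_h.sum(axis=1).astype(np.int8))
        child_id = f"{pop}_T{k + 1}C"
        parent = ds.samples[pa]
        new_samples.append(
            SampleRecord(
                sample_id=child_id,
                population=pop,
                continent=parent.continent,
                country=parent.country,
                latitude=parent.latitude,
                longitude=parent.longitude,
            )
        )
        trios.append((ds.samples[pa].sample_id, ds.samples[pb].sample_id, child_id))
    out = GenotypeDataset(
        new_samples,
        list(ds.variants),
        np.concatenate(new_calls, axis=0),
        np.concatenate(new_haps, axis=0),
    )
    out.validate()
    return out, trios


def wright_fisher_forward(
    ne: int,
    generations: int,
    seed: int,
    n_chromosomes: int = 3,
    snps_per_chromosome: int = 200,
    chrom_length_bp: int = 10_000_000,
    cm_per_mb: float = 1.0,
    init_maf_low: float = 0.1,
    init_maf_high: float = 0.5,
    population: str = "WF",
) -> GenotypeDataset:
    """Discrete-generation Wright-Fisher population with recombination.

    ``ne`` diploids mate at random (selfing allowed); each gamete is a
    recombinant of the parent's two haplotypes with crossover probability
    between adjacent SNPs from a uniform cm_per_mb map (Haldane).  The
    final generation is returned as a single-population dataset with
    haplotypes.
    """
    if ne < 2:
        raise ValueError("ne must be >= 2")
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        seed=seed,
        n_chromosomes=n_chromosomes,
        snps_per_chromosome=snps_per_chromosome,
        chrom_length_bp=chrom_length_bp,
    )
    variants = _variant_records(cfg)
    L = len(variants)
    pos = np.array([v.position_bp for v in variants], dtype=np.float64)
    chrom = np.array([int(v.chromosome) for v in variants])
    gaps_m = np.diff(pos) * cm_per_mb * 1e-8
    rec = 0.5 * (1.0 - np.exp(-2.0 * gaps_m))  # Haldane map function
    rec[np.diff(chrom) != 0] = 0.5  # free recombination across chromosomes

    p0 = rng.uniform(init_maf_low, init_maf_high, size=L)
    flip = rng.random(L) < 0.5
    p0 = np.where(flip, 1.0 - p0, p0)
    haps_a = (rng.random((ne, L)) < p0).astype(np.int8)
    haps_b = (rng.random((ne, L)) < p0).astype(np.int8)

    def _gametes(parents: np.ndarray) -> np.ndarray:
        start = rng.integers(2, size=(ne, 1))
        switches = (rng.random((ne, L - 1)) < rec).astype(np.int8)
        sel = (start + np.concatenate(
            [np.zeros((ne, 1), dtype=np.int8), np.cumsum(switches, axis=1)], axis=1
        )) % 2
        return np.where(sel == 0, haps_a[parents], haps_b[parents]).astype(np.int8)

    for _ in range(generations):
        mothers = rng.integers(ne, size=ne)
        fathers = rng.integers(ne, size=ne)
        new_a = _gametes(mothers)
        new_b = _gametes(fathers)
        haps_a, haps_b = new_a, new_b

    haplotypes = np.stack([haps_a, haps_b], axis=1)
    calls = haplotypes.sum(axis=1).astype(np.int8)
    samples = [
        SampleRecord(sample_id=f"{population}_I{i + 1:03d}", population=population,
                     continent="WF", country="WF")
        for i in range(ne)
    ]
    ds = GenotypeDataset(samples, variants, calls, haplotypes)
    ds.validate()
    return ds


def true_pairwise_fst(cfg: SimConfig) -> float:
    """Expected mean pairwise F_ST across all population pairs of the model.

    Within-group pairs differentiate at F_ST_within; cross-group pairs at
    F_CT + F_ST_within (1 - F_CT).
    """
    P = cfg.pops_per_group
    G = cfg.n_groups
    total_pairs = (G * P) * (G * P - 1) / 2
    within_pairs = G * P * (P - 1) / 2
    cross_pairs = total_pairs - within_pairs
    f_cross = cfg.f_ct + cfg.f_st_within * (1.0 - cfg.f_ct)
    return (within_pairs * cfg.f_st_within + cross_pairs * f_cross) / total_pairs
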