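"""Quality-control cascade for SNP-array genotype datasets.

The cascade runs in a fixed order: sample call rate, variant call rate
(recomputed after sample removal), identity-by-state duplicate removal,
monomorphic-variant removal, Mendelian-error relatedness pruning,
population exclusion/size rules, and representative subsampling of large
populations.  Every removal is logged in a :class:`QCReport` with a reason
code, and stage counts reconcile exactly.

Thresholds follow the missingness convention of PLINK's --mind/--geno:
"call rate higher than x" keeps samples with rate >= x (configurable to a
strict inequality via ``strict_call_rate``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass(frozen=True)
class QCThresholds:
    """Cut-offs of the QC cascade.

    ind_call_rate_min / snp_call_rate_min: minimum fraction of non-missing
        calls per individual / per SNP.
    ibs_duplicate_min: IBS similarity at or above which a pair is treated
        as a duplicate and one member dropped.
    me_related_max: pairs with fewer than this many pairwise Mendelian
        errors (opposing homozygotes) count as related.
    min_pop_size: populations with fewer individuals are dropped.
    target_pop_size: populations larger than this are subsampled down to it.
    """

    ind_call_rate_min: float = 0.96
    snp_call_rate_min: float = 0.98
    ibs_duplicate_min: float = 0.99
    me_related_max: int = 100
    min_pop_size: int = 3
    target_pop_size: int = 50
    subsample_draws: int = 100
    strict_call_rate: bool = False

    def __post_init__(self) -> None:
        for name in ("ind_call_rate_min", "snp_call_rate_min", "ibs_duplicate_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("me_related_max", "min_pop_size", "target_pop_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class QCReport:
    """Ordered record of everything the cascade removed and why."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_variants: list[tuple[str, str]] = field(default_factory=list)
    stages: list[tuple[str, int, int]] = field(default_factory=list)  # (stage, n_samp, n_var)
    notes: list[str] = field(default_factory=list)

    def record_stage(self, stage: str, ds: GenotypeDataset) -> None:
        self.stages.append((stage, ds.n_samples, ds.n_variants))

    def drop_samples(self, ids: list[str], reason: str) -> None:
        seen = {sid for sid, _ in self.removed_samples}
        for sid in ids:
            if sid in seen:
                raise ValueError(f"sample {sid} removed twice")
            self.removed_samples.append((sid, reason))

    def drop_variants(self, ids: list[str], reason: str) -> None:
        seen = {vid for vid, _ in self.removed_variants}
        for vid in ids:
            if vid in seen:
                raise ValueError(f"variant {vid} removed twice")
            self.removed_variants.append((vid, reason))

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", i, r) for i, r in self.removed_samples]
        rows += [("variant", i, r) for i, r in self.removed_variants]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])

    def stage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_samples", "n_variants"])


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def call_rates(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample and per-variant fraction of non-missing calls."""
    if ds.n_samples == 0 or ds.n_variants == 0:
        raise ValueError("empty dataset")
    nonmiss = ds.calls != MISSING
    return nonmiss.mean(axis=1), nonmiss.mean(axis=0)


def minor_allele_frequencies(
    ds: GenotypeDataset, by_population: bool = False
) -> pd.DataFrame:
    """MAF per variant, overall or stratified by population.

    Loci with no non-missing calls get ``NaN`` MAF.  MAF is invariant under
    allele recoding by construction (min(p, 1-p)).
    """

    def _maf(calls: np.ndarray) -> np.ndarray:
        nonmiss = calls != MISSING
        copies = 2.0 * nonmiss.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(copies > 0, np.where(nonmiss, calls, 0).sum(axis=0) / copies, np.nan)
        return np.minimum(p, 1.0 - p)

    if not by_population:
        return pd.DataFrame({"variant_id": ds.variant_ids, "maf": _maf(ds.calls)})
    frames = []
    for pop, idx in ds.population_indices().items():
        frames.append(
            pd.DataFrame(
                {"population": pop, "variant_id": ds.variant_ids, "maf": _maf(ds.calls[idx])}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _passes(rate: np.ndarray, minimum: float, strict: bool) -> np.ndarray:
    return rate > minimum if strict else rate >= minimum


def filter_call_rate(
    ds: GenotypeDataset, thr: QCThresholds, report: QCReport | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Drop low-call-rate samples, then low-call-rate variants (recomputed)."""
    report = report or QCReport()
    sample_rate, _ = call_rates(ds)
    keep_s = _passes(sample_rate, thr.ind_call_rate_min, thr.strict_call_rate)
    report.drop_samples(
        [s for s, k in zip(ds.sample_ids, keep_s) if not k], "low_call_rate"
    )
    ds = ds.subset_samples(np.flatnonzero(keep_s))
    if ds.n_samples == 0:
        raise ValueError("all samples failed the call-rate filter; review thresholds")
    report.record_stage("sample_call_rate", ds)

    _, variant_rate = call_rates(ds)
    keep_v = _passes(variant_rate, thr.snp_call_rate_min, thr.strict_call_rate)
    report.drop_variants(
        [v for v, k in zip(ds.variant_ids, keep_v) if not k], "low_call_rate"
    )
    ds = ds.subset_variants(np.flatnonzero(keep_v))
    if ds.n_variants == 0:
        raise ValueError("all variants failed the call-rate filter; review thresholds")
    report.record_stage("variant_call_rate", ds)
    return ds, report


def remove_monomorphic(
    ds: GenotypeDataset, report: QCReport | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Drop variants with a single observed allele across the whole dataset."""
    report = report or QCReport()
    nonmiss = ds.calls != MISSING
    dose = np.where(nonmiss, ds.calls, 0)
    b_copies = dose.sum(axis=0)
    total = 2 * nonmiss.sum(axis=0)
    poly = (b_copies > 0) & (b_copies < total)
    report.drop_variants(
        [v for v, k in zip(ds.variant_ids, poly) if not k], "monomorphic"
    )
    ds = ds.subset_variants(np.flatnonzero(poly))
    report.record_stage("monomorphic", ds)
    return ds, report


def pairwise_ibs(ds: GenotypeDataset) -> np.ndarray:
    """Symmetric matrix of IBS similarity over jointly non-missing loci.

    IBS(i, j) = mean of 1 - |d_i - d_j| / 2 (PLINK DST-style dosage
    agreement).  Pairs with no jointly non-missing loci get NaN.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least two samples")
    calls = ds.calls
    m = (calls != MISSING).astype(np.float64)
    i0 = ((calls == 0) & (calls != MISSING)).astype(np.float64)
    i1 = (calls == 1).astype(np.float64)
    i2 = (calls == 2).astype(np.float64)
    joint = m @ m.T
    diff1 = i0 @ i1.T + i1 @ i0.T + i1 @ i2.T + i2 @ i1.T
    diff2 = i0 @ i2.T + i2 @ i0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = 1.0 - (diff1 + 2.0 * diff2) / (2.0 * joint)
    ibs[joint == 0] = np.nan
    return ibs


def remove_ibs_duplicates(
    ds: GenotypeDataset, thr: QCThresholds, report: QCReport | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Drop one member of each near-duplicate pair (IBS >= threshold).

    The member with the lower call rate goes; on a tie, the later one in
    sample order.  Applied greedily until no flagged pair remains.
    """
    report = report or QCReport()
    if ds.n_samples < 2:
        report.record_stage("ibs_duplicates", ds)
        return ds, report
    ibs = pairwise_ibs(ds)
    rate, _ = call_rates(ds)
    n = ds.n_samples
    alive = np.ones(n, dtype=bool)
    removed: list[str] = []
    flagged = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if np.isfinite(ibs[i, j]) and ibs[i, j] >= thr.ibs_duplicate_min
    ]
    for i, j in flagged:
        if not (alive[i] and alive[j]):
            continue
        if rate[i] < rate[j]:
            victim = i
        elif rate[j] < rate[i]:
            victim = j
        else:
            victim = max(i, j)
        alive[victim] = False
        removed.append(ds.sample_ids[victim])
    report.drop_samples(removed, "ibs_duplicate")
    ds = ds.subset_samples(np.flatnonzero(alive))
    report.record_stage("ibs_duplicates", ds)
    return ds, report


# ---------------------------------------------------------------------------
# Mendelian-error relatedness
# ---------------------------------------------------------------------------

def mendelian_error_count(g_i: np.ndarray, g_j: np.ndarray) -> int:
    """Count loci where two individuals are opposing homozygotes (0 vs 2).

    Such loci are impossible between parent and offspring, so a low count
    over many markers indicates close relatedness.
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    if g_i.shape != g_j.shape:
        raise ValueError("dosage vectors must have equal length")
    return int((((g_i == 0) & (g_j == 2)) | ((g_i == 2) & (g_j == 0))).sum())


def mendelian_error_matrix(ds: GenotypeDataset) -> np.ndarray:
    """Pairwise opposing-homozygote counts for all sample pairs."""
    a = ((ds.calls == 0) & (ds.calls != MISSING)).astype(np.float64)
    b = (ds.calls == 2).astype(np.float64)
    me = a @ b.T + b @ a.T
    return me.astype(np.int64)


def relatedness_prune(
    ds: GenotypeDataset, thr: QCThresholds, report: QCReport | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Greedy cover of the relatedness graph built from pairwise ME counts.

    While related pairs (ME < me_related_max) remain, remove the sample in
    the most pairs (ties: lower call rate, then later sample order).
    """
    report = report or QCReport()
    if ds.n_samples < 2:
        report.record_stage("relatedness", ds)
        return ds, report
    me = mendelian_error_matrix(ds)
    related = me < thr.me_related_max
    np.fill_diagonal(related, False)
    rate, _ = call_rates(ds)
    alive = np.ones(ds.n_samples, dtype=bool)
    removed: list[str] = []
    while True:
        deg = (related & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max(initial=0) == 0:
            break
        top = deg == deg.max()
        cand = np.flatnonzero(top)
        worst_rate = rate[cand].min()
        cand = cand[rate[cand] == worst_rate]
        victim = int(cand.max())  # later sample order
        alive[victim] = False
        removed.append(ds.sample_ids[victim])
    report.drop_samples(removed, "related")
    report.notes.append(f"relatedness_prune removed {len(removed)} samples")
    ds = ds.subset_samples(np.flatnonzero(alive))
    report.record_stage("relatedness", ds)
    return ds, report


# ---------------------------------------------------------------------------
# population rules and subsampling
# ---------------------------------------------------------------------------

def apply_population_rules(
    ds: GenotypeDataset,
    exclusions: list[str],
    thr: QCThresholds,
    report: QCReport | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Drop excluded populations, then populations below the minimum size."""
    report = report or QCReport()
    pops = ds.population_indices()
    for name in exclusions:
        if name not in pops:
            report.notes.append(f"exclusion '{name}' names no present population")
    excluded = set(exclusions)
    drop_excl = [s.sample_id for s in ds.samples if s.population in excluded]
    report.drop_samples(drop_excl, "excluded_population")
    keep = [i for i, s in enumerate(ds.samples) if s.population not in excluded]
    ds = ds.subset_samples(keep)

    sizes = {p: len(ix) for p, ix in ds.population_indices().items()}
    small = {p for p, n in sizes.items() if n < thr.min_pop_size}
    drop_small = [s.sample_id for s in ds.samples if s.population in small]
    report.drop_samples(drop_small, "small_population")
    keep = [i for i, s in enumerate(ds.samples) if s.population not in small]
    ds = ds.subset_samples(keep)
    report.record_stage("population_rules", ds)
    return ds, report


def representative_subsample(
    ds: GenotypeDataset,
    population: str,
    n: int,
    seed: int,
    n_draws: int = 100,
) -> list[str]:
    """Pick n individuals whose allele frequencies best match the population.

    Draws ``n_draws`` seeded random subsets of size n and returns the one
    minimising the Euclidean distance between its per-locus allele-B
    frequencies and the full population's, so the variance structure of the
    original sample is preserved.  Deterministic given the seed.
    """
    idx = ds.population_indices().get(population)
    if idx is None:
        raise ValueError(f"population '{population}' not present")
    if len(idx) <= n:
        return [ds.samples[i].sample_id for i in idx]
    calls = ds.calls[idx]
    nonmiss = calls != MISSING
    dose = np.where(nonmiss, calls, 0).astype(np.float64)

    def _freq(rows: np.ndarray) -> np.ndarray:
        copies = 2.0 * nonmiss[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(copies > 0, dose[rows].sum(axis=0) / copies, np.nan)

    full = _freq(np.arange(len(idx)))
    rng = np.random.default_rng(seed)
    best_rows: np.ndarray | None = None
    best_dist = np.inf
    for _ in range(n_draws):
        rows = rng.choice(len(idx), size=n, replace=False)
        diff = _freq(rows) - full
        dist = float(np.sqrt(np.nansum(diff**2)))
        if dist < best_dist:
            best_dist = dist
            best_rows = np.sort(rows)
    assert best_rows is not None
    return [ds.samples[idx[i]].sample_id for i in best_rows]


def subsample_large_populations(
    ds: GenotypeDataset,
    thr: QCThresholds,
    seed: int,
    report: QCReport | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Reduce every population above target_pop_size via representative draws."""
    report = report or QCReport()
    keep_ids = set(ds.sample_ids)
    for pop, idx in ds.population_indices().items():
        if len(idx) > thr.target_pop_size:
            chosen = set(
                representative_subsample(
                    ds, pop, thr.target_pop_size,
                    seed=_pop_seed(seed, pop), n_draws=thr.subsample_draws,
                )
            )
            for i in idx:
                sid = ds.samples[i].sample_id
                if sid not in chosen:
                    keep_ids.discard(sid)
    dropped = [sid for sid in ds.sample_ids if sid not in keep_ids]
    report.drop_samples(dropped, "subsampled_out")
    keep = [i for i, s in enumerate(ds.samples) if s.sample_id in keep_ids]
    ds = ds.subset_samples(keep)
    report.record_stage("subsampling", ds)
    return ds, report


def _pop_seed(seed: int, population: str) -> int:
    """Stable per-population sub-seed below 2^31."""
    import hashlib

    h = hashlib.sha256(f"{seed}:{population}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def apply_qc(
    ds: GenotypeDataset,
    thr: QCThresholds | None = None,
    exclusions: list[str] | None = None,
    seed: int = 0,
) -> tuple[GenotypeDataset, QCReport]:
    """Run the full cascade in the fixed order and return dataset + report."""
    thr = thr or QCThresholds()
    report = QCReport()
    report.record_stage("input", ds)
    ds, report = filter_call_rate(ds, thr, report)
    ds, report = remove_ibs_duplicates(ds, thr, report)
    ds, report = remove_monomorphic(ds, report)
    ds, report = relatedness_prune(ds, thr, report)
    ds, report = apply_population_rules(ds, exclusions or [], thr, report)
    ds, report = subsample_large_populations(ds, thr, seed, report)
    return ds, report
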