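"""Between-population differentiation: Weir-Cockerham F_ST, Reynolds
distances, and neighbor-joining tree export.

The F_ST estimator is the two-population Weir-Cockerham theta: per-locus
variance components a (among populations), b (among individuals within
populations) and c (within individuals), combined across loci as a ratio
of sums.  Significance comes from permuting individuals between the two
populations.  Reynolds' unweighted distance averages the per-locus
coancestry ratio theta_l over loci.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class PairwiseMatrix:
    """Symmetric population-by-population matrix with optional p-values."""

    labels: list[str]
    values: np.ndarray
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def to_frame(self, floor_zero: bool = False) -> pd.DataFrame:
        vals = np.maximum(self.values, 0.0) if floor_zero else self.values
        return pd.DataFrame(vals, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "  " + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _pop_locus_stats(
    calls: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus sample size (individuals), allele-B frequency, het fraction."""
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nonmiss, calls, 0).sum(axis=0) / (2.0 * n)
        h = (calls == 1).sum(axis=0) / n
    return n, p, h


def wc_components(
    callsA: np.ndarray, callsB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham per-locus components (a, b, c) and the usable-locus mask.

    Loci need >= 2 individuals with data in each population and must be
    polymorphic in the pooled sample.
    """
    nA, pA, hA = _pop_locus_stats(callsA)
    nB, pB, hB = _pop_locus_stats(callsB)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (nA + nB) / r
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)
        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    usable = (nA >= 2) & (nB >= 2) & (pbar > 0) & (pbar < 1)
    return a, b, c, usable


def weir_cockerham_fst(
    ds: GenotypeDataset, pop_a: str, pop_b: str
) -> float:
    """Multi-locus Weir-Cockerham theta between two populations."""
    pops = ds.population_indices()
    for p in (pop_a, pop_b):
        if p not in pops:
            raise ValueError(f"population '{p}' not present")
        if len(pops[p]) < 2:
            raise ValueError(f"population '{p}' has fewer than two individuals")
    return _theta_from_calls(ds.calls[pops[pop_a]], ds.calls[pops[pop_b]])


def _theta_from_calls(callsA: np.ndarray, callsB: np.ndarray) -> float:
    a, b, c, usable = wc_components(callsA, callsB)
    if not usable.any():
        raise ValueError("no jointly usable polymorphic loci")
    num = float(a[usable].sum())
    den = float((a + b + c)[usable].sum())
    if den == 0.0:
        raise ValueError("zero total variance across loci")
    return num / den


def fst_matrix(
    ds: GenotypeDataset, n_perm: int = 0, seed: int = 0
) -> PairwiseMatrix:
    """All pairwise thetas, optionally with permutation p-values.

    For a pair, individuals are pooled and labels reshuffled n_perm times;
    p = smoothed proportion of permuted thetas >= the observed one.
    """
    pops = ds.population_indices()
    labels = list(pops)
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    k = len(labels)
    values = np.zeros((k, k))
    pvals = np.full((k, k), np.nan) if n_perm else None
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            ca, cb = ds.calls[pops[labels[i]]], ds.calls[pops[labels[j]]]
            theta = _theta_from_calls(ca, cb)
            values[i, j] = values[j, i] = theta
            if n_perm:
                pooled = np.concatenate([ca, cb], axis=0)
                na = ca.shape[0]
                exceed = 0
                for _ in range(n_perm):
                    order = rng.permutation(pooled.shape[0])
                    t = _theta_from_calls(pooled[order[:na]], pooled[order[na:]])
                    if t >= theta:
                        exceed += 1
                p = (1.0 + exceed) / (n_perm + 1.0)
                pvals[i, j] = pvals[j, i] = p
    if pvals is not None:
        np.fill_diagonal(pvals, 1.0)
    return PairwiseMatrix(labels, values, pvals)


# ---------------------------------------------------------------------------
# Reynolds distance
# ---------------------------------------------------------------------------

def _pop_freqs(ds: GenotypeDataset, pop: str) -> np.ndarray:
    idx = ds.population_indices().get(pop)
    if idx is None:
        raise ValueError(f"population '{pop}' not present")
    calls = ds.calls[idx]
    nonmiss = calls != MISSING
    copies = 2.0 * nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(copies > 0, np.where(nonmiss, calls, 0).sum(axis=0) / copies, np.nan)


def reynolds_theta_locus(p_a: float, p_b: float) -> float:
    """Single-locus Reynolds coancestry ratio for a biallelic locus.

    theta_l = sum_u (p_Au - p_Bu)^2 / (2 (1 - sum_u p_Au p_Bu)) over the
    two alleles u.
    """
    num = (p_a - p_b) ** 2 + ((1 - p_a) - (1 - p_b)) ** 2
    den = 2.0 * (1.0 - (p_a * p_b + (1 - p_a) * (1 - p_b)))
    if den == 0.0:
        raise ZeroDivisionError("both populations fixed for the same allele")
    return num / den


def reynolds_distance(
    ds: GenotypeDataset,
    pop_a: str,
    pop_b: str,
    ratio_of_sums: bool = False,
    neg_log: bool = False,
) -> float:
    """Reynolds distance D_R between two populations.

    Default is the "unweighted" reading: the plain mean of per-locus
    coancestry ratios theta_l over loci with a non-zero denominator.
    ``ratio_of_sums=True`` pools numerators and denominators instead;
    ``neg_log=True`` returns -ln(1 - theta).
    """
    pa = _pop_freqs(ds, pop_a)
    pb = _pop_freqs(ds, pop_b)
    ok = np.isfinite(pa) & np.isfinite(pb)
    pa, pb = pa[ok], pb[ok]
    num = (pa - pb) ** 2 + ((1 - pa) - (1 - pb)) ** 2
    den = 2.0 * (1.0 - (pa * pb + (1 - pa) * (1 - pb)))
    usable = den > 0
    if not usable.any():
        raise ValueError("no shared polymorphic locus with non-zero denominator")
    if ratio_of_sums:
        theta = float(num[usable].sum() / den[usable].sum())
    else:
        theta = float((num[usable] / den[usable]).mean())
    if neg_log:
        return -float(np.log(1.0 - theta))
    return theta


def reynolds_matrix(ds: GenotypeDataset, **kwargs) -> PairwiseMatrix:
    pops = list(ds.population_indices())
    k = len(pops)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = reynolds_distance(ds, pops[i], pops[j], **kwargs)
            values[i, j] = values[j, i] = d
    return PairwiseMatrix(pops, values)


# ---------------------------------------------------------------------------
# neighbor-joining export
# ---------------------------------------------------------------------------

def nj_tree(dm: PairwiseMatrix) -> str:
    """Neighbor-joining tree in newick, via scikit-bio's agglomeration."""
    if len(dm.labels) < 3:
        raise ValueError("need at least three taxa")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    sk = DistanceMatrix(np.maximum(dm.values, 0.0), ids=dm.labels)
    tree = nj(sk)
    return str(tree).strip()
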