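"""Independent brute-force oracles used to check the main code paths.

These deliberately take different routes from the package implementation:
theta via the raw nested ANOVA on per-gene-copy allele indicators, AMOVA
sums of squares via average pairwise squared distances within clusters.
"""
from __future__ import annotations

import numpy as np

MISSING = -1


def anova_theta(callsA: np.ndarray, callsB: np.ndarray) -> float:
    """Weir-Cockerham theta via explicit nested ANOVA on allele indicators.

    Complete data only.  For each locus, gene copies carry a 0/1 allele
    indicator; mean squares for populations / individuals-within /
    copies-within are equated to their expectations and the component
    ratio summed over loci.
    """
    num = den = 0.0
    for j in range(callsA.shape[1]):
        groups = []
        for calls in (callsA, callsB):
            inds = []
            for d in calls[:, j]:
                if d == 0:
                    inds.append([0, 0])
                elif d == 1:
                    inds.append([0, 1])
                else:
                    inds.append([1, 1])
            groups.append(inds)
        nA, nB = len(groups[0]), len(groups[1])
        if nA < 2 or nB < 2:
            continue
        all_copies = [y for g in groups for ind in g for y in ind]
        ybar = np.mean(all_copies)
        if ybar in (0.0, 1.0):
            continue
        r = 2
        n_total = nA + nB
        ss_p = ss_i = ss_g = 0.0
        for g in groups:
            copies = [y for ind in g for y in ind]
            ybar_p = np.mean(copies)
            ss_p += len(copies) * (ybar_p - ybar) ** 2
            for ind in g:
                ybar_i = np.mean(ind)
                ss_i += 2 * (ybar_i - ybar_p) ** 2
                ss_g += sum((y - ybar_i) ** 2 for y in ind)
        ms_p = ss_p / (r - 1)
        ms_i = ss_i / (n_total - r)
        ms_g = ss_g / n_total
        nc = (n_total - (nA**2 + nB**2) / n_total) / (r - 1)
        sigma_g = ms_g
        sigma_i = (ms_i - ms_g) / 2.0
        sigma_p = (ms_p - ms_i) / (2.0 * nc)
        num += sigma_p
        den += sigma_p + sigma_i + sigma_g
    if den == 0.0:
        raise ValueError("no usable loci")
    return num / den


def _ss_pairwise(values: list[float]) -> float:
    """Sum of squares of a cluster via average pairwise squared distance."""
    n = len(values)
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += (values[i] - values[j]) ** 2
    return total / n


def amova_ss_bruteforce(
    calls: np.ndarray,
    pop_of_sample: np.ndarray,
    group_of_pop: np.ndarray | None = None,
) -> dict[str, float]:
    """AMOVA sums of squares via the pairwise-distance identity.

    For each locus, gene copies (missing calls contribute none) are
    clustered by individual / population / group; each stratum's SS is
    the difference between nested cluster SS computed as
    (1/n) * sum of pairwise squared differences.  Returns the per-stratum
    totals over loci.
    """
    n, L = calls.shape
    out = {"total": 0.0, "wi": 0.0, "ai": 0.0, "ap": 0.0, "ag": 0.0}
    for j in range(L):
        copies_of_ind: list[list[float]] = []
        for i in range(n):
            d = calls[i, j]
            if d == MISSING:
                copies_of_ind.append([])
            elif d == 0:
                copies_of_ind.append([0.0, 0.0])
            elif d == 1:
                copies_of_ind.append([0.0, 1.0])
            else:
                copies_of_ind.append([1.0, 1.0])
        all_copies = [y for c in copies_of_ind for y in c]
        ss_total = _ss_pairwise(all_copies)
        ss_wi = sum(_ss_pairwise(c) for c in copies_of_ind)
        ss_within_pop = 0.0
        pops = np.unique(pop_of_sample)
        for p in pops:
            rows = np.flatnonzero(pop_of_sample == p)
            ss_within_pop += _ss_pairwise(
                [y for i in rows for y in copies_of_ind[i]]
            )
        out["total"] += ss_total
        out["wi"] += ss_wi
        out["ai"] += ss_within_pop - ss_wi
        if group_of_pop is None:
            out["ap"] += ss_total - ss_within_pop
        else:
            ss_within_group = 0.0
            for g in np.unique(group_of_pop):
                member_pops = np.flatnonzero(group_of_pop == g)
                rows = np.flatnonzero(np.isin(pop_of_sample, member_pops))
                ss_within_group += _ss_pairwise(
                    [y for i in rows for y in copies_of_ind[i]]
                )
            out["ap"] += ss_within_group - ss_within_pop
            out["ag"] += ss_total - ss_within_group
    return out


def nj_three_taxon_lengths(d_ab: float, d_ac: float, d_bc: float) -> dict[str, float]:
    """Closed-form branch lengths of the unique unrooted 3-taxon tree."""
    return {
        "a": (d_ab + d_ac - d_bc) / 2.0,
        "b": (d_ab + d_bc - d_ac) / 2.0,
        "c": (d_ac + d_bc - d_ab) / 2.0,
    }
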