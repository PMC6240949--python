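"""Hierarchical analysis of molecular variance (AMOVA) on SNP genotypes.

Gene copies (two per individual, fewer where calls are missing) are the
observational units; the distance between two copies at a locus is the
squared allele difference, so sums of squares are ordinary deviation sums
on 0/1 allele values.  The design is fully nested: groups (continents) >
populations > individuals > gene copies.  Sums of squares are computed
locus by locus with pairwise-complete deletion of missing copies, variance
components are solved per locus from the expected-SS coefficients of the
unbalanced nested design, and components are summed over loci.  Phi
statistics are ratios of the summed components.

Reported degrees of freedom use the complete-design convention
(total = 2N - 1 gene copies).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

LEVELS_4 = (
    "Among groups",
    "Among populations within groups",
    "Among individuals within populations",
    "Within individuals",
)
LEVELS_3 = (
    "Among populations",
    "Among individuals within populations",
    "Within individuals",
)


@dataclass
class HierarchyAssignment:
    """Sample -> population and (optionally) population -> group labels."""

    populations: dict[str, str]
    groups: dict[str, str] | None = None

    @classmethod
    def from_dataset(
        cls, ds: GenotypeDataset, use_continent_groups: bool = False
    ) -> "HierarchyAssignment":
        pops = {s.sample_id: s.population for s in ds.samples}
        groups = None
        if use_continent_groups:
            groups = {}
            for s in ds.samples:
                prev = groups.get(s.population)
                if prev is not None and prev != s.continent:
                    raise ValueError(
                        f"population {s.population} spans several continents"
                    )
                groups[s.population] = s.continent
        return cls(pops, groups)

    def validate(self, ds: GenotypeDataset) -> None:
        for s in ds.samples:
            if s.sample_id not in self.populations:
                raise ValueError(f"sample {s.sample_id} lacks a population")
        if self.groups is not None:
            pops = set(self.populations.values())
            for p in pops:
                if p not in self.groups:
                    raise ValueError(f"population {p} lacks a group")


@dataclass
class AmovaResult:
    """Per-level d.f., SS, variance components, percentages plus Phi ratios."""

    levels: list[str]
    df: list[int]
    sum_of_squares: list[float]
    variance_components: list[float]
    percentages: list[float]
    phi: dict[str, float]
    pvalues: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        total_row = pd.DataFrame(
            {
                "Source of variation": ["Total"],
                "d.f.": [sum(self.df)],
                "Sum of squares": [sum(self.sum_of_squares)],
                "Variance components": [sum(self.variance_components)],
                "Percentage of variation": [100.0],
            }
        )
        body = pd.DataFrame(
            {
                "Source of variation": self.levels,
                "d.f.": self.df,
                "Sum of squares": self.sum_of_squares,
                "Variance components": self.variance_components,
                "Percentage of variation": self.percentages,
            }
        )
        return pd.concat([body, total_row], ignore_index=True)


# ---------------------------------------------------------------------------
# locus-wise sums of squares and components (vectorised over loci)
# ---------------------------------------------------------------------------

def _group_sums(values: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Sum rows of ``values`` (n x L) by integer label -> (k x L)."""
    out = np.zeros((k, values.shape[1]), dtype=np.float64)
    np.add.at(out, labels, values)
    return out


def _locus_components(
    calls: np.ndarray,
    pop_of_sample: np.ndarray,
    group_of_pop: np.ndarray | None,
) -> dict[str, np.ndarray]:
    """Per-locus SS and variance components for the nested design.

    Returns arrays over loci for each stratum; loci where a coefficient
    degenerates (e.g. every individual missing) yield zeros.
    """
    n, L = calls.shape
    P = int(pop_of_sample.max()) + 1
    nonmiss = calls != MISSING
    c = 2.0 * nonmiss  # copies per individual per locus
    x = np.where(nonmiss, calls, 0).astype(np.float64)  # allele-B copies

    N = c.sum(axis=0)
    I_cnt = nonmiss.sum(axis=0).astype(np.float64)
    T = x.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_tot = T / N

    het = (calls == 1).sum(axis=0).astype(np.float64)
    ss_wi = 0.5 * het

    Np = _group_sums(c, pop_of_sample, P)           # copies per pop
    Tp = _group_sums(x, pop_of_sample, P)           # allele-B copies per pop
    x2_half = _group_sums(x**2 / 2.0, pop_of_sample, P)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_ai = np.nansum(x2_half - np.where(Np > 0, Tp**2 / Np, 0.0), axis=0)

    A_p = _group_sums(c**2, pop_of_sample, P)       # sum of c_i^2 per pop

    res: dict[str, np.ndarray] = {"ss_wi": ss_wi, "ss_ai": ss_ai}

    with np.errstate(invalid="ignore", divide="ignore"):
        P_eff = (Np > 0).sum(axis=0).astype(np.float64)
        df_wi = N - I_cnt
        df_ai = I_cnt - P_eff

        sigma_wi = np.where(df_wi > 0, ss_wi / df_wi, 0.0)
        coef_ai = N - np.nansum(np.where(Np > 0, A_p / Np, 0.0), axis=0)
        sigma_ai = np.where(
            coef_ai > 0, (ss_ai - df_ai * sigma_wi) / coef_ai, 0.0
        )

        k1 = (c**2).sum(axis=0)
        sum_ApNp = np.nansum(np.where(Np > 0, A_p / Np, 0.0), axis=0)
        sum_Np2 = (Np**2).sum(axis=0)

        if group_of_pop is None:
            ss_ap = np.nansum(np.where(Np > 0, Tp**2 / Np, 0.0), axis=0) - np.where(
                N > 0, T**2 / N, 0.0
            )
            df_ap = P_eff - 1.0
            coef_ai_in_ap = sum_ApNp - np.where(N > 0, k1 / N, 0.0)
            coef_ap = N - np.where(N > 0, sum_Np2 / N, 0.0)
            sigma_ap = np.where(
                coef_ap > 0,
                (ss_ap - df_ap * sigma_wi - coef_ai_in_ap * sigma_ai) / coef_ap,
                0.0,
            )
            res.update(
                ss_ap=ss_ap, sigma_wi=sigma_wi, sigma_ai=sigma_ai, sigma_ap=sigma_ap
            )
            return res

        G = int(group_of_pop.max()) + 1
        Ng = np.zeros((G, L))
        Tg = np.zeros((G, L))
        B_g = np.zeros((G, L))  # sum of c_i^2 by group
        C_g = np.zeros((G, L))  # sum of Np^2 by group
        np.add.at(Ng, group_of_pop, Np)
        np.add.at(Tg, group_of_pop, Tp)
        np.add.at(B_g, group_of_pop, A_p)
        np.add.at(C_g, group_of_pop, Np**2)

        G_eff = (Ng > 0).sum(axis=0).astype(np.float64)
        ss_ap = np.nansum(np.where(Np > 0, Tp**2 / Np, 0.0), axis=0) - np.nansum(
            np.where(Ng > 0, Tg**2 / Ng, 0.0), axis=0
        )
        ss_ag = np.nansum(np.where(Ng > 0, Tg**2 / Ng, 0.0), axis=0) - np.where(
            N > 0, T**2 / N, 0.0
        )
        df_ap = P_eff - G_eff
        df_ag = G_eff - 1.0

        sum_BgNg = np.nansum(np.where(Ng > 0, B_g / Ng, 0.0), axis=0)
        sum_CgNg = np.nansum(np.where(Ng > 0, C_g / Ng, 0.0), axis=0)
        sum_Ng2 = (Ng**2).sum(axis=0)

        coef_ai_in_ap = sum_ApNp - sum_BgNg
        coef_ap_in_ap = N - sum_CgNg
        sigma_ap = np.where(
            coef_ap_in_ap > 0,
            (ss_ap - df_ap * sigma_wi - coef_ai_in_ap * sigma_ai) / coef_ap_in_ap,
            0.0,
        )
        coef_ai_in_ag = sum_BgNg - np.where(N > 0, k1 / N, 0.0)
        coef_ap_in_ag = sum_CgNg - np.where(N > 0, sum_Np2 / N, 0.0)
        coef_ag = N - np.where(N > 0, sum_Ng2 / N, 0.0)
        sigma_ag = np.where(
            coef_ag > 0,
            (ss_ag - df_ag * sigma_wi - coef_ai_in_ag * sigma_ai
             - coef_ap_in_ag * sigma_ap) / coef_ag,
            0.0,
        )
        res.update(
            ss_ap=ss_ap, ss_ag=ss_ag,
            sigma_wi=sigma_wi, sigma_ai=sigma_ai,
            sigma_ap=sigma_ap, sigma_ag=sigma_ag,
        )
        return res


def _encode(hierarchy: HierarchyAssignment, ds: GenotypeDataset, levels: int):
    sample_pops = [hierarchy.populations[s.sample_id] for s in ds.samples]
    pop_labels = list(dict.fromkeys(sample_pops))
    pop_index = {p: i for i, p in enumerate(pop_labels)}
    pop_of_sample = np.array([pop_index[p] for p in sample_pops], dtype=np.intp)
    group_of_pop = None
    if levels == 4:
        if hierarchy.groups is None:
            raise ValueError("4-level AMOVA needs a population -> group mapping")
        group_labels = list(dict.fromkeys(hierarchy.groups[p] for p in pop_labels))
        gidx = {g: i for i, g in enumerate(group_labels)}
        group_of_pop = np.array(
            [gidx[hierarchy.groups[p]] for p in pop_labels], dtype=np.intp
        )
    return pop_of_sample, group_of_pop, pop_labels


def amova(
    ds: GenotypeDataset,
    hierarchy: HierarchyAssignment | None = None,
    levels: int = 3,
    n_perm: int = 0,
    seed: int = 0,
) -> AmovaResult:
    """Run the 3- or 4-level AMOVA; optionally attach permutation p-values.

    Percentages use the sum of components as the denominator, with negative
    components retained (the convention of the standard report tables, which
    does not re-normalise when the among-groups level is added).
    """
    if levels not in (3, 4):
        raise ValueError("levels must be 3 or 4")
    hierarchy = hierarchy or HierarchyAssignment.from_dataset(
        ds, use_continent_groups=(levels == 4)
    )
    hierarchy.validate(ds)
    pop_of_sample, group_of_pop, pop_labels = _encode(hierarchy, ds, levels)
    # a single population is a valid degenerate design: the among-populations
    # component is exactly zero
    sizes = np.bincount(pop_of_sample)
    for p, s in zip(pop_labels, sizes):
        if s < 2:
            raise ValueError(f"population {p} has a single individual")

    comp = _locus_components(ds.calls, pop_of_sample, group_of_pop)
    n = ds.n_samples
    P = len(pop_labels)

    ss_wi = float(comp["ss_wi"].sum())
    ss_ai = float(comp["ss_ai"].sum())
    ss_ap = float(comp["ss_ap"].sum())
    s_wi = float(comp["sigma_wi"].sum())
    s_ai = float(comp["sigma_ai"].sum())
    s_ap = float(comp["sigma_ap"].sum())

    if levels == 3:
        sigmas = [s_ap, s_ai, s_wi]
        total = sum(sigmas)
        if total == 0.0:
            raise ValueError("zero total variance")
        phi = {
            "F_ST": s_ap / total,
            "F_IS": _ratio(s_ai, s_ai + s_wi),
            "F_IT": (s_ap + s_ai) / total,
        }
        result = AmovaResult(
            levels=list(LEVELS_3),
            df=[P - 1, n - P, n],
            sum_of_squares=[ss_ap, ss_ai, ss_wi],
            variance_components=sigmas,
            percentages=[100.0 * s / total for s in sigmas],
            phi=phi,
        )
    else:
        G = int(group_of_pop.max()) + 1
        if G < 2:
            raise ValueError("4-level AMOVA needs at least two groups")
        ss_ag = float(comp["ss_ag"].sum())
        s_ag = float(comp["sigma_ag"].sum())
        sigmas = [s_ag, s_ap, s_ai, s_wi]
        total = sum(sigmas)
        if total == 0.0:
            raise ValueError("zero total variance")
        phi = {
            "F_CT": s_ag / total,
            "F_SC": _ratio(s_ap, s_ap + s_ai + s_wi),
            "F_ST": (s_ag + s_ap) / total,
            "F_IS": _ratio(s_ai, s_ai + s_wi),
            "F_IT": (s_ag + s_ap + s_ai) / total,
        }
        result = AmovaResult(
            levels=list(LEVELS_4),
            df=[G - 1, P - G, n - P, n],
            sum_of_squares=[ss_ag, ss_ap, ss_ai, ss_wi],
            variance_components=sigmas,
            percentages=[100.0 * s / total for s in sigmas],
            phi=phi,
        )
    if n_perm:
        result.pvalues = amova_significance(
            ds, hierarchy, levels=levels, n_perm=n_perm, seed=seed
        )
    return result


def _ratio(num: float, den: float) -> float:
    """Component ratio; NaN when the denominator stratum has no variance."""
    return num / den if den != 0.0 else float("nan")


def phi_statistics(components: list[float]) -> dict[str, float]:
    """Phi ratios from variance components ordered top level first."""
    total = sum(components)
    if total == 0:
        raise ValueError("zero total variance")
    if len(components) == 3:
        s_ap, s_ai, s_wi = components
        return {
            "F_ST": s_ap / total,
            "F_IS": _ratio(s_ai, s_ai + s_wi),
            "F_IT": (s_ap + s_ai) / total,
        }
    if len(components) == 4:
        s_ag, s_ap, s_ai, s_wi = components
        return {
            "F_CT": s_ag / total,
            "F_SC": _ratio(s_ap, s_ap + s_ai + s_wi),
            "F_ST": (s_ag + s_ap) / total,
            "F_IS": _ratio(s_ai, s_ai + s_wi),
            "F_IT": (s_ag + s_ap + s_ai) / total,
        }
    raise ValueError("components must have length 3 or 4")


def amova_significance(
    ds: GenotypeDataset,
    hierarchy: HierarchyAssignment | None = None,
    levels: int = 3,
    n_perm: int = 99,
    seed: int = 0,
) -> dict[str, float]:
    """Level-appropriate permutation p-values for the Phi statistics.

    among populations: individuals are permuted among populations (within
    groups in the 4-level design, testing F_SC); among groups: whole
    populations are permuted among groups (F_CT); within individuals: gene
    copies are permuted among individuals within populations (F_IS).
    """
    if n_perm < 1:
        return {}
    hierarchy = hierarchy or HierarchyAssignment.from_dataset(
        ds, use_continent_groups=(levels == 4)
    )
    pop_of_sample, group_of_pop, pop_labels = _encode(hierarchy, ds, levels)
    comp = _locus_components(ds.calls, pop_of_sample, group_of_pop)
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}

    def _phis(c: dict[str, np.ndarray]) -> dict[str, float]:
        s_wi = float(c["sigma_wi"].sum())
        s_ai = float(c["sigma_ai"].sum())
        s_ap = float(c["sigma_ap"].sum())
        if group_of_pop is None:
            tot = s_ap + s_ai + s_wi
            return {"F_ST": s_ap / tot, "F_IS": s_ai / (s_ai + s_wi)}
        s_ag = float(c["sigma_ag"].sum())
        tot = s_ag + s_ap + s_ai + s_wi
        return {
            "F_CT": s_ag / tot,
            "F_SC": s_ap / (s_ap + s_ai + s_wi),
            "F_IS": s_ai / (s_ai + s_wi),
        }

    obs = _phis(comp)

    # individuals among populations (within groups when grouped)
    stat = "F_ST" if group_of_pop is None else "F_SC"
    exceed = 0
    for _ in range(n_perm):
        if group_of_pop is None:
            perm = rng.permutation(pop_of_sample)
        else:
            perm = pop_of_sample.copy()
            sample_group = group_of_pop[pop_of_sample]
            for g in np.unique(group_of_pop):
                rows = np.flatnonzero(sample_group == g)
                perm[rows] = pop_of_sample[rows[rng.permutation(len(rows))]]
        c = _locus_components(ds.calls, perm, group_of_pop)
        if _phis(c)[stat] >= obs[stat]:
            exceed += 1
    out[stat] = (1.0 + exceed) / (n_perm + 1.0)

    if group_of_pop is not None:
        exceed = 0
        for _ in range(n_perm):
            gperm = group_of_pop[rng.permutation(len(group_of_pop))]
            c = _locus_components(ds.calls, pop_of_sample, gperm)
            if _phis(c)["F_CT"] >= obs["F_CT"]:
                exceed += 1
        out["F_CT"] = (1.0 + exceed) / (n_perm + 1.0)

    # gene copies among individuals within populations (F_IS)
    if (ds.calls != MISSING).all():
        exceed = 0
        n = ds.n_samples
        copies = np.concatenate(
            [(ds.calls == 2), (ds.calls >= 1)], axis=0
        ).astype(np.int8)
        for _ in range(n_perm):
            perm_calls = np.empty_like(ds.calls)
            for p in np.unique(pop_of_sample):
                rows = np.flatnonzero(pop_of_sample == p)
                sub = copies[np.concatenate([rows, rows + n])]
                sub = rng.permuted(sub, axis=0)
                half = len(rows)
                perm_calls[rows] = sub[:half] + sub[half:]
            c = _locus_components(perm_calls, pop_of_sample, group_of_pop)
            if _phis(c)["F_IS"] >= obs["F_IS"]:
                exceed += 1
        out["F_IS"] = (1.0 + exceed) / (n_perm + 1.0)
    return out
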