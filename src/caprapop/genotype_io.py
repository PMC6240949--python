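"""Genotype data model and PLINK PED/MAP text input/output.

The central container is :class:`GenotypeDataset`: an ordered sample list, an
ordered variant list, and a samples x variants matrix of allele-B dosages
(0, 1, 2, or :data:`MISSING`).  Allele B is the lexicographically larger of
the two alleles observed at a locus, which makes the coding deterministic and
independent of sample order.  All frequency-symmetric statistics downstream
(expected heterozygosity, F_ST, r^2) are invariant under swapping the coding,
see :func:`flip_coding`.

Optionally a dataset carries phased haplotypes, stored as a
``(n_samples, 2, n_variants)`` binary array whose per-locus sum equals the
dosage wherever the call is non-missing.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid call in the dosage matrix.
MISSING: int = -1

#: Placeholder used for the unobservable second allele of a monomorphic locus.
UNSEEN_ALLELE: str = "N"


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic marker with its map position (1-based base pairs)."""

    variant_id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(
                f"variant {self.variant_id}: position_bp must be >= 1, "
                f"got {self.position_bp}"
            )
        if self.allele_a == self.allele_b:
            raise ValueError(f"variant {self.variant_id}: alleles must differ")


@dataclass(frozen=True)
class SampleRecord:
    """One individual with its population label and optional geography."""

    sample_id: str
    population: str
    continent: str = ""
    country: str = ""
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if not self.population:
            raise ValueError(f"sample {self.sample_id}: population must be non-empty")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"sample {self.sample_id}: latitude out of range")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"sample {self.sample_id}: longitude out of range")


@dataclass
class GenotypeDataset:
    """Samples x variants allele-B dosage matrix with metadata.

    ``calls[i, j]`` is the number of copies of ``variants[j].allele_b``
    carried by ``samples[i]`` (0/1/2) or :data:`MISSING`.
    """

    samples: list[SampleRecord]
    variants: list[VariantRecord]
    calls: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (len(self.samples), 2, len(self.variants)):
                raise ValueError("haplotypes shape must be (n_samples, 2, n_variants)")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def populations(self) -> np.ndarray:
        """Population label per sample, as an object array."""
        return np.array([s.population for s in self.samples], dtype=object)

    def population_indices(self) -> dict[str, np.ndarray]:
        """Map population code -> sample row indices, in first-seen order."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            out.setdefault(s.population, []).append(i)
        return {k: np.asarray(v, dtype=np.intp) for k, v in out.items()}

    def mapped_variant_mask(self) -> np.ndarray:
        """True for variants with a usable map position (chromosome != '0')."""
        return np.array([v.chromosome != "0" for v in self.variants], dtype=bool)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check the container invariants; raise ValueError on violation."""
        ids = self.sample_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id")
        vids = self.variant_ids
        if len(set(vids)) != len(vids):
            raise ValueError("duplicate variant_id")
        ok = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not ok.all():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")
        if self.haplotypes is not None:
            dose = self.haplotypes.sum(axis=1)
            nonmiss = self.calls != MISSING
            if not np.array_equal(dose[nonmiss], self.calls[nonmiss]):
                raise ValueError("haplotype sums disagree with non-missing calls")

    # -- subsetting --------------------------------------------------------

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index, dtype=np.intp)
        haps = self.haplotypes[index] if self.haplotypes is not None else None
        return GenotypeDataset(
            [self.samples[i] for i in index], list(self.variants),
            self.calls[index], haps,
        )

    def subset_variants(self, index: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index, dtype=np.intp)
        haps = self.haplotypes[:, :, index] if self.haplotypes is not None else None
        return GenotypeDataset(
            list(self.samples), [self.variants[i] for i in index],
            self.calls[:, index], haps,
        )

    def select_populations(self, populations: Iterable[str]) -> "GenotypeDataset":
        keep = set(populations)
        idx = [i for i, s in enumerate(self.samples) if s.population in keep]
        return self.subset_samples(idx)

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# PLINK text format
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read a PLINK PED/MAP text pair into a :class:`GenotypeDataset`.

    The PED family column is taken as the population label; father/mother/
    sex/phenotype columns are ignored (relatedness is established from the
    genotypes themselves, not the pedigree).  ``0`` allele tokens denote
    missing; a half-missing pair is treated as fully missing.  Allele B is
    the lexicographically larger observed allele.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    variants_raw: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 MAP columns")
            chrom, vid, _cm, pos = tok[0], tok[1], tok[2], tok[3]
            variants_raw.append((vid, chrom, int(pos)))
    m = len(variants_raw)

    fams: list[str] = []
    iids: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(tok)}"
                )
            fams.append(tok[0])
            iids.append(tok[1])
            rows.append(np.array(tok[6:], dtype=object).reshape(m, 2))

    geno = (
        np.stack(rows, axis=0) if rows else np.empty((0, m, 2), dtype=object)
    )  # (n, m, 2) allele tokens

    variants: list[VariantRecord] = []
    calls = np.full((len(rows), m), MISSING, dtype=np.int8)
    for j, (vid, chrom, pos) in enumerate(variants_raw):
        col = geno[:, j, :] if len(rows) else np.empty((0, 2), dtype=object)
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise ValueError(
                f"variant {vid}: more than two alleles observed: {observed}"
            )
        if len(observed) == 2:
            a, b = observed
        elif len(observed) == 1:
            a = observed[0]
            b = UNSEEN_ALLELE if a != UNSEEN_ALLELE else UNSEEN_ALLELE + "2"
        else:
            a, b = "A", "B"
        variants.append(VariantRecord(vid, chrom, pos, a, b))
        if len(rows):
            nonmiss = (col[:, 0] != "0") & (col[:, 1] != "0")
            dose = (col[:, 0] == b).astype(np.int8) + (col[:, 1] == b).astype(np.int8)
            calls[:, j] = np.where(nonmiss, dose, MISSING)

    samples = [
        SampleRecord(sample_id=iid, population=fam if fam else "0")
        for fam, iid in zip(fams, iids)
    ]
    ds = GenotypeDataset(samples, variants, calls)
    ds.validate()
    return ds


def write_plink_text(ds: GenotypeDataset, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns the two paths.

    Re-reading with :func:`read_plink_text` reproduces the calls exactly and,
    for polymorphic loci, the allele records too.
    """
    if ds.n_samples == 0:
        raise ValueError("refusing to write an empty dataset")
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for v in ds.variants:
            fh.write(f"{v.chromosome}\t{v.variant_id}\t0\t{v.position_bp}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(ds.samples):
            fields = [s.population or "0", s.sample_id, "0", "0", "0", "-9"]
            row = ds.calls[i]
            for j, v in enumerate(ds.variants):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [v.allele_a, v.allele_a]
                elif d == 1:
                    fields += [v.allele_a, v.allele_b]
                else:
                    fields += [v.allele_b, v.allele_b]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def attach_metadata(
    ds: GenotypeDataset, table_path: str | Path
) -> tuple[GenotypeDataset, list[str]]:
    """Join a tab-separated metadata table onto the samples.

    The table must have a header with at least ``sample_id`` and
    ``population`` columns; ``continent``, ``country``, ``latitude`` and
    ``longitude`` are picked up when present.  Returns the updated dataset
    and the list of sample ids absent from the table (their records are
    kept unchanged).  Duplicate ``sample_id`` rows are an error.
    """
    tab = pd.read_csv(table_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "population"):
        if col not in tab.columns:
            raise ValueError(f"metadata table lacks required column '{col}'")
    if tab["sample_id"].duplicated().any():
        dupes = tab.loc[tab["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id rows in metadata: {dupes}")
    tab = tab.set_index("sample_id")

    def _get(row: pd.Series, col: str, default):
        if col in row.index and pd.notna(row[col]):
            return row[col]
        return default

    new_samples: list[SampleRecord] = []
    unmatched: list[str] = []
    for s in ds.samples:
        if s.sample_id not in tab.index:
            unmatched.append(s.sample_id)
            new_samples.append(s)
            continue
        row = tab.loc[s.sample_id]
        lat = _get(row, "latitude", None)
        lon = _get(row, "longitude", None)
        new_samples.append(
            SampleRecord(
                sample_id=s.sample_id,
                population=str(row["population"]),
                continent=str(_get(row, "continent", "")),
                country=str(_get(row, "country", "")),
                latitude=float(lat) if lat is not None else None,
                longitude=float(lon) if lon is not None else None,
            )
        )
    out = GenotypeDataset(new_samples, list(ds.variants), ds.calls, ds.haplotypes)
    return out, unmatched


def write_metadata(ds: GenotypeDataset, path: str | Path) -> Path:
    """Write the samples' metadata as the tab-separated table the reader expects."""
    path = Path(path)
    rows = [
        {
            "sample_id": s.sample_id,
            "population": s.population,
            "continent": s.continent,
            "country": s.country,
            "latitude": s.latitude,
            "longitude": s.longitude,
        }
        for s in ds.samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def flip_coding(ds: GenotypeDataset, variant_index: Sequence[int]) -> GenotypeDataset:
    """Swap which allele is counted at the given variants (dosage d -> 2-d).

    Frequency-symmetric statistics are invariant under this recoding; the
    helper exists so tests can assert exactly that.
    """
    idx = np.asarray(variant_index, dtype=np.intp)
    calls = ds.calls.copy()
    sub = calls[:, idx]
    nonmiss = sub != MISSING
    sub[nonmiss] = 2 - sub[nonmiss]
    calls[:, idx] = sub
    variants = list(ds.variants)
    for j in idx:
        v = variants[j]
        variants[j] = replace(v, allele_a=v.allele_b, allele_b=v.allele_a)
    haps = None
    if ds.haplotypes is not None:
        haps = ds.haplotypes.copy()
        haps[:, :, idx] = 1 - haps[:, :, idx]
    return GenotypeDataset(list(ds.samples), variants, calls, haps)
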