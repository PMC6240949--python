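"""IBS kinship matrices and classical (Torgerson) multidimensional scaling.

Kinship between two individuals is their IBS similarity (dosage agreement
over jointly non-missing loci), with unit self-kinship.  Individual-level
MDS embeds the distance d = 1 - kinship; population-level MDS embeds the
coancestry-style distance d_pq = (s_pp + s_qq)/2 - s_pq where s is the mean
kinship over all sample pairs of the two populations (self-pairs included
on the diagonal blocks), which collapses identical populations onto a
single point and reduces to the individual embedding when every population
is a singleton.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset
from .qc import pairwise_ibs


@dataclass
class MdsResult:
    labels: list[str]
    coordinates: np.ndarray       # points x dimensions
    eigenvalues: np.ndarray       # per retained dimension, decreasing
    variance_fraction: np.ndarray  # share of the positive-eigenvalue total

    def to_frame(self) -> pd.DataFrame:
        cols = {f"dim{i + 1}": self.coordinates[:, i]
                for i in range(self.coordinates.shape[1])}
        return pd.DataFrame({"label": self.labels, **cols})


def ibs_kinship(ds: GenotypeDataset) -> np.ndarray:
    """Pairwise IBS similarity with the diagonal fixed at 1."""
    k = pairwise_ibs(ds)
    np.fill_diagonal(k, 1.0)
    return k


def classical_mds(
    matrix: np.ndarray,
    k: int,
    labels: list[str] | None = None,
    is_similarity: bool = True,
) -> MdsResult:
    """Torgerson scaling of a similarity (d = 1 - s) or distance matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue), restricted to
    positive eigenvalues; each axis's sign is fixed so its largest-magnitude
    loading is positive, making the output reproducible bit for bit.
    If fewer than k positive eigenvalues exist the result is truncated.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError("input must be symmetric")
    if k < 1:
        raise ValueError("k must be >= 1")
    d = (1.0 - m) if is_similarity else m.copy()
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12
    n_pos = int(pos.sum())
    keep = min(k, n_pos)
    coords = evecs[:, :keep] * np.sqrt(evals[:keep])
    for axis in range(keep):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    pos_total = evals[pos].sum() if n_pos else 1.0
    labels = labels if labels is not None else [str(i) for i in range(n)]
    return MdsResult(
        labels=list(labels),
        coordinates=coords,
        eigenvalues=evals[:keep],
        variance_fraction=evals[:keep] / pos_total,
    )


def individual_mds(ds: GenotypeDataset, k: int = 3) -> MdsResult:
    return classical_mds(ibs_kinship(ds), k, labels=ds.sample_ids)


def population_kinship(ds: GenotypeDataset) -> tuple[list[str], np.ndarray]:
    """Mean kinship between (and within) populations, self-pairs included."""
    kin = ibs_kinship(ds)
    pops = ds.population_indices()
    labels = list(pops)
    out = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j_, b in enumerate(labels[i:], start=i):
            block = kin[np.ix_(pops[a], pops[b])]
            out[i, j_] = out[j_, i] = float(block.mean())
    return labels, out


def population_mds(ds: GenotypeDataset, k: int = 3) -> MdsResult:
    """Classical MDS of populations from mean between-population kinship."""
    pops = ds.population_indices()
    if len(pops) < 3:
        raise ValueError("need at least three populations")
    labels, s = population_kinship(ds)
    diag = np.diag(s)
    d = (diag[:, None] + diag[None, :]) / 2.0 - s
    d = np.maximum(d, 0.0)
    return classical_mds(d, k, labels=labels, is_similarity=False)


def embedding_stress(d_input: np.ndarray, result: MdsResult) -> float:
    """Root-mean-square difference between input and embedded distances."""
    from scipy.spatial.distance import squareform, pdist

    emb = squareform(pdist(result.coordinates))
    diff = d_input - emb
    iu = np.triu_indices_from(diff, k=1)
    return float(np.sqrt(np.mean(diff[iu] ** 2)))
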