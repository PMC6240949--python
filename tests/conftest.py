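import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from caprapop.genotype_io import GenotypeDataset, SampleRecord, VariantRecord
from caprapop.simdata import SimConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(
    calls,
    populations=None,
    continents=None,
    chromosomes=None,
    positions=None,
    haplotypes=None,
):
    """Small handcrafted dataset from a dosage matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    populations = populations or ["P1"] * n
    continents = continents or ["C1"] * n
    chromosomes = chromosomes or ["1"] * m
    positions = positions or [1000 * (j + 1) for j in range(m)]
    samples = [
        SampleRecord(f"S{i + 1}", populations[i], continents[i], "X")
        for i in range(n)
    ]
    variants = [
        VariantRecord(f"v{j + 1}", chromosomes[j], positions[j], "A", "G")
        for j in range(m)
    ]
    return GenotypeDataset(samples, variants, calls, haplotypes)


@pytest.fixture
def tiny_ds():
    return make_dataset(
        [[0, 1, 2], [1, 1, 0], [2, 0, 1]],
        populations=["P1", "P1", "P2"],
    )


@pytest.fixture(scope="session")
def structured_ds():
    """Hierarchical dataset reused by structure-sensitive tests."""
    cfg = SimConfig(
        seed=11, n_groups=2, pops_per_group=2, inds_per_pop=20,
        n_chromosomes=2, snps_per_chromosome=400,
        f_ct=0.08, f_st_within=0.10, f_is=0.0,
    )
    return simulate_dataset(cfg)
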