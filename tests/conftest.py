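import numpy as np
import pandas as pd
import pytest

from sweepscan.dataset import MISSING, SNP_COLUMNS, GenotypeDataset


def build_dataset(dosage_columns, pop_sizes=(2, 2), chromosomes=None,
                  positions=None, alleles=None):
    """Handmade dataset: dosage_columns is a list of per-SNP dosage lists
    (sample-major once transposed), pop_sizes splits the samples in order."""
    dosages = np.array(dosage_columns, dtype=np.int8).T
    n_samples, n_snps = dosages.shape
    assert sum(pop_sizes) == n_samples
    chromosomes = chromosomes or [1] * n_snps
    positions = positions or [1000 * (i + 1) for i in range(n_snps)]
    alleles = alleles or [("A", "G")] * n_snps
    snps = pd.DataFrame(
        [(f"rs{i+1}", chromosomes[i], positions[i], *alleles[i]) for i in range(n_snps)],
        columns=list(SNP_COLUMNS),
    )
    samples = [f"s{i+1}" for i in range(n_samples)]
    pops = {}
    k = 0
    for label, size in zip(("popA", "popB"), pop_sizes):
        for _ in range(size):
            pops[samples[k]] = label
            k += 1
    ds = GenotypeDataset(snps, samples, pops, dosages)
    ds.sort_map()
    ds.validate()
    return ds


@pytest.fixture
def tiny_dataset():
    """4+4 samples, 5 SNPs on two chromosomes, one missing call."""
    return build_dataset(
        [
            [0, 1, 1, 2, 0, 0, 1, 2],
            [2, 2, 1, 2, 0, 1, 0, 0],
            [0, 0, 0, 0, 2, 2, 2, 2],
            [1, 1, 0, MISSING, 1, 0, 1, 1],
            [0, 0, 0, 0, 0, 0, 0, 0],
        ],
        pop_sizes=(4, 4),
        chromosomes=[1, 1, 1, 2, 2],
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated two-population dataset shared across tests."""
    from sweepscan.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(seed=42, n_chromosomes=3, snps_per_chromosome=300,
                    n_samples=(60, 70))
    return simulate_dataset(cfg)
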