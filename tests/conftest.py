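import numpy as np
import pytest

from adaptscan import mmgwa, simdata
from adaptscan.datatypes import GenotypeMatrix


@pytest.fixture(scope="session")
def small_scenario():
    """102 accessions x 4000 sites, 3 populations, no causal loci."""
    cfg = simdata.ScenarioConfig(
        n_pops=3, n_acc_per_pop=34, n_sites=4000, seed=11
    )
    gm, pops, causal, freqs = simdata.simulate_genotypes(cfg)
    return cfg, gm, pops, causal, freqs


@pytest.fixture(scope="session")
def causal_scenario():
    """102 accessions x 4000 sites with 5 near-fixed pop3 causal loci."""
    cfg = simdata.ScenarioConfig(
        n_pops=3,
        n_acc_per_pop=34,
        n_sites=4000,
        n_causal=5,
        causal_freq_split=(0.02, 0.02, 0.98),
        seed=13,
    )
    gm, pops, causal, freqs = simdata.simulate_genotypes(cfg)
    return cfg, gm, pops, causal, freqs


@pytest.fixture(scope="session")
def small_kinship(small_scenario):
    _, gm, _, _, _ = small_scenario
    return mmgwa.kinship_matrix(gm).values


def toy_matrix(dosage, chrom=None, pos=None, prefix="a"):
    """Build a GenotypeMatrix from a (n_acc, n_sites) int list."""
    d = np.asarray(dosage, dtype=np.int8)
    n, m = d.shape
    chrom = np.array(chrom if chrom is not None else ["chr1"] * m, dtype=object)
    pos = np.asarray(pos if pos is not None else np.arange(1, m + 1))
    return GenotypeMatrix(d, [f"{prefix}{i}" for i in range(n)], chrom, pos)
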