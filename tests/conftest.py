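import numpy as np
import pytest

from metapepiter.simdata import SimParams, simulate_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def small_sim():
    """A compact community used by the workflow tests: 3 genomes x 30 genes,
    400 traces, 150 spectra."""
    params = SimParams(
        n_genomes=3, genes_per_genome=30, n_traces=400, n_spectra=150, rng_seed=1
    )
    return simulate_benchmark(params)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))
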