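import numpy as np
import pytest

from threshfdr import KinshipMatrix, simulate_genotypes, simulate_trait


@pytest.fixture(scope="session")
def small_panel():
    """50 genotypes x 200 SNPs with block LD, shared across read-only tests."""
    return simulate_genotypes(50, 200, seed=11)


@pytest.fixture(scope="session")
def trait_panel():
    """Mid-size panel with a simulated trait and its truth set."""
    G = simulate_genotypes(150, 600, seed=21)
    table, truth = simulate_trait(G, pi0=0.98, h2=0.6, seed=22)
    return G, table, truth


@pytest.fixture
def identity_kinship():
    def make(n):
        return KinshipMatrix(np.eye(n))

    return make
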