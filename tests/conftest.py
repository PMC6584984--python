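import numpy as np
import pytest

from ssgwas.simulate import SimConfig, make_dataset
from ssgwas.ssgblup_core import VarianceComponents


@pytest.fixture(scope="session")
def vc():
    return VarianceComponents(sigma_u2=0.48, sigma_e2=0.42, sigma_pe2=0.10)


@pytest.fixture(scope="session")
def small_dataset():
    """180 animals over 2 generations, 54 genotyped sires-first, 150 markers."""
    return make_dataset(SimConfig(n_founders=60, n_generations=2, n_markers=150, seed=2))


@pytest.fixture(scope="session")
def full_geno_dataset():
    """Fully genotyped: 120 animals, 300 markers (for equivalence checks)."""
    return make_dataset(
        SimConfig(
            n_founders=40,
            n_generations=2,
            n_markers=300,
            seed=4,
            genotyping_rule="all",
            qtl=((25, 0.25),),
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
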