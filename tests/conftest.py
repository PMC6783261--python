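import numpy as np
import pytest

from tedyn.params import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """A 4-locus toy scenario (2 chromosomes x 2 loci), N=2."""
    return SimParams(pop_size=2, n_chromosomes=2, loci_per_chromosome=2,
                     founder_copies=2, burn_in_generations=0,
                     total_generations=1, sex_interval=0, u=0.2, v=0.1,
                     a=0.05, b=0.0, sample_every=1, n_replicates=1, seed=0)


@pytest.fixture
def small_params():
    """A small but non-trivial scenario for fast end-to-end runs."""
    return SimParams(pop_size=200, n_chromosomes=4, loci_per_chromosome=25,
                     founder_copies=20, burn_in_generations=5,
                     total_generations=60, sex_interval=20, u=5e-3, v=5e-3,
                     a=1e-3, b=0.0, sample_every=10, n_replicates=3, seed=7)
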