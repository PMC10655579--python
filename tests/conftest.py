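import numpy as np
import pytest

from pairbond import Genotype, NoiseSpec, Population, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """Small deterministic-friendly config: no noise, no deceit, no costs."""
    return SimConfig(N=4, iterations=10, noise=NoiseSpec("none", 0.0),
                     c_cou=0.0, c_div=0.0, c_dec=0.0, seed=7)


def make_pair_population(geno_a: Genotype, geno_b: Genotype,
                         bonded: bool = True) -> Population:
    """Two-agent population, partnered (bonded or courting), emotions at base."""
    pop = Population.from_genotypes([geno_a, geno_b])
    pop.partner[:] = [1, 0]
    pop.bonded_flag[:] = bonded
    return pop


@pytest.fixture
def pair_factory():
    return make_pair_population
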