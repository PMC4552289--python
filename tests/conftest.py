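import numpy as np
import pytest

from poolsel import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return synth.SimulationConfig(
        n_genes=5, length_range=(100, 130), seed=11,
        fixed_syn_rate=0.004, fixed_nonsyn_rate=0.004, poly_rate=0.003,
    )


@pytest.fixture
def small_dataset(small_config):
    ancestral = synth.generate_ancestral_cds(small_config)
    pool_a, pool_b, truth = synth.evolve_species_pair(ancestral, small_config)
    return ancestral, pool_a, pool_b, truth


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
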