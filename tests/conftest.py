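import numpy as np
import pytest

from biastruct.io_formats import build_config
from biastruct.synthdata import (
    assemble_study_population,
    gen_founder_frequencies,
    sample_founder_genotypes,
)


@pytest.fixture(scope="session")
def small_freqs():
    """Founder frequencies at a desk scale adequate for moment checks."""
    return gen_founder_frequencies(2_000, 0.1, seed=11)


@pytest.fixture(scope="session")
def small_founders(small_freqs):
    return sample_founder_genotypes(small_freqs, 30, seed=12)


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature study population: quick to simulate, same structure."""
    return build_config(
        {
            "n_loci": 800,
            "n_founders": 15,
            "unmixed_pool": 30,
            "n_admixed": 60,
            "n_generations": 4,
            "seed": 5,
        }
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    freqs = gen_founder_frequencies(tiny_config.n_loci, tiny_config.fst, seed=21)
    return assemble_study_population(freqs, tiny_config, seed=22)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
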