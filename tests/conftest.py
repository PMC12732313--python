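import numpy as np
import pytest

from fkpkit.simulate import SimConfig, gen_domain_families, gen_hit_table


@pytest.fixture(scope="session")
def small_families():
    """Noiseless 15-protein synthetic dataset shared across tests."""
    cfg = SimConfig(seed=11)
    proteins, truth = gen_domain_families(cfg)
    hits = gen_hit_table(proteins, truth, score_noise_sd=0.0, seed=11)
    return cfg, proteins, truth, hits


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
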