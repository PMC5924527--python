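import random

import pytest

from genomeprep import synthetic_data as sd


@pytest.fixture(scope="session")
def sim_genome():
    """Small error-free study genome shared across modules (50 kb, seed 11)."""
    cfg = sd.SimConfig(seed=11, genome_size=50_000)
    return cfg, sd.make_genome(cfg)


@pytest.fixture()
def rng():
    return random.Random(1234)
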