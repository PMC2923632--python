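import numpy as np
import pytest

from spacerhis.crispr_array import RepeatConsensus
from spacerhis.synthetic_data import (
    ArraySpec,
    PCAR_REPEAT,
    ProteomeSpec,
    SynthConfig,
    synth_genome,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def consensus():
    return RepeatConsensus(PCAR_REPEAT)


@pytest.fixture(scope="session")
def small_synth():
    """A 10-repeat planted genome: (config, genome, features, truth)."""
    cfg = SynthConfig(seed=11, genome_length=25_000,
                      array=ArraySpec(n_repeats=10))
    genome, features, truth = synth_genome(cfg)
    return cfg, genome, features, truth


@pytest.fixture(scope="session")
def default_synth():
    """The full-size default planted genome (112 repeats, 111 spacers)."""
    cfg = SynthConfig(seed=7)
    genome, features, truth = synth_genome(cfg)
    return cfg, genome, features, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, length):
    return "".join(rng.choice(list(AA20), size=length))
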