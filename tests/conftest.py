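import numpy as np
import pytest

from mitomct import (
    GeneFeature,
    GeneratorConfig,
    MitoGenome,
    builtin_reference,
)


@pytest.fixture(scope="session")
def human_ref():
    return builtin_reference("human")


@pytest.fixture(scope="session")
def mouse_ref():
    return builtin_reference("mouse")


@pytest.fixture
def toy_genome():
    # single H-strand gene covering the whole 9-mer: M K *
    return MitoGenome("toy", "toy", "ATGAAATAA"), [GeneFeature("G1", 1, 9, "H", "protein")]


@pytest.fixture
def rng():
    return np.random.default_rng(20210625)


@pytest.fixture
def gen_config():
    return GeneratorConfig(seed=0)
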