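import numpy as np
import pytest

from telosen.generate import GeneratorConfig, generate_dataset
from telosen.lineages import lineage_from_durations


@pytest.fixture
def make_lineage():
    """Factory for lineages from plain duration lists."""
    return lineage_from_durations


@pytest.fixture(scope="session")
def default_dataset():
    """One default-configuration synthetic dataset (fixed seed)."""
    return generate_dataset(GeneratorConfig(), seed=20210)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
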