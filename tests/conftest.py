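import numpy as np
import pytest

from invpopgen import SynthConfig
from invpopgen.ld import build_site_table
from invpopgen.synthetic import generate_dataset


@pytest.fixture(scope="session")
def synth_dataset():
    """One default-condition synthetic panel shared across tests."""
    return generate_dataset(SynthConfig(seed=20130701))


@pytest.fixture(scope="session")
def site_table(synth_dataset):
    return build_site_table(synth_dataset.alignments)


@pytest.fixture()
def rng():
    return np.random.default_rng(11)
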