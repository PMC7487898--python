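import numpy as np
import pytest

from molgenrl.synthetic import sample_molecules


@pytest.fixture(scope="session")
def fixture_smiles():
    """100 varied, valid molecules for round-trip / batch tests."""
    return sample_molecules(100, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
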