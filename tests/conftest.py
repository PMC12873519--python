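import numpy as np
import pytest

import leafxylem as lx


@pytest.fixture(scope="session")
def sim88():
    """One default-condition synthetic data set (88 species + tree)."""
    return lx.simulate_dataset(n_species=88, seed=11)


@pytest.fixture(scope="session")
def small_tree():
    return lx.generate_tree(12, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
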