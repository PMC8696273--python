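import numpy as np
import pytest

from genefc import generate_dataset
from genefc.simulate import SyntheticConfig


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results do not depend on test order
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small benchmark dataset shared across read-only tests."""
    cfg = SyntheticConfig(
        n_regions=30,
        n_genes=120,
        n_subjects=16,
        network_sizes=(14, 8, 4, 4),
        n_coupling_genes=10,
        coupling_effect=0.5,
        seed=7,
    )
    return generate_dataset(cfg)
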