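import numpy as np
import pytest

from methyltiers import synthetic


@pytest.fixture(scope="session")
def worked_example():
    """Tiny deterministic dataset: 36 sites, 3 genes, 5 vs 14 samples."""
    return synthetic.worked_example_fixture()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
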