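import numpy as np
import pytest

from tripoint.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_synth():
    """A small generated dataset shared by read-only tests."""
    cfg = SyntheticConfig(n_labeled=60, n_unlabeled=20, holdout_size=20, seed=11)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
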