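import numpy as np
import pytest

from inflammeth.synthetic_data import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic bundle shared across read-only tests."""
    return generate_bundle(SyntheticConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
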