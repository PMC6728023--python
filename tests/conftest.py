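import numpy as np
import pytest

from metadendro.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """Six-organism synthetic dataset shared by read-only tests."""
    return generate_dataset(SynthConfig(n_organisms=6, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
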