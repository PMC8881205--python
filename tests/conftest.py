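import numpy as np
import pytest

from tebusco.experiments import make_benchmark_dataset


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The standard 2 Mb benchmark dataset at seed 1 (simulated once)."""
    return make_benchmark_dataset(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
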