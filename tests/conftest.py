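import numpy as np
import pytest

import ecgelm


@pytest.fixture(scope="session")
def benchmark():
    """The frozen 3-class synthetic benchmark record and its annotations."""
    return ecgelm.default_benchmark()


@pytest.fixture(scope="session")
def benchmark_features(benchmark):
    """Default 20-column feature matrix of the benchmark record."""
    record, annotations = benchmark
    return ecgelm.extract_beat_features(record, annotations)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
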