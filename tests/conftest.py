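import numpy as np
import pytest

from markermine import benchmark as bm

#: Seed of the default benchmark study; every stochastic test derives from it.
BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark_result():
    """The full two-station benchmark (5e4 reads); shared across tests."""
    return bm.run_benchmark(seed=BENCHMARK_SEED, n_reads_total=50_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(BENCHMARK_SEED)
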