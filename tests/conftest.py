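import numpy as np
import pytest

import sccvae


@pytest.fixture(scope="session")
def benchmark_spec():
    return sccvae.default_benchmark(seed=0)


@pytest.fixture(scope="session")
def benchmark_data(benchmark_spec):
    """Canonical synthetic screen plus ground truth, generated once."""
    return sccvae.simulate(benchmark_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_adata():
    """A small, quickly simulated screen for I/O and filter tests."""
    spec = sccvae.default_benchmark(
        seed=3,
        m=60,
        n_true=16,
        n_groups=2,
        perts_per_group=3,
        cells_per_perturbation=80,
        n_control_cells=300,
    )
    adata, truth = sccvae.simulate(spec)
    return adata
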