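import numpy as np
import pytest

from tvfc import simkit, wishart


@pytest.fixture(scope="session")
def bench_wp_config():
    """Desk-scale WP training configuration used throughout the tests."""
    return wishart.WPConfig(m=24, max_iter=2500, seed=0)


@pytest.fixture(scope="session")
def constant_fit(bench_wp_config):
    """One WP fit on noiseless constant-0.8 bivariate data, shared by tests."""
    data, truth = simkit.simulate_dataset("constant", n=400, seed=7)
    model = wishart.fit_wp(data, bench_wp_config)
    return data, truth, model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
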