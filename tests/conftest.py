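import numpy as np
import pytest

from stablesize.urn_process import ProcessConfig, run


@pytest.fixture(scope="session")
def case1_run():
    """A moderate shrink-only run shared across tests."""
    config = ProcessConfig.from_mean_size(
        M=2000, E=10.0, q0=0.05, mode="shrink_only", T=150, burn_in=100, seed=7, thin=5
    )
    return run(config, collect_pairs=True)


@pytest.fixture(scope="session")
def case2_run():
    """A moderate exit-only run shared across tests."""
    config = ProcessConfig.from_mean_size(
        M=2000, E=10.0, q0=0.05, mode="exit_only", delta_exit=0.05,
        T=150, burn_in=100, seed=7, thin=5,
    )
    return run(config, collect_pairs=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
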