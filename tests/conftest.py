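import numpy as np
import pytest

from basemort.simulate import simulate_scenario


@pytest.fixture(scope="session")
def base_series():
    """One frozen base-case simulated series, 2000-2023 (seed 20).

    The same series underlies the frozen external-oracle comparisons, so it
    must not change seed.
    """
    return simulate_scenario("quadratic", 20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
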