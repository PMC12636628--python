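import numpy as np
import pytest

from sexbias import synthetic


@pytest.fixture(scope="session")
def small_panel():
    """Shared 6-block panel for LD-dependent tests."""
    return synthetic.simulate_panel(6, 8, 0.6, 4000, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
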