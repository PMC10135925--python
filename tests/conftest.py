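import numpy as np
import pytest

from hydrostress import FlowField, WATER_310K


@pytest.fixture
def water():
    """Water at the 310.15 K cultivation temperature."""
    return WATER_310K


@pytest.fixture
def rng():
    return np.random.default_rng(20230478)


@pytest.fixture
def random_field(rng):
    """A 1000-cell field with log-normal volumes and dissipation."""
    n = 1000
    vol = rng.lognormal(0.0, 0.4, n)
    vol *= 4e-3 / vol.sum()
    k = rng.lognormal(-4.0, 0.8, n)
    omega = rng.lognormal(1.0, 0.8, n)
    return FlowField(volume=vol, k=k, omega=omega, total_volume=4e-3)
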