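import numpy as np
import pytest

from pleurakit import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Piecewise-constant phantom: no noise, no ribs, no tilt."""
    return generate_phantom(PhantomConfig(noise_sd=0.0, rib_count=0,
                                          illumination_tilt=0.0))


@pytest.fixture(scope="session")
def phantom_pair():
    """Matched normal/effusion pair sharing seed and anatomy."""
    normal = generate_phantom(PhantomConfig(seed=3))
    effusion = generate_phantom(PhantomConfig(seed=3, effusion=True,
                                              fill_level=0.4, side="right"))
    return normal, effusion
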