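import numpy as np
import pytest

from electrome import Recording, gen_colored_noise, gen_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def white_rec():
    return gen_colored_noise(0.0, 4096, seed=11)


@pytest.fixture
def pink_rec():
    return gen_colored_noise(1.0, 4096, seed=12)


@pytest.fixture(scope="session")
def small_experiment():
    """Four condition classes, three short recordings each."""
    return gen_experiment(n_per_class=3, seed=7, n=4096)


@pytest.fixture
def sine_rec():
    t = np.arange(4096) / 62.5
    return Recording(samples=np.sin(2 * np.pi * 0.5 * t), fs=62.5)
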