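import numpy as np
import pytest

from activeclean import (
    MixtureSpec,
    NoiseConfig,
    fixture_toy4,
    generate_mixture_dataset,
    make_noisy_benchmark,
)


@pytest.fixture
def toy4():
    return fixture_toy4()


@pytest.fixture(scope="session")
def small_benchmark():
    """Well-separated 5-class mixture with 15% symmetric label noise, n=400."""
    base = generate_mixture_dataset(MixtureSpec(n=400, C=5, separation=6.0, seed=11))
    noisy, rate = make_noisy_benchmark(base, NoiseConfig("symmetric", eta=0.15, seed=12))
    return noisy, rate


@pytest.fixture
def rng():
    return np.random.default_rng(7)
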