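import numpy as np
import pytest

from myofat import PhantomSpec, make_thigh_phantom

# muscle mean 110 at SNR 15
SNR15_SIGMA = 110.0 / 15.0


@pytest.fixture
def phantom_spec():
    """Factory for thigh-phantom specs with study-condition defaults."""

    def make(**overrides):
        defaults = dict(imat_fraction_target=0.2, noise_sigma=SNR15_SIGMA, seed=3)
        defaults.update(overrides)
        return PhantomSpec(**defaults)

    return make


@pytest.fixture
def clean_phantom(phantom_spec):
    """Noise-free 20% infiltration phantom with its ground truth."""
    spec = phantom_spec(noise_sigma=0.0)
    vol, truth = make_thigh_phantom(spec)
    return spec, vol, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
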