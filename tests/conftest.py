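import numpy as np
import pytest

from levysmooth.synthetic_prints import (
    SyntheticPrintParams,
    generate_latent,
    print_mask,
)


@pytest.fixture(scope="session")
def default_latent():
    """Synthetic latent print at default conditions, seed 1."""
    params = SyntheticPrintParams(seed=1)
    latent, clean = generate_latent(params)
    return params, latent, clean, print_mask(params)


@pytest.fixture(scope="session")
def noisy_latent():
    """Heavier-noise synthetic latent (sigma 25), seed 1, used for the
    smoothing-helps-ridge-fidelity checks."""
    params = SyntheticPrintParams(noise_sigma=25.0, seed=1)
    latent, clean = generate_latent(params)
    return params, latent, clean, print_mask(params)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
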