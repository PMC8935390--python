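import numpy as np
import pytest

from cryovalid.synthetic import (
    default_phantom_spec,
    make_half_pair,
    make_phantom,
    noise_sigma_for_snr,
)


@pytest.fixture(scope="session")
def phantom48():
    """Canonical 48³ multi-blob phantom at 1 Å pixels."""
    return make_phantom(default_phantom_spec(48, 1.0))


@pytest.fixture(scope="session")
def phantom32():
    # fewer blobs than the 48³ default: the smaller box would otherwise be
    # overcrowded once the 3-sigma face margin is enforced
    return make_phantom(default_phantom_spec(32, 1.0, n_blobs=6, seed=3))


@pytest.fixture(scope="session")
def half_pair48(phantom48):
    sigma = noise_sigma_for_snr(phantom48, 5.0)
    return make_half_pair(phantom48, sigma, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
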