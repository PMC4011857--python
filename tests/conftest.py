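"""Shared fixtures: phantoms are expensive, so the commonly used ones
are session-scoped and generated once."""

import numpy as np
import pytest

from fissint.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_noise_free():
    """Mid-range integrities, no noise: the easiest full phantom."""
    spec = PhantomSpec(target_integrity=(70.0, 50.0, 80.0), seed=1, noise_sd=0.0)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def phantom_noisy():
    """Same geometry under 30 HU additive noise."""
    spec = PhantomSpec(target_integrity=(70.0, 50.0, 80.0), seed=1, noise_sd=30.0)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def phantom_complete():
    """All fissures complete, noise-free."""
    spec = PhantomSpec(target_integrity=(100.0, 100.0, 100.0), seed=3, noise_sd=0.0)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
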