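"""Shared fixtures: small phantoms so every stage is testable in seconds."""

import numpy as np
import pytest

from orgamri import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """32³ non-cystic phantom spec (fast to render and segment)."""
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        organoid_radius_vox=7.0,
        noise_sigma=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def cystic_spec():
    """32³ phantom with one large central cyst."""
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        organoid_radius_vox=8.0,
        cysts=[((16.0, 16.0, 16.0), 4.0)],
        noise_sigma=0.02,
        seed=12,
    )


@pytest.fixture(scope="session")
def noncystic_sample(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def cystic_sample(cystic_spec):
    return generate_phantom(cystic_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
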