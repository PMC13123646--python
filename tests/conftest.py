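import numpy as np
import pytest

from hsisas.cube_io import RawCube, ReflectanceCube, SpectralAxis, default_axis
from hsisas.synth import (
    PhantomScene,
    SpectralModel,
    generate_subject,
    make_noise_free,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_axis():
    return default_axis(16)


@pytest.fixture
def axis64():
    return default_axis(64)


def make_reflectance(data, axis=None):
    data = np.asarray(data, dtype=float)
    axis = axis or default_axis(data.shape[2])
    return ReflectanceCube(data=data, axis=axis)


@pytest.fixture
def constant_cube():
    """4x5 spatial, 64 bands, constant reflectance 0.5."""
    axis = default_axis(64)
    return make_reflectance(np.full((4, 5, 64), 0.5), axis)


@pytest.fixture(scope="session")
def small_scene():
    return PhantomScene(rows=96, cols=64, L=64)


@pytest.fixture(scope="session")
def noise_free_subject(small_scene):
    model = make_noise_free(SpectralModel())
    return generate_subject(model, small_scene, "phantom", seed=7)


@pytest.fixture(scope="session")
def noisy_subject(small_scene):
    return generate_subject(SpectralModel(), small_scene, "noisy", seed=7)
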