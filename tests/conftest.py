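import numpy as np
import pytest

from jointphen.synthetic import SurfaceSpec, VolumeSpec, generate_surface, generate_volume


@pytest.fixture(scope="session")
def small_surface():
    """A 512 px surface with 3 cracks, 2 debris blobs and 20 speckles."""
    spec = SurfaceSpec(
        image_shape=(512, 512),
        n_cracks=3,
        crack_length_px=(80, 160),
        crack_aspect_ratio=8.0,
        n_debris_blobs=2,
        n_speckles=20,
        seed=7,
    )
    return (spec,) + generate_surface(spec)


@pytest.fixture(scope="session")
def grid_volume():
    """Default crossing-wall volume with its analytic truths."""
    spec = VolumeSpec(seed=3)
    volume, truths = generate_volume(spec)
    return spec, volume, truths


@pytest.fixture(scope="session")
def plates_volume():
    """Parallel-plate volume: thickness metrics are exactly analytic."""
    spec = VolumeSpec(lattice_kind="plates", seed=4)
    volume, truths = generate_volume(spec)
    return spec, volume, truths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
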