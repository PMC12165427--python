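import numpy as np
import pytest

from glioseg3d.phantom import PhantomSpec, generate_phantom
from glioseg3d.preprocess import zscore_normalize
from glioseg3d.volumes import MultimodalVolume


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_spec():
    """32-cube phantom with spheres r_net=2, r_et=3.5, r_ed=5.5."""
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        brain_radius_vox=13.0,
        r_net=2.0,
        r_et=3.5,
        r_ed=5.5,
        noise_sigma=0.02,
        bias_amplitude=0.1,
        seed=7,
    )


@pytest.fixture
def small_case(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture
def spec64():
    """64-cube phantom with the spec's example radii 3/5/8."""
    return PhantomSpec(
        grid_shape=(64, 64, 64),
        brain_radius_vox=28.0,
        r_net=3.0,
        r_et=5.0,
        r_ed=8.0,
        noise_sigma=0.02,
        bias_amplitude=0.1,
        seed=11,
    )


def make_training_case(seed, shape=(32, 32, 32)):
    """Normalized phantom suitable for feeding the network directly."""
    gen = np.random.default_rng(seed)
    scale = min(shape) / 32.0
    center = tuple((n - 1) / 2.0 + gen.uniform(-3, 3) * scale for n in shape)
    r_ed = gen.uniform(4.5, 6.0) * scale
    spec = PhantomSpec(
        grid_shape=shape,
        brain_radius_vox=min(shape) * 0.42,
        tumor_center_vox=center,
        r_net=r_ed * 0.35,
        r_et=r_ed * 0.6,
        r_ed=r_ed,
        noise_sigma=0.02,
        bias_amplitude=0.1,
        seed=seed,
    )
    vol, lab = generate_phantom(spec)
    mask = np.any(vol.data > 0.1, axis=0)
    data = np.stack([zscore_normalize(vol.data[i], mask) for i in range(4)])
    return MultimodalVolume(data, spacing=vol.spacing), lab
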