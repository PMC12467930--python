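import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    """Small multi-task model shared by read-only tests."""
    from gliomark.model import GliomaNet, tiny_config

    return GliomaNet(tiny_config(seed=7), build_shape=(16, 16, 16))


@pytest.fixture(scope="session")
def small_phantom():
    from gliomark.phantom import PhantomSpec, generate_phantom

    spec = PhantomSpec(volume_shape=(48, 48, 48), core_radius=5.0, rim_thickness=2.0,
                       halo_width=3.0, seed=11)
    return generate_phantom(spec)
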