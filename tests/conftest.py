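import numpy as np
import pytest

from omtapc.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(
        grid_shape=(20, 20, 20),
        brain_axes=(7.5, 7.0, 6.5),
        tumor_radius=3.0,
        class_label=1,
        effect_size=2.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_volume(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
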