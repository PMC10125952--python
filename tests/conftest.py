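import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from phytocyto.synthetic import PhantomSpec, gen_aoeb_field, gen_nuclei_field


@pytest.fixture
def small_spec():
    """A small, quick-to-render noise-free field."""
    return PhantomSpec(image_shape=(256, 256), n_cells=5, noise_sd=0.0, seed=11)


@pytest.fixture
def nuclei_field(small_spec):
    return gen_nuclei_field(small_spec)


@pytest.fixture
def aoeb_field():
    spec = PhantomSpec(
        image_shape=(256, 256), n_cells=8, noise_sd=0.0, seed=23,
        stage_mixture=(0.25, 0.25, 0.25, 0.25),
    )
    return gen_aoeb_field(spec)
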