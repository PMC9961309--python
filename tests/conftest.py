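import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_small():
    """In-memory separable phantom set: 40 images/class, no blanks."""
    from mgmtpmp.phantoms import PhantomSpec, generate_arrays

    return generate_arrays(PhantomSpec(n_per_class=40, blank_fraction=0.0, seed=5))


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """Small phantom dataset written to disk, with blanks injected."""
    from mgmtpmp.phantoms import PhantomSpec, generate_phantoms

    out = tmp_path_factory.mktemp("phantoms")
    spec = PhantomSpec(n_per_class=20, blank_fraction=0.2, seed=9)
    index = generate_phantoms(spec, out)
    return out, spec, index


@pytest.fixture(scope="session")
def random_images(rng):
    """A stack of random 64x64 uint8 images for descriptor properties."""
    return rng.integers(0, 256, size=(6, 64, 64)).astype(np.uint8)
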