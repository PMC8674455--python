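import numpy as np
import pytest

from bpimap import PhantomSpec, VolumeGeometry, build_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced-layout phantom shared by evaluation tests (fast, seeded)."""
    spec = PhantomSpec(
        counts=(60, 50, 300), effect_act=0.2, noise_sd=0.3, n_images=300, seed=11
    )
    return build_phantom(spec)


@pytest.fixture
def geom_4x4x4():
    return VolumeGeometry((4, 4, 4), np.diag([2.0, 2.0, 2.0, 1.0]))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
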