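import numpy as np
import pytest

from nodulekit import phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One 64³ phantom with an isolated 8 mm nodule and a z-axis vessel."""
    shape = (64, 64, 64)
    spec = phantom.PhantomSpec(
        shape=shape,
        nodules=[phantom.NoduleSpec(center=(32.0, 32.0, 20.0),
                                    diameter_mm=8.0)],
        vessels=[phantom.VesselSpec(axis="z", start=(8.0, 30.0, 44.0),
                                    end=(56.0, 30.0, 44.0), radius_mm=2.0)],
        noise_sigma=10.0, seed=3)
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_sphere_mask():
    """Analytic 8 mm sphere mask at 1 mm isotropic spacing."""
    return phantom.sphere_mask((64, 64, 64), (32.0, 32.0, 32.0), 4.0,
                               (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
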