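import numpy as np
import pytest

from resectquant.phantom import DscCurveSpec, PhantomSpec, make_phantom_pair


@pytest.fixture(scope="session")
def iso_phantom_spec():
    """Small isotropic phantom: fast to build, exact rim truth."""
    return PhantomSpec(
        grid_shape=(40, 40, 40),
        spacing_mm=(1.0, 1.0, 1.0),
        cavity_radius_mm=8.0,
        rim_thickness_mm=3.0,
        rim_enhancement=60.0,
    )


@pytest.fixture(scope="session")
def iso_phantom(iso_phantom_spec):
    return make_phantom_pair(iso_phantom_spec)


@pytest.fixture(scope="session")
def native_phantom():
    """Phantom at the native anisotropic (5 mm slice) resolution."""
    return make_phantom_pair(PhantomSpec())


@pytest.fixture
def default_curve_spec():
    return DscCurveSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
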