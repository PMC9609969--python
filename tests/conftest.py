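import numpy as np
import pytest

from circam import RadialPolynomialModel, synthetic_fisheye_model


@pytest.fixture(scope="session")
def fisheye():
    """Synthetic wide-angle ground-truth lens (185-degree max FOV)."""
    return synthetic_fisheye_model()


@pytest.fixture(scope="session")
def pinhole():
    """Constant-polynomial model: exactly a pinhole with focal 100 px."""
    return RadialPolynomialModel((100.0,), center=(64.0, 64.0), rho_max=300.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
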