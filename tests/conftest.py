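import numpy as np
import pytest

from sandplume.params import PhysicalParams


@pytest.fixture(scope="session")
def capsule_params() -> PhysicalParams:
    """Betaine-capsule parameters as used for the surface-detectability prediction
    (V = 1 mL overrides the geometric ellipsoid volume for the total moles)."""
    return PhysicalParams()


@pytest.fixture(scope="session")
def consistent_params() -> PhysicalParams:
    """Capsule with V derived from the axes, so interior density equals c0."""
    return PhysicalParams.from_axes()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
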