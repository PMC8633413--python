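import numpy as np
import pytest

from crinet.growth import CRIParams, TraitState
from crinet.mapping import SADParams


@pytest.fixture
def poplar_params():
    """Mildly antagonistic coupled-growth parameters on a poplar-like scale."""
    return CRIParams(alpha_h=0.60, k_h=24.0, beta_hd=-0.010,
                     alpha_d=0.45, k_d=30.0, beta_dh=0.004)


@pytest.fixture
def init_state():
    return TraitState(h=1.2, d=1.0, t=1.0)


@pytest.fixture
def annual_times():
    return np.arange(1.0, 15.0)


@pytest.fixture
def sad_params():
    return SADParams(phi_h=0.7, phi_d=0.6, nu_h=1.0, nu_d=1.5, rho=0.4)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Keep expected fit warnings (dropped classes, re-seeded modules) from
    cluttering test output; tests that assert on warnings re-enable them."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
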