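import numpy as np
import pytest

from lingslide.model_core import ModelParameters, ReducedCoefficients
from lingslide.filippov import FilippovModel

# Reduced coefficients of the four built-in policy parameterizations
# (mu = 0.02, a = 1): baseline, status-only, interaction-only, combined.
BASELINE = ReducedCoefficients(0.016, 0.00588, 0.004, 0.02352)
STATUS_CTRL = ReducedCoefficients(0.012, 0.01176, 0.008, 0.01764)
INTERACT_CTRL = ReducedCoefficients(0.016, 0.01176, 0.004, 0.04704)
COMBINED_CTRL = ReducedCoefficients(0.012, 0.02352, 0.008, 0.03528)


@pytest.fixture
def baseline_coeffs():
    return BASELINE


@pytest.fixture
def baseline_params():
    return ModelParameters(
        mu=0.02, a=1.0, s_A=0.8, s_B=0.2, I_wA=1.0, I_wB=1.0, I_Aw=0.03, I_Bw=0.03
    )


@pytest.fixture
def combined_policy_model():
    """Free baseline + combined status-and-interaction policy, ET = 0.3.

    The configuration whose sliding analysis yields a pseudo-equilibrium.
    """
    return FilippovModel(free=BASELINE, controlled=COMBINED_CTRL, a=1.0, ET=0.3)


@pytest.fixture
def status_policy_model():
    return FilippovModel(free=BASELINE, controlled=STATUS_CTRL, a=1.0, ET=0.3)


@pytest.fixture
def interaction_policy_model():
    return FilippovModel(free=BASELINE, controlled=INTERACT_CTRL, a=1.0, ET=0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(20230629)


def random_coeffs(rng, low=1e-3, high=3.0):
    return ReducedCoefficients(*rng.uniform(low, high, size=4))
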