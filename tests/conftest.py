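import numpy as np
import pytest
from hypothesis import settings

from levyswitch import Domain1D, ModelParams

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

# Reference equilibria of the standard parameter set, frozen from a
# bracketing + bisection root find at 1e-12 bracket width.
X_MINUS = 0.62685
X_U = 1.48971
X_PLUS = 4.28343


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """The standard TF-A rate set used throughout the analysis."""
    return ModelParams(k_f=6.0, K_d=10.0, k_d=1.0, R_bas=0.4)


@pytest.fixture(scope="session")
def params_shallow() -> ModelParams:
    """Alternative bistable rate set with a much shallower low state."""
    return ModelParams(k_f=7.5, K_d=10.0, k_d=1.0, R_bas=0.1)


@pytest.fixture(scope="session")
def low_region() -> Domain1D:
    """The low-concentration region D = (0, x_u)."""
    return Domain1D.interval(0.0, X_U)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160714)


def zero_drift(x):
    return np.zeros_like(np.asarray(x, dtype=float))
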