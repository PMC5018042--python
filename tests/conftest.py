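import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from immunopulse import NondimParameters

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_params() -> NondimParameters:
    """All nondimensional rates equal to one, unit endogenous source."""
    return NondimParameters(
        k_v=1.0, k_m=1.0, k_CR=1.0, mu_D=1.0, mu_R=1.0, mu_C=1.0,
        k=1.0, g=1.0, a=1.0, V_p=1.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(autouse=True)
def _silence_degenerate_rate_warning():
    """Unit-parameter fixtures intentionally sit on the k_m == k_v resonance."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*degenerate t\\*exp branch.*")
        yield
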