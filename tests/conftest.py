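import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from asboincomb import DesignParams, TrialState


@pytest.fixture
def table1_params() -> DesignParams:
    """Reference design: target 0.3, initial bracket 0.3*phi / 1.7*phi, t1=t2=100."""
    return DesignParams(phi=0.3, phi1_init=0.09, phi2_init=0.51, t1=100.0, t2=100.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230302)


def make_state(n, y, current=(0, 0)) -> TrialState:
    n = np.asarray(n, dtype=int)
    return TrialState(J=n.shape[0], K=n.shape[1], n=n, y=np.asarray(y, dtype=int),
                      current=current)
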