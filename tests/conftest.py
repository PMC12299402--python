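import numpy as np
import pytest

from tumorkin import GompertzParams


@pytest.fixture
def gp():
    """A generic saturating growth state used across modules."""
    return GompertzParams(V0=1.0, V_inf=5.0, k=0.1, t0=0.0)


@pytest.fixture
def slow_gp():
    """Slow-rate growth typical of in-vivo series (k ~ 0.03/day)."""
    return GompertzParams(V0=1.0, V_inf=5.0, k=0.03, t0=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
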