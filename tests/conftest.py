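import numpy as np
import pytest

from stochpd import ModelParams, DoseSchedule


@pytest.fixture
def p_sustained():
    """Sustained-dose parameters used throughout the extinction-time figures."""
    return ModelParams(mu=0.2, lam=0.0, delta=1.0)


@pytest.fixture
def pm_cycles():
    """Multiple-dose simulation parameters (mu=1, lam=0.4, delta=2.5, alpha=2)."""
    return ModelParams(mu=1.0, lam=0.4, delta=2.5, alpha=2.0)


@pytest.fixture
def sch_cycles():
    """T=3 cycles with a one-unit dose and a two-unit recovery."""
    return DoseSchedule.cycles(T=3.0, T_d=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
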