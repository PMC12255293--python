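import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mcsdr import kinetics, reference, thermo

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("deterministic")

CONC = reference.DEFAULT_CONC
T_END = reference.DEFAULT_T_END


@pytest.fixture(scope="session")
def system():
    return reference.reference_system()


@pytest.fixture(scope="session")
def tparams():
    return thermo.ThermoParams()


@pytest.fixture(scope="session")
def kparams():
    return kinetics.KineticParams()


@pytest.fixture(scope="session")
def t_grid():
    return kinetics.fit_time_grid(T_END)


@pytest.fixture(scope="session")
def grid(kparams):
    """The full 6x5 toehold x closure sweep (computed once per session)."""
    return kinetics.sweep_grid(params=kparams, t_end=T_END)
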