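import logging

import pytest
from hypothesis import HealthCheck, settings

import osteomeno as om
from osteomeno.model import EstrogenModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# The packaged defaults intentionally warn about the osteoclast-level
# inconsistency; keep test output readable.
logging.getLogger("osteomeno.parameters").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def p():
    return om.natural_defaults()


@pytest.fixture(scope="session")
def s_short():
    return om.surgical_short_term()


@pytest.fixture(scope="session")
def s_long():
    return om.surgical_long_term()


@pytest.fixture(scope="session")
def e_nat(p):
    return EstrogenModel.natural(p.t_m, p.tau_E)


@pytest.fixture(scope="session")
def e_surg(p, s_short):
    return EstrogenModel.surgical(p.t_m, s_short.kappa_E, s_short.k_syn)


@pytest.fixture(scope="session")
def traj_nat(p, e_nat):
    return om.simulate(p, None, e_nat)


@pytest.fixture(scope="session")
def traj_short(p, s_short, e_surg):
    return om.simulate(p, s_short, e_surg)


@pytest.fixture(scope="session")
def traj_long(p, s_long, e_surg):
    return om.simulate(p, s_long, e_surg)


@pytest.fixture(scope="session")
def traj_zero(p, s_short, e_surg):
    """Sudden estrogen loss alone: surgery fold-increases zeroed."""
    zero = s_short.replace(eta_surg=0.0, omega_surg=0.0)
    return om.simulate(p, zero, e_surg)
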