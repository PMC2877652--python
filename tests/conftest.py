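import numpy as np
import pytest

from lnflare import (
    KineticParameters,
    StateVector,
    TherapyLevels,
    TherapySchedule,
    load_fixture,
)


@pytest.fixture(scope="session")
def patient_416():
    return load_fixture("416")


@pytest.fixture(scope="session")
def patient_444():
    return load_fixture("444")


@pytest.fixture(scope="session")
def patient_448():
    return load_fixture("448")


@pytest.fixture(scope="session")
def patient_491():
    return load_fixture("491")


@pytest.fixture(scope="session")
def all_patients(patient_416, patient_444, patient_448, patient_491):
    return {
        "416": patient_416,
        "444": patient_444,
        "448": patient_448,
        "491": patient_491,
    }


@pytest.fixture
def decoupled_params():
    """Parameters with every coupling and source zeroed: each state decays
    at its own rate (or stays constant for I)."""
    return KineticParameters(
        s_i=0.0, s_id=0.0, k_id=1.0, k_ip=0.0, k_pi=0.0, k_pp=0.0, k_pd=0.0,
        mu_p=0.06, k_dip=0.0, k_dp=0.0, mu_d=0.04, s_a=0.0, k_ap=0.0,
        k_ad=0.0, mu_a=2.2, A_inf=0.45,
    )


@pytest.fixture
def single_interval_schedule():
    def make(t0=0.0, t1=10.0, s_i=0.0, s_id=0.0, s_a=0.0):
        return TherapySchedule((t0, t1), (TherapyLevels(s_i, s_id, s_a),))

    return make


def random_params(rng: np.random.Generator) -> KineticParameters:
    """Random valid parameter draw spanning the published rate range."""
    u = lambda lo, hi: float(rng.uniform(lo, hi))
    return KineticParameters(
        s_i=u(0, 6), s_id=u(0, 4), k_id=u(0.1, 3), k_ip=u(0, 0.1),
        k_pi=u(0, 0.2), k_pp=u(0, 0.2), k_pd=u(0, 0.05), mu_p=u(0.01, 0.5),
        k_dip=u(0, 0.1), k_dp=u(0, 0.3), mu_d=u(0.01, 0.1), s_a=u(0, 10),
        k_ap=u(0, 0.05), k_ad=u(0, 0.5), mu_a=u(0.5, 3), A_inf=u(0.1, 1),
    )
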