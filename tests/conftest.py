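import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import resurgentsim as rs

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wt():
    return rs.wild_type_parameters()


@pytest.fixture(scope="session")
def iem():
    return rs.iem_parameters()


@pytest.fixture(scope="session")
def scheme():
    return rs.default_scheme()


@pytest.fixture(scope="session")
def wt_resurgent_25(scheme, wt):
    """WT resurgent battery at 25 degC (reused across analysis tests)."""
    return rs.run_battery(scheme, wt, rs.make_protocol("resurgent"), 25.0,
                          keep_occupancy=False)


@pytest.fixture(scope="session")
def control_axon():
    """Control axon scenario at 36 degC (expensive; shared)."""
    return rs.load_scenario("control", temperature_c=36.0)


def table3_rates():
    """Independent transcription of the printed rate table, used as an
    assembly oracle; kept separate from the package's YAML data."""
    wt = {
        "alpha": (100.0, 0.08, 2.1), "beta": (0.55, -0.01, 2.1),
        "gamma": (40.0, 0.01, 2.1), "delta": (2.0, -0.01, 2.1),
        "c_on": (0.1, 0.0, 3.2), "c_off": (0.5, 0.0, 3.2),
        "o_on": (2.5, 0.0, 3.2), "o_off": (0.004, 0.0, 3.2),
        "o1o2": (0.12, 0.057, 2.0), "o2o1": (0.001, -0.095, 2.0),
        "o2i2": (0.5, 0.04, 2.0), "i2o2": (0.06, -0.03, 2.0),
        "i1i2": (0.002, 0.01, 2.6), "i2i1": (0.2, -0.038, 2.6),
    }
    iem = dict(wt)
    iem.update({
        "alpha": (500.0, 0.08, 2.1), "beta": (4.0, -0.01, 2.1),
        "o1o2": (0.12, 0.057, 2.6), "o2o1": (0.001, -0.095, 2.6),
        "o2i2": (0.3, 0.04, 3.3), "i2o2": (0.07, -0.03, 3.3),
        "i1i2": (0.001, 0.01, 2.6), "i2i1": (0.12, -0.038, 2.6),
    })
    return {"WT": wt, "IEM": iem}


@pytest.fixture(scope="session")
def rate_table():
    return table3_rates()
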