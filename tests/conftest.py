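import pytest

from metasurv import calibrate_config, default_config
from metasurv.parameters import set_param


@pytest.fixture(scope="session")
def base_config():
    return default_config()


@pytest.fixture(scope="session")
def base_tp(base_config):
    return calibrate_config(base_config)


@pytest.fixture(scope="session")
def undiscounted_config(base_config):
    return set_param(base_config, "settings.annual_discount_rate", 0.0)


@pytest.fixture()
def zero_hazard_config(undiscounted_config):
    """No recurrence, no death, perfect specificity: deterministic trajectories."""
    cfg = undiscounted_config
    for path, value in [
        ("cohort.recurrence_fraction", 0.0),
        ("cohort.os10_nonrecurred", 1.0),
        ("cohort.os5_recurred", 1.0),
        ("cohort.os10_recurred", 1.0),
        ("tests.clinic_visit.specificity", 1.0),
        ("tests.cea_test.specificity", 1.0),
        ("tests.ct.specificity", 1.0),
    ]:
        cfg = set_param(cfg, path, value)
    return cfg
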