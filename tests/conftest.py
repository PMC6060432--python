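import pytest
from hypothesis import settings

from glucofret import (BaselineWindow, RatioTrace, correct_drift,
                       default_params, median_filter5, relative_ratio,
                       simulate_cell_ratio, standard_protocols)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocols():
    return standard_protocols()


@pytest.fixture(scope="session")
def nontg():
    return default_params("nonTg")


@pytest.fixture(scope="session")
def tg3x():
    return default_params("3xTgAD")


@pytest.fixture(scope="session")
def baseline():
    """Standard 10 min pre-stimulus control window."""
    return BaselineWindow(0.0, 10.0)


def relative_trace(kinetics, sensor, protocol, baseline, filtered=False):
    """Ground-truth relative-ratio trace for one simulated cell."""
    t, r = simulate_cell_ratio(kinetics, sensor, protocol)
    rel = relative_ratio(correct_drift(RatioTrace("cell", t, r), baseline), baseline)
    return median_filter5(rel) if filtered else rel


@pytest.fixture(scope="session")
def make_relative_trace():
    return relative_trace
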