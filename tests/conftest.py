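import numpy as np
import pytest

from eegmarkers.designs import AssrDesign, OddballDesign, SubjectProfile
from eegmarkers.schedules import (generate_click_schedule,
                                  generate_oddball_schedule)
from eegmarkers.simulate import simulate_erp_session


@pytest.fixture(scope="session")
def oddball_design():
    return OddballDesign()


@pytest.fixture(scope="session")
def assr_design_40():
    return AssrDesign(n_trains=30, rates_tested=(40.0,))


@pytest.fixture()
def quiet_profile():
    return SubjectProfile("S0001", blink_rate_per_min=0.0)


@pytest.fixture(scope="session")
def small_oddball_schedule(oddball_design):
    return generate_oddball_schedule(oddball_design, 200, seed=11)


@pytest.fixture(scope="session")
def small_click_schedule(assr_design_40):
    return generate_click_schedule(assr_design_40, seed=12)


@pytest.fixture()
def quiet_erp_recording(small_oddball_schedule, quiet_profile):
    """Noise-free oddball session: deviant responses only."""
    return simulate_erp_session(small_oddball_schedule, quiet_profile,
                                seed=13, background_rms=0.0, alpha_rms=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
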