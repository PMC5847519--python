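import numpy as np
import pytest

from natriq.curves import DecayCurve
from natriq.models import BiexpParams, biexp_signal
from natriq.schedule import make_default_schedule


@pytest.fixture(scope="session")
def schedule():
    return make_default_schedule()


@pytest.fixture(scope="session")
def te(schedule):
    return np.asarray(schedule.echo_times, dtype=float)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def gm_params():
    """GM-like generating parameters used across fitting tests."""
    return BiexpParams(
        amplitude_A=100.0,
        short_fraction_f=0.46,
        t2star_short=4.99,
        t2star_long=31.51,
        ric=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_gm_curve(gm_params, te):
    return DecayCurve(te, biexp_signal(gm_params, te), source_id="GM")
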