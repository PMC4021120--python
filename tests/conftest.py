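import numpy as np
import pytest

from nrffit.events import EventStream, compute_lags
from nrffit.forward import ForwardModel
from nrffit.simulate import make_repetition_schedule, make_tonotopy_schedule


@pytest.fixture(scope="session")
def rep_schedule():
    """Small seeded repetition schedule (2 epochs, 4 conditions)."""
    return make_repetition_schedule(n_epochs=2, seed=7)


@pytest.fixture(scope="session")
def tono_schedule():
    """Short tonotopy sweep (2 cycles of the 14-tone protocol)."""
    return make_tonotopy_schedule(n_cycles=2)


@pytest.fixture(scope="session")
def rs_forward(rep_schedule):
    """Item-lag exponential forward model on the small schedule."""
    events = compute_lags(rep_schedule.events, mode="item")
    return ForwardModel(events, "exp_lag", rep_schedule.tr,
                        rep_schedule.n_scans)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def simple_events():
    """Three events of one condition in a single train."""
    return EventStream(np.array([10.0, 12.0, 14.5]), np.zeros(3, dtype=int),
                       trains=np.zeros(3, dtype=int))
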