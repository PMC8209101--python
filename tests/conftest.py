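import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from labbatch import EventLog

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def random_event_log(rng: np.random.Generator, n: int,
                     integer: bool = False, tat_limit: float = 60.0,
                     span: float = 200.0) -> EventLog:
    """A small random valid log (x <= y <= z) for property tests."""
    x = np.sort(rng.uniform(0, span, n))
    pre = rng.uniform(0, 30, n)
    post = rng.uniform(0, 40, n)
    if integer:
        x, pre, post = (np.floor(v) for v in (x, pre, post))
    return EventLog(ids=[f"S{i:03d}" for i in range(n)],
                    x=x, y=x + pre, z=x + pre + post, tat_limit=tat_limit)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def three_record_log():
    """The hand-simulated 3-record log: (0,10,25), (8,20,36), (40,52,66)."""
    return EventLog.from_records(
        [("A", 0, 10, 25), ("B", 8, 20, 36), ("C", 40, 52, 66)])


@pytest.fixture
def four_record_log():
    """3-record log plus ("D", 41, 45, 95), used for TAT-rate checks."""
    return EventLog.from_records(
        [("A", 0, 10, 25), ("B", 8, 20, 36), ("C", 40, 52, 66),
         ("D", 41, 45, 95)])
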