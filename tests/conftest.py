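import numpy as np
import pandas as pd
import pytest

from mpulse.ingest import EventStream, SensorEvent
from mpulse.synth import SyntheticCohortConfig, generate_bundle


def ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s, tz="UTC")


def make_stream(sensor, starts, durations, pid="P001", span=None):
    """Build a small event stream from ISO strings / timestamps and
    durations in seconds."""
    events = [
        SensorEvent(pid, sensor, s if isinstance(s, pd.Timestamp) else ts(s), float(d))
        for s, d in zip(starts, durations)
    ]
    return EventStream(participant_id=pid, sensor=sensor, events=events,
                       observation_span=span)


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic cohort (26 participants, 21 days) shared by the
    slower integration-style tests."""
    return generate_bundle(SyntheticCohortConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
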