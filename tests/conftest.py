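import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from circabee import ActivitySeries, LightSchedule

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

LIGHTS_ON = 480  # 08:00
START = pd.Timestamp("2020-01-01 08:00")  # recording starts at lights-on


@pytest.fixture
def schedule() -> LightSchedule:
    """2 LD days followed by 2 DD days, lights on 08:00-20:00."""
    return LightSchedule(
        entrain_days=2, dd_days=2, lights_on_clock=LIGHTS_ON, reference_start=START
    )


@pytest.fixture
def ld_schedule() -> LightSchedule:
    return LightSchedule(
        entrain_days=4, dd_days=0, lights_on_clock=LIGHTS_ON, reference_start=START
    )


def make_series(counts, bin_width=1, subject_id="bee", start=START) -> ActivitySeries:
    return ActivitySeries(
        subject_id=subject_id,
        start_time=start,
        bin_width=bin_width,
        counts=np.asarray(counts),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20201120)
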