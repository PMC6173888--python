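import datetime as dt

import numpy as np
import pandas as pd
import pytest

from swaft.device import AccelSample, EpochWindow
from swaft.simulate import SimConfig, simulate_cohort

MONDAY = dt.date(2015, 11, 16)  # an arbitrary intervention Monday


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully-featured simulated trial shared across tests."""
    cfg = SimConfig(seed=42, n_admitted=200)
    return simulate_cohort(cfg)


@pytest.fixture
def period1() -> EpochWindow:
    return EpochWindow(MONDAY, 1, dt.time(8, 0), dt.time(10, 0))


def make_trace(t: np.ndarray, az: np.ndarray) -> list[AccelSample]:
    return [AccelSample(float(tt), 0.0, 0.0, float(a)) for tt, a in zip(t, az)]


@pytest.fixture
def make_epoch_frame():
    """Build an epoch-record frame from (patient, date, period, score, worn) rows."""

    def _make(rows):
        return pd.DataFrame(
            rows,
            columns=["patient_id", "date", "period", "activity_score", "worn"],
        ).assign(worn_fraction=lambda d: d["worn"].astype(float))

    return _make
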