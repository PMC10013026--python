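from datetime import datetime

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circastrain.actigraphy import ActimetryRecording, DayWindow, exclude_days

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

MIDNIGHT = datetime(2015, 6, 1, 0, 0)


def make_recording(values, epoch_minutes=10.0, channel="activity",
                   start=MIDNIGHT, brand="A", subject_id="T0") -> ActimetryRecording:
    return ActimetryRecording(subject_id=subject_id, device_brand=brand,
                              channel=channel, start=start,
                              epoch_minutes=epoch_minutes,
                              values=np.asarray(values, dtype=float))


def make_window(day_matrix, epoch_minutes=None, channel="activity") -> DayWindow:
    """DayWindow from a (n_days, bins_per_day) array (NaN = missing)."""
    day_matrix = np.asarray(day_matrix, dtype=float)
    if day_matrix.ndim != 2:
        raise ValueError("expected a 2-D day matrix")
    if epoch_minutes is None:
        epoch_minutes = 1440.0 / day_matrix.shape[1]
    rec = make_recording(day_matrix.ravel(), epoch_minutes=epoch_minutes,
                         channel=channel)
    window = exclude_days(rec, max_missing_hours=24.0)  # keep every day
    assert len(window.days) == day_matrix.shape[0]
    return window


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
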