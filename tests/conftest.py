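from __future__ import annotations

from datetime import date, time

import numpy as np
import pytest

from activerx.am_format import (
    AMFile,
    MODE_ACTIVITY,
    MODE_RESTING,
    PrescriptionRecord,
    SAMPLE_RATE,
)
from activerx.prescription import ParticipantProfile

START = date(2025, 1, 6)  # a Monday


def build_resting_file(
    beat_values,
    duration_min: float = 10.0,
    user_id: str = "u01",
    file_date: date = date(2025, 1, 6),
) -> AMFile:
    """Resting file with one beat per second (at t = i + 0.5 s)."""
    n = int(round(duration_min * 60 * SAMPLE_RATE))
    hr = np.zeros(n, dtype=np.uint8)
    for i, val in enumerate(beat_values):
        row = i * SAMPLE_RATE + SAMPLE_RATE // 2
        if row < n:
            hr[row] = val
    accel = np.zeros((n, 3), dtype=np.int16)
    accel[:, 2] = 1000
    return AMFile(
        user_id=user_id,
        file_date=file_date,
        file_time=time(7, 15, 0),
        mode=MODE_RESTING,
        t_ds=np.arange(n, dtype=np.uint32),
        accel_mg=accel,
        hr=hr,
        source_name=f"{user_id}_{file_date:%Y%m%d}_071500_R.amb",
    )


def build_activity_file(
    hr_value: int,
    duration_min: float = 30.0,
    user_id: str = "u01",
    file_date: date = date(2025, 1, 6),
    hr_series=None,
) -> AMFile:
    """Activity file with HR on every row (constant, or a per-row series)."""
    n = int(round(duration_min * 60 * SAMPLE_RATE))
    if hr_series is not None:
        hr = np.asarray(hr_series, dtype=np.uint8)
        assert hr.size == n
    else:
        hr = np.full(n, hr_value, dtype=np.uint8)
    accel = np.zeros((n, 3), dtype=np.int16)
    accel[:, 2] = 1000
    return AMFile(
        user_id=user_id,
        file_date=file_date,
        file_time=time(18, 30, 0),
        mode=MODE_ACTIVITY,
        t_ds=np.arange(n, dtype=np.uint32),
        accel_mg=accel,
        hr=hr,
        source_name=f"{user_id}_{file_date:%Y%m%d}_183000_A.amb",
    )


def week1_prescription(day: date = date(2025, 1, 6)) -> PrescriptionRecord:
    return PrescriptionRecord(day, "mandatory", 5, 20, 5, 115, 128, 1)


@pytest.fixture
def profile() -> ParticipantProfile:
    return ParticipantProfile(
        user_id="u01", sex="M", hrmax=190.0, baseline_hrrest=65.0, start_date=START
    )


@pytest.fixture
def profile_no_baseline() -> ParticipantProfile:
    return ParticipantProfile(
        user_id="u02", sex="M", hrmax=190.0, baseline_hrrest=None, start_date=START
    )
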