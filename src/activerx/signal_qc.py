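"""Heart-rate signal quality control, resting-HR extraction, and session analysis.

A "beat" is any row of a monitor file whose ``hr`` field is nonzero — the
row at which the monitor registered an instantaneous heart rate.  Resting
recordings are filtered beat-wise against a trailing 10-beat moving average
before any value is trusted; whole files are then accepted or rejected by
the rules below, and accepted resting files yield one daily resting-HR
value from the centered five-minute window.

Rejection rules (boundaries follow the stated inequality directions, so
equality is always accepted):

* resting files shorter than 7.5 minutes;
* resting files with more than 20 % of beats filtered;
* activity files with no heart-rate data at all;
* activity files whose mean heart rate over beat rows is below 80 bpm.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Optional, Sequence

import numpy as np

from .am_format import AMFile, MODE_ACTIVITY, MODE_RESTING, PrescriptionRecord

__all__ = [
    "QCResult",
    "SessionSummary",
    "FeedbackEvent",
    "ModeError",
    "QCComputationError",
    "trailing_moving_average",
    "extract_beats",
    "filter_resting_beats",
    "resting_file_qc",
    "daily_hrrest",
    "activity_file_qc",
    "segment_and_summarize",
    "feedback_events",
]

# defaults for every tunable threshold; callers may override per call
BEAT_MA_WINDOW = 10
BEAT_MA_DELTA = 0.25
BEAT_ABS_LO = 30.0
BEAT_ABS_HI = 220.0
MIN_RESTING_MINUTES = 7.5
MAX_FRACTION_FILTERED = 0.20
MIN_ACTIVITY_MEAN_HR = 80.0
RESTING_WINDOW_MINUTES = 5.0
FEEDBACK_MA_WINDOW = 5

REASON_OK = "ok"
REASON_NO_HR = "no_hr"
REASON_LOW_MEAN_HR = "low_mean_hr"
REASON_TOO_SHORT = "too_short"
REASON_OVER_FILTERED = "over_filtered"
REASON_EMPTY = "empty"


class ModeError(ValueError):
    """A file of the wrong recording mode was passed to a QC routine."""


class QCComputationError(ValueError):
    """An accepted file could not yield the requested quantity."""


@dataclass(frozen=True)
class QCResult:
    accepted: bool
    reason: str
    fraction_filtered: Optional[float] = None
    mean_hr: Optional[float] = None

    def __post_init__(self) -> None:
        assert self.accepted == (self.reason == REASON_OK)


@dataclass(frozen=True)
class SessionSummary:
    """Minute accounting and endurance-phase mean HR for one activity file."""

    day: date
    total_min: float
    endurance_min: float
    endurance_mean_hr: Optional[float]


@dataclass(frozen=True)
class FeedbackEvent:
    """In-session light cue: a phase boundary or a target-zone violation entry."""

    t_offset: float  # seconds
    kind: str


PHASE_END_WARMUP = "phase_end_warmup"
PHASE_END_ENDURANCE = "phase_end_endurance"
PHASE_END_COOLDOWN = "phase_end_cooldown"
ABOVE_ZONE = "above_zone"
BELOW_ZONE = "below_zone"


def trailing_moving_average(series: Sequence[float], window: int) -> np.ndarray:
    """Trailing mean with a partial window at the start.

    Element ``i`` is the mean of elements ``max(0, i-window+1) .. i``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=np.float64)
    if x.size == 0:
        return x.copy()
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    out = np.empty(n, dtype=np.float64)
    head = min(window, n)
    out[:head] = c[1 : head + 1] / np.arange(1, head + 1)
    if n > window:
        out[window:] = (c[window + 1 :] - c[1 : n - window + 1]) / window
    return out


def extract_beats(f: AMFile) -> tuple[np.ndarray, np.ndarray]:
    """Return (hr values, t_offset seconds) of all beat rows (``hr > 0``)."""
    mask = f.hr > 0
    return f.hr[mask].astype(np.float64), f.t_offset[mask]


def filter_resting_beats(
    beats: Sequence[float],
    window: int = BEAT_MA_WINDOW,
    delta: float = BEAT_MA_DELTA,
    abs_lo: float = BEAT_ABS_LO,
    abs_hi: float = BEAT_ABS_HI,
) -> tuple[np.ndarray, float]:
    """Remove aberrant beats; return (clean beats, fraction removed).

    A beat is removed when it lies outside ``[abs_lo, abs_hi]`` bpm or when
    it deviates from the trailing ``window``-beat moving average by more
    than the relative fraction ``delta``.
    """
    b = np.asarray(beats, dtype=np.float64)
    if b.size == 0:
        return b.copy(), 1.0
    ma = trailing_moving_average(b, window)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(b - ma) / ma
    removed = (b < abs_lo) | (b > abs_hi) | (rel > delta)
    clean = b[~removed]
    return clean, float(removed.sum()) / float(b.size)


def resting_file_qc(
    f: AMFile,
    min_minutes: float = MIN_RESTING_MINUTES,
    max_fraction: float = MAX_FRACTION_FILTERED,
    window: int = BEAT_MA_WINDOW,
    delta: float = BEAT_MA_DELTA,
) -> QCResult:
    """Accept or reject a resting recording for daily resting-HR use."""
    if f.mode != MODE_RESTING:
        raise ModeError(f"resting_file_qc needs a resting file, got mode {f.mode!r}")
    if f.is_empty:
        return QCResult(False, REASON_EMPTY, fraction_filtered=1.0)
    if f.duration_minutes < min_minutes:
        return QCResult(False, REASON_TOO_SHORT)
    beats, _t = extract_beats(f)
    if beats.size == 0:
        return QCResult(False, REASON_NO_HR, fraction_filtered=1.0)
    clean, fraction = filter_resting_beats(beats, window=window, delta=delta)
    if fraction > max_fraction:
        return QCResult(False, REASON_OVER_FILTERED, fraction_filtered=fraction)
    return QCResult(
        True,
        REASON_OK,
        fraction_filtered=fraction,
        mean_hr=float(clean.mean()) if clean.size else None,
    )


def daily_hrrest(
    f: AMFile,
    window_minutes: float = RESTING_WINDOW_MINUTES,
    ma_window: int = BEAT_MA_WINDOW,
    delta: float = BEAT_MA_DELTA,
) -> float:
    """Daily resting HR: mean of clean beats in the centered five-minute window.

    For a 10-minute recording this is minutes 2.5-7.5; shorter accepted
    files use the same window centered at their midpoint.
    """
    if f.mode != MODE_RESTING:
        raise ModeError(f"daily_hrrest needs a resting file, got mode {f.mode!r}")
    beats, t = extract_beats(f)
    if beats.size == 0:
        raise QCComputationError("no beats recorded")
    ma = trailing_moving_average(beats, ma_window)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(beats - ma) / ma
    keep = ~((beats < BEAT_ABS_LO) | (beats > BEAT_ABS_HI) | (rel > delta))
    mid = f.duration_minutes * 60.0 / 2.0
    half = window_minutes * 60.0 / 2.0
    in_win = keep & (t >= mid - half) & (t < mid + half)
    if not in_win.any():
        raise QCComputationError("no clean beats inside the centered window")
    return float(beats[in_win].mean())


def activity_file_qc(
    f: AMFile, min_mean_hr: float = MIN_ACTIVITY_MEAN_HR
) -> QCResult:
    """Accept or reject an activity recording for dose accounting."""
    if f.mode != MODE_ACTIVITY:
        raise ModeError(f"activity_file_qc needs an activity file, got mode {f.mode!r}")
    if f.is_empty:
        return QCResult(False, REASON_EMPTY)
    beats, _t = extract_beats(f)
    if beats.size == 0:
        return QCResult(False, REASON_NO_HR)
    mean_hr = float(beats.mean())
    if mean_hr < min_mean_hr:
        return QCResult(False, REASON_LOW_MEAN_HR, mean_hr=mean_hr)
    return QCResult(True, REASON_OK, mean_hr=mean_hr)


def segment_and_summarize(f: AMFile, p: PrescriptionRecord) -> SessionSummary:
    """Split a session into warm-up / endurance / cool-down by recorded time.

    Warm-up is the first ``p.warmup_min`` recorded minutes and cool-down the
    last ``p.cooldown_min``; whatever remains is endurance.  Files no longer
    than warm-up + cool-down have zero endurance and no endurance mean HR.
    """
    total_min = f.duration_minutes
    endurance_min = max(total_min - p.warmup_min - p.cooldown_min, 0.0)
    mean_hr: Optional[float] = None
    if endurance_min > 0:
        t = f.t_offset
        lo = p.warmup_min * 60.0
        hi = (total_min - p.cooldown_min) * 60.0
        mask = (t >= lo) & (t < hi) & (f.hr > 0)
        if mask.any():
            mean_hr = float(f.hr[mask].astype(np.float64).mean())
    return SessionSummary(
        day=f.file_date,
        total_min=total_min,
        endurance_min=endurance_min,
        endurance_mean_hr=mean_hr,
    )


def feedback_events(
    f: AMFile,
    p: PrescriptionRecord,
    ma_window: int = FEEDBACK_MA_WINDOW,
) -> list[FeedbackEvent]:
    """Reconstruct the monitor's in-session light cues as an event stream.

    Phase-end events fall at the prescribed phase boundaries.  During the
    endurance phase only, a trailing ``ma_window``-beat moving average of
    instantaneous HR is tracked and an event is emitted each time it
    *enters* violation of the target zone (above or below), not per row.
    """
    if p.kind == "rest":
        raise ValueError("no feedback for a rest day")
    events: list[FeedbackEvent] = []
    t_wu = p.warmup_min * 60.0
    t_end = (p.warmup_min + p.endurance_min) * 60.0
    t_cd = (p.warmup_min + p.endurance_min + p.cooldown_min) * 60.0
    events.append(FeedbackEvent(t_wu, PHASE_END_WARMUP))
    events.append(FeedbackEvent(t_end, PHASE_END_ENDURANCE))
    events.append(FeedbackEvent(t_cd, PHASE_END_COOLDOWN))

    beats, t = extract_beats(f)
    if beats.size:
        ma = trailing_moving_average(beats, ma_window)
        state = "in"
        for i in range(beats.size):
            if not (t_wu <= t[i] < t_end):
                continue
            if ma[i] > p.zone_hi_bpm:
                if state != "above":
                    events.append(FeedbackEvent(float(t[i]), ABOVE_ZONE))
                state = "above"
            elif ma[i] < p.zone_lo_bpm:
                if state != "below":
                    events.append(FeedbackEvent(float(t[i]), BELOW_ZONE))
                state = "below"
            else:
                state = "in"
    events.sort(key=lambda e: (e.t_offset, e.kind))
    return events
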