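"""Synthetic participants: physiology, compliance, monitor files, closed loop.

Replaces the physical monitor and human subjects.  A
:class:`PhysiologyProfile` defines true resting HR (with a weekly training
drift), maximum HR, endurance-intensity bias relative to the prescribed
zone, beat noise, and an artifact rate; a :class:`ComplianceProfile`
defines session-completion and upload behavior, including upload lag and
blackout windows with no server contact.

All randomness flows from one integer seed through
``numpy.random.default_rng`` seed sequences, so every output — file bytes,
store tables, event logs — is reproducible bit-for-bit.

Acceleration channels carry plausible magnitudes only; no quality-control
or dose rule ever reads them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, time, timedelta
from typing import Optional, Sequence

import numpy as np

from .am_format import (
    AMFile,
    KIND_OPTIONAL,
    KIND_REST,
    MODE_ACTIVITY,
    MODE_RESTING,
    PrescriptionRecord,
    SAMPLE_RATE,
    monitor_filename,
)
from .admin_monitor import (
    IngestOutcome,
    Store,
    TriggerEvent,
    ingest_uploads,
    milestone_emails,
    scan_triggers,
)
from .metrics import WeeklyDose, completed_hrr, weekly_dose
from .prescription import (
    InterventionEngine,
    ParticipantProfile,
    PlanWeek,
    WEEKS,
)

__all__ = [
    "PhysiologyProfile",
    "ComplianceProfile",
    "SimulationResult",
    "simulate_resting_file",
    "simulate_activity_file",
    "run_closed_loop",
    "preset_profiles",
    "PRESET_NAMES",
]

DEFAULT_START = date(2025, 1, 6)  # a Monday; arbitrary but fixed
RESTING_TIME = time(7, 0, 0)
ACTIVITY_TIME = time(18, 0, 0)


@dataclass(frozen=True)
class PhysiologyProfile:
    """True cardiovascular parameters of a synthetic participant."""

    hrrest0: float
    hrmax: float
    hrrest_drift: float = 0.0  # bpm per week; negative = training adaptation
    zone_bias: float = 0.0  # fraction of zone width off the zone midpoint
    hr_noise_sd: float = 2.0  # bpm
    aberrant_rate: float = 0.0  # per-beat artifact probability

    def __post_init__(self) -> None:
        if self.hrrest0 >= self.hrmax:
            raise ValueError("hrrest0 must be below hrmax")
        if not (0.0 <= self.aberrant_rate <= 0.5):
            raise ValueError("aberrant_rate must lie in [0, 0.5]")

    def true_hrrest(self, day_index: int) -> float:
        return self.hrrest0 + self.hrrest_drift * (day_index / 7.0)


@dataclass(frozen=True)
class ComplianceProfile:
    """Behavioral parameters of a synthetic participant."""

    p_mandatory: float = 1.0
    p_optional: float = 0.0
    p_resting: float = 1.0
    upload_lag_days: tuple[float, ...] = (1.0,)  # P(lag = 0, 1, 2, ...)
    blackout_windows: tuple[tuple[int, int], ...] = ()  # inclusive day ranges
    p_mandatory_late: Optional[float] = None  # replaces p_mandatory from ...
    dropoff_week: Optional[int] = None  # ... this calendar week onward

    def __post_init__(self) -> None:
        for name in ("p_mandatory", "p_optional", "p_resting"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.upload_lag_days) - 1.0) > 1e-9:
            raise ValueError("upload_lag_days must sum to 1")

    def p_session(self, week: int, kind: str) -> float:
        if kind == KIND_OPTIONAL:
            return self.p_optional
        if self.dropoff_week is not None and week >= self.dropoff_week:
            return self.p_mandatory_late if self.p_mandatory_late is not None else (
                self.p_mandatory
            )
        return self.p_mandatory

    def in_blackout(self, day_index: int) -> bool:
        return any(a <= day_index <= b for a, b in self.blackout_windows)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, *stream])


def simulate_resting_file(
    phys: PhysiologyProfile,
    day_index: int,
    seed: int,
    user_id: str = "sim",
    start_date: date = DEFAULT_START,
    duration_min: float = 10.0,
) -> AMFile:
    """A supine morning recording: beat rows at ~1 Hz amid zero rows."""
    rng = _rng(seed, 1, day_index)
    n = int(round(duration_min * 60 * SAMPLE_RATE))
    hr = np.zeros(n, dtype=np.uint8)
    true = phys.true_hrrest(day_index) + rng.normal(0.0, 0.5)
    true = float(np.clip(true, 35.0, 110.0))
    t = rng.uniform(0.2, 1.0)
    duration_s = duration_min * 60.0
    while t < duration_s:
        val = true + rng.normal(0.0, phys.hr_noise_sd)
        if rng.random() < phys.aberrant_rate:
            val = rng.uniform(120, 200) if rng.random() < 0.5 else rng.uniform(30, 45)
        row = int(t * SAMPLE_RATE)
        if row < n:
            hr[row] = int(np.clip(round(val), 20, 250))
        t += 60.0 / true
    accel = np.empty((n, 3), dtype=np.int16)
    accel[:, 0] = np.clip(rng.normal(0, 15, n), -8000, 8000).astype(np.int16)
    accel[:, 1] = np.clip(rng.normal(0, 15, n), -8000, 8000).astype(np.int16)
    accel[:, 2] = np.clip(rng.normal(1000, 15, n), -8000, 8000).astype(np.int16)
    d = start_date + timedelta(days=day_index - 1)
    return AMFile(
        user_id=user_id,
        file_date=d,
        file_time=RESTING_TIME,
        mode=MODE_RESTING,
        t_ds=np.arange(n, dtype=np.uint32),
        accel_mg=accel,
        hr=hr,
        source_name=monitor_filename(user_id, d, RESTING_TIME, MODE_RESTING),
    )


def simulate_activity_file(
    phys: PhysiologyProfile,
    p: PrescriptionRecord,
    seed: int,
    user_id: str = "sim",
    day_index: int = 1,
    ar_coef: float = 0.9,
) -> AMFile:
    """A session recording matching its prescription's total duration.

    Heart rate ramps from resting toward the zone during warm-up, tracks
    ``zone midpoint + zone_bias * zone width`` plus first-order
    autocorrelated noise through endurance, and decays during cool-down.
    Every row carries an HR value (continuous monitoring).
    """
    if p.kind == KIND_REST:
        raise ValueError("cannot simulate a session for a rest day")
    rng = _rng(seed, 2, day_index)
    rest = phys.true_hrrest(day_index)
    width = float(p.zone_hi_bpm - p.zone_lo_bpm)
    mid = (p.zone_lo_bpm + p.zone_hi_bpm) / 2.0
    target = mid + phys.zone_bias * width

    n_wu = p.warmup_min * 60 * SAMPLE_RATE
    n_en = p.endurance_min * 60 * SAMPLE_RATE
    n_cd = p.cooldown_min * 60 * SAMPLE_RATE
    n = n_wu + n_en + n_cd

    hr = np.empty(n, dtype=np.float64)
    hr[:n_wu] = rest + (target - rest) * np.linspace(0.0, 1.0, n_wu, endpoint=False)
    # AR(1) noise with stationary sd = hr_noise_sd
    eps_sd = phys.hr_noise_sd * math.sqrt(max(1.0 - ar_coef**2, 1e-12))
    noise = np.empty(n_en)
    x = 0.0
    shocks = rng.normal(0.0, eps_sd, n_en)
    for i in range(n_en):
        x = ar_coef * x + shocks[i]
        noise[i] = x
    hr[n_wu : n_wu + n_en] = target + noise
    hr[n_wu + n_en :] = target + (rest + 10.0 - target) * np.linspace(
        0.0, 1.0, n_cd, endpoint=False
    )
    hr_rows = np.clip(np.round(hr), 25, 250).astype(np.uint8)

    tt = np.arange(n) / SAMPLE_RATE
    stride = 2.0 * math.pi * 1.5  # ~1.5 steps/s gait oscillation
    accel = np.empty((n, 3), dtype=np.int16)
    accel[:, 0] = np.clip(
        300 * np.sin(stride * tt) + rng.normal(0, 50, n), -8000, 8000
    ).astype(np.int16)
    accel[:, 1] = np.clip(rng.normal(0, 50, n), -8000, 8000).astype(np.int16)
    accel[:, 2] = np.clip(
        1000 + 400 * np.cos(stride * tt) + rng.normal(0, 50, n), -8000, 8000
    ).astype(np.int16)
    return AMFile(
        user_id=user_id,
        file_date=p.date,
        file_time=ACTIVITY_TIME,
        mode=MODE_ACTIVITY,
        t_ds=np.arange(n, dtype=np.uint32),
        accel_mg=accel,
        hr=hr_rows,
        source_name=monitor_filename(user_id, p.date, ACTIVITY_TIME, MODE_ACTIVITY),
    )


@dataclass
class SimulationResult:
    store: Store
    events: list[TriggerEvent]
    weekly_doses: list[WeeklyDose]
    state_history: list[dict]
    prescriptions: list[PrescriptionRecord]
    engine: InterventionEngine


def run_closed_loop(
    phys: PhysiologyProfile,
    compliance: ComplianceProfile,
    weeks: int = WEEKS,
    seed: int = 0,
    user_id: str = "sim",
    start_date: date = DEFAULT_START,
    framework: Optional[dict[int, PlanWeek]] = None,
    baseline_measured: bool = True,
) -> SimulationResult:
    """Drive the full prescribe -> behave -> upload -> ingest -> advance loop.

    Fully deterministic given ``seed``.  ``weeks`` may be at most the
    engine's 12-week window; shorter runs are useful in tests.
    """
    if not (1 <= weeks <= WEEKS):
        raise ValueError(f"weeks must lie in 1..{WEEKS}")
    profile = ParticipantProfile(
        user_id=user_id,
        sex="M",
        hrmax=phys.hrmax,
        start_date=start_date,
        baseline_hrrest=round(phys.hrrest0) if baseline_measured else None,
    )
    engine = InterventionEngine(profile, framework=framework)
    store = Store(profile)
    behavior = _rng(seed, 3)
    total_days = weeks * 7
    pending: dict[int, list[AMFile]] = {}
    completed_by_week: dict[int, list[tuple[float, float]]] = {}
    week_rows: dict[int, tuple[PlanWeek, int]] = {}
    state_history: list[dict] = []
    prescriptions: list[PrescriptionRecord] = []
    milestones = {ev.date: ev for ev in milestone_emails(profile)}

    def schedule_upload(f: AMFile, day_index: int) -> None:
        lag = int(behavior.choice(len(compliance.upload_lag_days),
                                  p=compliance.upload_lag_days))
        up = day_index + lag
        while compliance.in_blackout(up):
            up = max(b for a, b in compliance.blackout_windows if a <= up <= b) + 1
        if up <= total_days:
            pending.setdefault(up, []).append(f)

    for day in range(1, total_days + 1):
        d = start_date + timedelta(days=day - 1)
        cweek = (day - 1) // 7 + 1
        presc = engine.prescription_for(d)
        prescriptions.append(presc)
        week_rows.setdefault(
            cweek, (engine.state.framework[presc.plan_week], 3)
        )
        blackout = compliance.in_blackout(day)

        # prescription download (the optional day counts toward recommended
        # volume only if its file was actually fetched)
        if not blackout:
            if presc.kind == KIND_OPTIONAL:
                if behavior.random() < compliance.p_optional:
                    store.day(d).prescription_downloaded = True
                    engine.note_optional_download()
                    row, _ = week_rows[cweek]
                    week_rows[cweek] = (row, 4)
            else:
                store.day(d).prescription_downloaded = True

        # participant behavior: record files, schedule uploads
        if behavior.random() < compliance.p_resting:
            rf = simulate_resting_file(phys, day, seed, user_id=user_id,
                                       start_date=start_date)
            schedule_upload(rf, day)
        do_session = False
        if presc.kind == KIND_OPTIONAL:
            do_session = store.day(d).prescription_downloaded
        elif presc.is_activity:
            do_session = behavior.random() < compliance.p_session(cweek, presc.kind)
        if do_session:
            af = simulate_activity_file(phys, presc, seed, user_id=user_id,
                                        day_index=day)
            schedule_upload(af, day)

        # server side: ingest whatever arrived today
        outcomes: list[IngestOutcome] = []
        if day in pending:
            outcomes = ingest_uploads(pending.pop(day), store, d)
        for out in outcomes:
            if out.status != "stored":
                continue
            if out.mode == MODE_RESTING and out.resting_value is not None:
                engine.note_resting(out.file_date, out.resting_value)
            elif out.mode == MODE_ACTIVITY and out.summary is not None:
                if not out.late:
                    engine.credit_activity(out.summary.endurance_min)
                if out.summary.endurance_mean_hr is not None:
                    fweek = (out.file_date - start_date).days // 7 + 1
                    rest_day = store.day(out.file_date).resting_value
                    if rest_day is None:
                        rest_day = engine.state.effective_hrrest
                    hrr = completed_hrr(out.summary.endurance_mean_hr, rest_day,
                                        phys.hrmax)
                    completed_by_week.setdefault(fweek, []).append(
                        (out.summary.endurance_min, hrr)
                    )

        engine.advance_day(d)
        scan_triggers(store, d)
        if d in milestones:
            store.add_event(milestones[d])
        state_history.append({"date": d.isoformat(), **engine.state.snapshot()})

    doses = []
    for wk in range(1, weeks + 1):
        row, sessions = week_rows[wk]
        doses.append(
            weekly_dose(
                wk, sessions, row.endurance_min, row.pct_lo, row.pct_hi,
                completed_by_week.get(wk, ()), sex=profile.sex,
            )
        )
    return SimulationResult(
        store=store,
        events=list(store.events),
        weekly_doses=doses,
        state_history=state_history,
        prescriptions=prescriptions,
        engine=engine,
    )


_PRESETS = {
    # sustained full compliance with a clear training adaptation
    "adherent": (
        PhysiologyProfile(hrrest0=65.0, hrmax=190.0, hrrest_drift=-0.4,
                          zone_bias=0.0, hr_noise_sd=2.0, aberrant_rate=0.02),
        ComplianceProfile(p_mandatory=1.0, p_optional=0.3, p_resting=1.0,
                          upload_lag_days=(1.0,)),
    ),
    # strong start, sparse sessions from week four, offline for weeks 9-12
    "sporadic": (
        PhysiologyProfile(hrrest0=70.0, hrmax=185.0, hrrest_drift=-0.1,
                          zone_bias=-0.3, hr_noise_sd=3.0, aberrant_rate=0.05),
        ComplianceProfile(p_mandatory=1.0, p_optional=0.1, p_resting=0.75,
                          upload_lag_days=(0.6, 0.3, 0.1),
                          p_mandatory_late=0.35, dropoff_week=4,
                          blackout_windows=((57, 84),)),
    ),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset_profiles(name: str) -> tuple[PhysiologyProfile, ComplianceProfile]:
    """Documented parameter sets for the two reference behavior patterns."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
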