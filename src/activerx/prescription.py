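"""The closed-loop prescription engine.

A 12-week walking/running progression is parameterized by a per-week table
(sessions, %heart-rate-reserve intensity band, endurance minutes) shipped
as ``data/framework.tsv``.  Each participant's position in the loop is an
:class:`InterventionState`: the *calendar* week counts elapsed real weeks,
while the *plan* week indexes the progression table and only advances when
the weekly compliance gate passes.

Rules implemented here:

* target zones come from the heart-rate-reserve (Karvonen) formula
  ``HRrest + pct/100 * (HRmax - HRrest)``, rounded half-up to integer bpm,
  re-personalized each week from the measured weekly mean resting HR;
* weekly sessions follow the fixed pattern M, rest, M, rest, M, optional,
  rest (three mandatory sessions, an optional fourth on day six, never more
  than two consecutive activity days);
* from the end of week two onward the plan advances only when completed
  endurance minutes reach 70 % of the recommended weekly total (week one
  always advances; equality passes); the optional session's minutes join
  the recommended total only if its prescription was downloaded;
* the first activity session of calendar week 12 is a 12-minute field test,
  and the plan week is forced to 12 for calendar week 12 regardless of
  compliance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .am_format import (
    KIND_EFT,
    KIND_MANDATORY,
    KIND_OPTIONAL,
    KIND_REST,
    PrescriptionRecord,
    ValidationError,
)
from .signal_qc import SessionSummary

__all__ = [
    "ParticipantProfile",
    "PlanWeek",
    "InterventionState",
    "TargetHRZone",
    "InterventionEngine",
    "SequencingError",
    "WindowError",
    "DEFAULT_HRREST",
    "COMPLIANCE_FRACTION",
    "WEEKS",
    "EFT_ENDURANCE_MIN",
    "load_framework",
    "default_framework",
    "target_hr_zone",
    "weekly_effective_hrrest",
    "schedule_week",
    "next_prescription",
    "weekly_compliance_check",
    "recommended_weekly_minutes",
    "ADVANCE",
    "HOLD",
]

DEFAULT_HRREST = 65.0  # substituted when no measurement and no baseline exist
COMPLIANCE_FRACTION = 0.70
WEEKS = 12
EFT_ENDURANCE_MIN = 12
WARMUP_MIN = 5
COOLDOWN_MIN = 5

ADVANCE = "advance"
HOLD = "hold"

DAY_PATTERN: tuple[str, ...] = (
    KIND_MANDATORY,
    KIND_REST,
    KIND_MANDATORY,
    KIND_REST,
    KIND_MANDATORY,
    KIND_OPTIONAL,
    KIND_REST,
)


class SequencingError(ValueError):
    """Days must be advanced one at a time, in order."""


class WindowError(ValueError):
    """A date outside the 12-calendar-week intervention window."""


@dataclass(frozen=True)
class PlanWeek:
    """One row of the progression table."""

    week_no: int
    sessions_min: int
    sessions_max: int
    pct_lo: int
    pct_hi: int
    endurance_min: int


@dataclass(frozen=True)
class ParticipantProfile:
    user_id: str
    sex: str  # "M" or "F"
    hrmax: float
    start_date: date
    baseline_hrrest: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not (100 <= self.hrmax <= 220):
            raise ValidationError(f"hrmax {self.hrmax} outside [100, 220]")
        if self.baseline_hrrest is not None:
            if not (30 <= self.baseline_hrrest <= 120):
                raise ValidationError(
                    f"baseline_hrrest {self.baseline_hrrest} outside [30, 120]"
                )
            if self.baseline_hrrest >= self.hrmax:
                raise ValidationError("baseline_hrrest must be below hrmax")


@dataclass(frozen=True)
class TargetHRZone:
    lo_bpm: int
    hi_bpm: int


def load_framework(path: Union[str, Path, None] = None) -> dict[int, PlanWeek]:
    """Load the progression table from TSV (the packaged default if no path)."""
    if path is None:
        text = (
            resources.files("activerx").joinpath("data/framework.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    expected = ["week_no", "sessions_min", "sessions_max", "pct_lo", "pct_hi",
                "endurance_min"]
    if header != expected:
        raise ValidationError(f"framework table header {header} != {expected}")
    table: dict[int, PlanWeek] = {}
    for ln in lines[1:]:
        vals = [int(v) for v in ln.split("\t")]
        row = PlanWeek(*vals)
        if row.pct_lo >= row.pct_hi or row.endurance_min <= 0:
            raise ValidationError(f"bad framework row {row}")
        table[row.week_no] = row
    if sorted(table) != list(range(1, len(table) + 1)):
        raise ValidationError("framework weeks must be contiguous from 1")
    return table


_DEFAULT_FRAMEWORK: dict[int, PlanWeek] | None = None


def default_framework() -> dict[int, PlanWeek]:
    global _DEFAULT_FRAMEWORK
    if _DEFAULT_FRAMEWORK is None:
        _DEFAULT_FRAMEWORK = load_framework()
    return _DEFAULT_FRAMEWORK


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def target_hr_zone(
    hrrest: float, hrmax: float, pct_lo: float, pct_hi: float
) -> TargetHRZone:
    """Heart-rate-reserve target zone, rounded half-up to integer bpm."""
    if hrrest >= hrmax:
        raise ValidationError(f"hrrest {hrrest} must be below hrmax {hrmax}")
    if not (0 < pct_lo < pct_hi <= 100):
        raise ValidationError(f"need 0 < pct_lo < pct_hi <= 100, got ({pct_lo}, {pct_hi})")
    reserve = hrmax - hrrest
    lo = _round_half_up(hrrest + pct_lo / 100.0 * reserve)
    hi = _round_half_up(hrrest + pct_hi / 100.0 * reserve)
    return TargetHRZone(lo, hi)


def weekly_effective_hrrest(
    ledger: Mapping[date, float],
    week: int,
    profile: ParticipantProfile,
    default_hrrest: float = DEFAULT_HRREST,
) -> float:
    """Resting HR used for week ``week``'s zones.

    Mean of the daily values measured during the preceding calendar week;
    falling back to the most recent prior week with data, then the baseline
    measurement, then the global default.
    """
    if week < 1:
        raise ValidationError(f"week {week} must be >= 1")
    for wk in range(week - 1, 0, -1):
        w0 = profile.start_date + timedelta(days=7 * (wk - 1))
        vals = [
            ledger[w0 + timedelta(days=i)]
            for i in range(7)
            if (w0 + timedelta(days=i)) in ledger
            and ledger[w0 + timedelta(days=i)] is not None
        ]
        if vals:
            return float(sum(vals)) / len(vals)
    if profile.baseline_hrrest is not None:
        return float(profile.baseline_hrrest)
    return float(default_hrrest)


def schedule_week(plan_week: int) -> tuple[str, ...]:
    """Kinds of the seven days of any intervention week."""
    if not (1 <= plan_week <= 12):
        raise ValidationError(f"plan_week {plan_week} outside 1-12")
    return DAY_PATTERN


def recommended_weekly_minutes(row: PlanWeek, optional_downloaded: bool) -> float:
    """Recommended endurance minutes for one week under a table row."""
    rec = row.sessions_min * row.endurance_min
    if optional_downloaded:
        rec += row.endurance_min
    return float(rec)


def weekly_compliance_check(
    completed_min: float,
    recommended_min: float,
    fraction: float = COMPLIANCE_FRACTION,
) -> str:
    """Advance iff completed minutes reach ``fraction`` of recommended.

    Strictly-less-than fails, so exact equality at the threshold advances.
    """
    if recommended_min <= 0:
        return ADVANCE
    # epsilon absorbs float representation of fraction*recommended
    return ADVANCE if completed_min / recommended_min >= fraction - 1e-12 else HOLD


@dataclass
class InterventionState:
    """A participant's position in the closed loop."""

    profile: ParticipantProfile
    framework: dict[int, PlanWeek]
    calendar_day: int = 0  # last completed day number (1-based); 0 = not started
    plan_week: int = 1
    effective_hrrest: float = DEFAULT_HRREST
    optional_downloaded: bool = False  # for the week in progress
    weekly_completed_min: float = 0.0
    daily_hrrest_ledger: dict[date, float] = field(default_factory=dict)
    advance_history: dict[int, str] = field(default_factory=dict)

    @property
    def calendar_week(self) -> int:
        """Week in progress (1 before any day has been advanced)."""
        return max(1, math.ceil((self.calendar_day + 1) / 7)) if (
            self.calendar_day < WEEKS * 7
        ) else WEEKS

    def snapshot(self) -> dict:
        return {
            "calendar_day": self.calendar_day,
            "calendar_week": self.calendar_week,
            "plan_week": self.plan_week,
            "effective_hrrest": self.effective_hrrest,
            "weekly_completed_min": self.weekly_completed_min,
            "optional_downloaded": self.optional_downloaded,
        }


def next_prescription(state: InterventionState, d: date) -> PrescriptionRecord:
    """The prescription for calendar date ``d`` under the current state."""
    day = (d - state.profile.start_date).days + 1
    if not (1 <= day <= WEEKS * 7):
        raise WindowError(f"{d} is outside the {WEEKS}-week intervention window")
    cweek = (day - 1) // 7 + 1
    dow = (day - 1) % 7  # 0-based position in the week pattern
    kind = DAY_PATTERN[dow]
    plan_week = WEEKS if cweek == WEEKS else min(state.plan_week, WEEKS)
    if kind == KIND_REST:
        return PrescriptionRecord(d, KIND_REST, 0, 0, 0, 0, 0, plan_week)
    row = state.framework[plan_week]
    zone = target_hr_zone(
        state.effective_hrrest, state.profile.hrmax, row.pct_lo, row.pct_hi
    )
    endurance = row.endurance_min
    if cweek == WEEKS and dow == _first_activity_dow():
        kind = KIND_EFT
        endurance = EFT_ENDURANCE_MIN
    return PrescriptionRecord(
        d, kind, WARMUP_MIN, endurance, COOLDOWN_MIN, zone.lo_bpm, zone.hi_bpm,
        plan_week,
    )


def _first_activity_dow() -> int:
    return next(i for i, k in enumerate(DAY_PATTERN) if k != KIND_REST)


class InterventionEngine:
    """Drives an :class:`InterventionState` one day at a time.

    Credit activity minutes and resting-HR measurements as they are
    ingested, then call :meth:`advance_day` once per calendar date; week
    rollovers (compliance gate, zone re-personalization) happen at every
    seventh day automatically.
    """

    def __init__(
        self,
        profile: ParticipantProfile,
        framework: Optional[dict[int, PlanWeek]] = None,
        compliance_fraction: float = COMPLIANCE_FRACTION,
        default_hrrest: float = DEFAULT_HRREST,
    ) -> None:
        self.compliance_fraction = compliance_fraction
        self.default_hrrest = default_hrrest
        fw = framework if framework is not None else default_framework()
        self.state = InterventionState(
            profile=profile,
            framework=fw,
            effective_hrrest=weekly_effective_hrrest({}, 1, profile, default_hrrest),
        )

    # -- queries ------------------------------------------------------
    def prescription_for(self, d: date) -> PrescriptionRecord:
        return next_prescription(self.state, d)

    # -- notifications from ingest ------------------------------------
    def note_resting(self, d: date, bpm: float) -> None:
        self.state.daily_hrrest_ledger[d] = float(bpm)

    def note_optional_download(self) -> None:
        self.state.optional_downloaded = True

    def credit_activity(self, endurance_min: float) -> None:
        """Credit qualifying endurance minutes toward this week's gate."""
        self.state.weekly_completed_min += float(endurance_min)

    # -- the daily tick ------------------------------------------------
    def advance_day(
        self, d: date, summaries: Iterable[SessionSummary] = ()
    ) -> None:
        st = self.state
        expected = st.profile.start_date + timedelta(days=st.calendar_day)
        if d != expected:
            raise SequencingError(f"expected day {expected}, got {d}")
        if st.calendar_day >= WEEKS * 7:
            raise WindowError("intervention window already complete")
        for s in summaries:
            self.credit_activity(s.endurance_min)
        st.calendar_day += 1
        if st.calendar_day % 7 == 0:
            self._week_rollover(st.calendar_day // 7)

    def _week_rollover(self, week: int) -> None:
        st = self.state
        row = st.framework[min(st.plan_week, WEEKS)]
        recommended = recommended_weekly_minutes(row, st.optional_downloaded)
        if week == 1:
            decision = ADVANCE  # the gate starts at the end of week two
        else:
            decision = weekly_compliance_check(
                st.weekly_completed_min, recommended, self.compliance_fraction
            )
        st.advance_history[week] = decision
        if decision == ADVANCE:
            st.plan_week = min(st.plan_week + 1, WEEKS)
        st.weekly_completed_min = 0.0
        st.optional_downloaded = False
        next_week = week + 1
        if next_week <= WEEKS:
            if next_week == WEEKS:
                st.plan_week = WEEKS  # field-test override, regardless of compliance
            st.effective_hrrest = weekly_effective_hrrest(
                st.daily_hrrest_ledger, next_week, st.profile, self.default_hrrest
            )
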