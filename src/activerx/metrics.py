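"""Training-impulse dose metrics and the pluggable field-test fitness estimate.

The dose of one session is ``TRIMP = duration_min * HRr * exp(k * HRr)``
with the sex-specific coefficient k = 1.92 (men) or 1.67 (women).  The
*recommended* HRr of a prescription is the midpoint of its intensity band
expressed as a fraction (a 40-50 % band gives 0.45).  The *completed* HRr
of a session defaults to the heart-rate-reserve reading
``(mean endurance HR - daily HRrest) / (HRmax - daily HRrest)``; a
``literal`` mode (mean HR divided by daily HRrest) is kept available
because both readings exist for the completed quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

__all__ = [
    "K_MALE",
    "K_FEMALE",
    "TrimpParams",
    "WeeklyDose",
    "ConfigurationError",
    "trimp",
    "recommended_hrr",
    "completed_hrr",
    "weekly_dose",
    "register_vo2peak_equation",
    "clear_vo2peak_equation",
    "estimate_vo2peak",
]

K_MALE = 1.92
K_FEMALE = 1.67
HRR_CLIP = 1.5


class ConfigurationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrimpParams:
    k_male: float = K_MALE
    k_female: float = K_FEMALE

    def k(self, sex: str) -> float:
        if sex == "M":
            return self.k_male
        if sex == "F":
            return self.k_female
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")


@dataclass(frozen=True)
class WeeklyDose:
    """Recommended vs completed volume for one calendar week."""

    week: int
    recommended_min: float
    completed_min: float
    recommended_trimp: float
    completed_trimp: float

    def __post_init__(self) -> None:
        for name in ("recommended_min", "completed_min", "recommended_trimp",
                     "completed_trimp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def trimp(
    duration_min: float,
    hrr: float,
    sex: str = "M",
    params: TrimpParams = TrimpParams(),
) -> float:
    """Training impulse of one session, in arbitrary units."""
    if duration_min < 0:
        raise ValueError("duration_min must be >= 0")
    if not (0 <= hrr <= HRR_CLIP):
        raise ValueError(f"hrr {hrr} outside [0, {HRR_CLIP}]")
    return duration_min * hrr * math.exp(params.k(sex) * hrr)


def recommended_hrr(pct_lo: float, pct_hi: float) -> float:
    """HRr of a prescribed band: the midpoint of the endpoints, as a fraction."""
    if not (0 < pct_lo < pct_hi <= 100):
        raise ValueError(f"need 0 < pct_lo < pct_hi <= 100, got ({pct_lo}, {pct_hi})")
    return (pct_lo + pct_hi) / 200.0


def completed_hrr(
    mean_endurance_hr: float,
    hrrest_day: float,
    hrmax: Optional[float] = None,
    mode: str = "reserve",
) -> float:
    """HRr achieved in a completed session.

    ``reserve`` (default): fraction of heart-rate reserve used, clipped to
    [0, 1.5].  ``literal``: mean endurance HR divided by the day's resting
    HR (dimensionally a different quantity; kept for comparison).
    """
    if mean_endurance_hr <= 0:
        raise ValueError("mean_endurance_hr must be > 0")
    if mode == "literal":
        return mean_endurance_hr / hrrest_day
    if mode != "reserve":
        raise ValueError(f"mode must be 'reserve' or 'literal', got {mode!r}")
    if hrmax is None:
        raise ValueError("reserve mode requires hrmax")
    if hrrest_day >= hrmax:
        raise ValueError("hrrest_day must be below hrmax")
    raw = (mean_endurance_hr - hrrest_day) / (hrmax - hrrest_day)
    return min(max(raw, 0.0), HRR_CLIP)


def weekly_dose(
    week: int,
    sessions: int,
    endurance_min: float,
    pct_lo: float,
    pct_hi: float,
    completed_sessions: Iterable[tuple[float, float]],
    sex: str = "M",
    params: TrimpParams = TrimpParams(),
) -> WeeklyDose:
    """Aggregate one week's dose.

    ``completed_sessions`` is an iterable of ``(endurance_min, hrr)`` pairs
    for the qualifying sessions of the week; ``sessions`` is the number of
    recommended sessions (3, or 4 if the optional prescription was
    downloaded).
    """
    rec_hrr = recommended_hrr(pct_lo, pct_hi)
    rec_trimp = sessions * trimp(endurance_min, rec_hrr, sex, params)
    comp_min = 0.0
    comp_trimp = 0.0
    for dur, hrr in completed_sessions:
        comp_min += dur
        comp_trimp += trimp(dur, hrr, sex, params)
    return WeeklyDose(
        week=week,
        recommended_min=sessions * endurance_min,
        completed_min=comp_min,
        recommended_trimp=rec_trimp,
        completed_trimp=comp_trimp,
    )


# -- field-test fitness estimate (plug-in only) ------------------------
# The distance -> VO2peak equation is intentionally not bundled: none is
# defined by this package, so callers must register their own.
_vo2peak_equation: Optional[Callable[[float], float]] = None


def register_vo2peak_equation(fn: Callable[[float], float]) -> None:
    global _vo2peak_equation
    _vo2peak_equation = fn


def clear_vo2peak_equation() -> None:
    global _vo2peak_equation
    _vo2peak_equation = None


def estimate_vo2peak(
    distance_m: float, equation: Optional[Callable[[float], float]] = None
) -> float:
    """Apply the registered (or passed) distance->VO2peak equation."""
    fn = equation if equation is not None else _vo2peak_equation
    if fn is None:
        raise ConfigurationError(
            "no VO2peak equation registered; supply one via "
            "register_vo2peak_equation() or the `equation` argument"
        )
    return float(fn(distance_m))
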