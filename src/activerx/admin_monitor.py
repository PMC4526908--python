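"""File management, trigger events, and daily logs over a text-backed store.

The store stands in for the original relational database: per-date rows
(daily resting value or null, concatenated activity minutes, per-file QC
outcomes, prescription-download flag) plus an append-only event list, all
serialized as headered tab-separated text files.

File-management rules implemented by :func:`ingest_uploads`:

* empty and repeated files are dropped by content fingerprint;
* every file is allocated to the date encoded in its filename, not the
  upload date;
* of multiple resting files on one date, the first that passes QC wins;
* multiple activity files on one date have their durations concatenated;
* activity files uploaded after their calendar week has rolled over are
  stored for credit but excluded from that week's adherence check.

Trigger events (one per streak, re-armed only after the condition clears):

* ``reminder_3day_hr`` on the 3rd consecutive date without an accepted
  resting value;
* ``survey_7day`` on the 7th consecutive date without any file upload;
* ``admin_no_download`` after consecutive days (default 3) in which the
  prescription was never downloaded;
* four ``milestone_email`` events (account creation, intervention start,
  the day before the field test, conclusion).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .am_format import (
    AMFile,
    MODE_ACTIVITY,
    MODE_RESTING,
    PrescriptionRecord,
    file_fingerprint,
)
from .prescription import WEEKS, ParticipantProfile
from .signal_qc import (
    QCComputationError,
    QCResult,
    SessionSummary,
    activity_file_qc,
    daily_hrrest,
    resting_file_qc,
    segment_and_summarize,
)

__all__ = [
    "StoreDay",
    "TriggerEvent",
    "IngestOutcome",
    "Store",
    "ingest_uploads",
    "scan_triggers",
    "milestone_emails",
    "daily_log",
    "REMINDER_3DAY_HR",
    "SURVEY_7DAY",
    "ADMIN_NO_DOWNLOAD",
    "MILESTONE_EMAIL",
]

REMINDER_3DAY_HR = "reminder_3day_hr"
SURVEY_7DAY = "survey_7day"
ADMIN_NO_DOWNLOAD = "admin_no_download"
MILESTONE_EMAIL = "milestone_email"

RESTING_REMINDER_DAYS = 3
UPLOAD_SURVEY_DAYS = 7
NO_DOWNLOAD_DAYS = 3

_DEFAULT_WARMUP = 5
_DEFAULT_COOLDOWN = 5


@dataclass
class StoreDay:
    date: date
    resting_value: Optional[float] = None  # null until a resting file passes QC
    activity_min: float = 0.0  # endurance minutes credited to this date
    activity_min_excluded: float = 0.0  # portion uploaded after week rollover
    files: list[tuple[str, str, QCResult]] = field(default_factory=list)
    prescription_downloaded: bool = False

    @property
    def qualifying_activity_min(self) -> float:
        return self.activity_min - self.activity_min_excluded


@dataclass(frozen=True)
class TriggerEvent:
    date: date
    kind: str
    detail: str


@dataclass(frozen=True)
class IngestOutcome:
    filename: str
    file_date: Optional[date]
    mode: Optional[str]
    status: str  # stored | duplicate | empty | rejected | error
    qc: Optional[QCResult] = None
    summary: Optional[SessionSummary] = None
    resting_value: Optional[float] = None
    late: bool = False


class Store:
    """Per-participant day ledger plus events, persistable as TSV tables."""

    def __init__(self, profile: ParticipantProfile) -> None:
        self.profile = profile
        self.days: dict[date, StoreDay] = {}
        self.fingerprints: set[str] = set()
        self.upload_dates: set[date] = set()
        self.events: list[TriggerEvent] = []
        self.rejects: list[tuple[str, str]] = []

    # -- access --------------------------------------------------------
    def day(self, d: date) -> StoreDay:
        if d not in self.days:
            self.days[d] = StoreDay(date=d)
        return self.days[d]

    def add_event(self, ev: TriggerEvent) -> bool:
        """Append unless an event of this kind already exists for this date."""
        for existing in self.events:
            if existing.date == ev.date and existing.kind == ev.kind:
                return False
        self.events.append(ev)
        return True

    def resting_ledger(self) -> dict[date, float]:
        return {
            d: sd.resting_value
            for d, sd in self.days.items()
            if sd.resting_value is not None
        }

    # -- persistence ---------------------------------------------------
    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "user.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["user_id", "sex", "hrmax", "baseline_hrrest", "start_date"])
            p = self.profile
            w.writerow([
                p.user_id, p.sex, p.hrmax,
                "" if p.baseline_hrrest is None else p.baseline_hrrest,
                p.start_date.isoformat(),
            ])
        with open(directory / "days.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow([
                "date", "resting_value", "activity_min", "activity_min_excluded",
                "prescription_downloaded", "uploaded",
            ])
            for d in sorted(self.days):
                sd = self.days[d]
                w.writerow([
                    d.isoformat(),
                    "null" if sd.resting_value is None else f"{sd.resting_value:.3f}",
                    f"{sd.activity_min:.3f}",
                    f"{sd.activity_min_excluded:.3f}",
                    int(sd.prescription_downloaded),
                    int(d in self.upload_dates),
                ])
        with open(directory / "files.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["date", "filename", "mode", "accepted", "reason",
                        "fraction_filtered", "mean_hr"])
            for d in sorted(self.days):
                for fname, mode, qc in self.days[d].files:
                    w.writerow([
                        d.isoformat(), fname, mode, int(qc.accepted), qc.reason,
                        "" if qc.fraction_filtered is None
                        else f"{qc.fraction_filtered:.4f}",
                        "" if qc.mean_hr is None else f"{qc.mean_hr:.2f}",
                    ])
        with open(directory / "events.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["date", "kind", "detail"])
            for ev in sorted(self.events, key=lambda e: (e.date, e.kind)):
                w.writerow([ev.date.isoformat(), ev.kind, ev.detail])
        with open(directory / "fingerprints.tsv", "w") as fh:
            fh.write("digest\n")
            for digest in sorted(self.fingerprints):
                fh.write(digest + "\n")

    @classmethod
    def read(cls, directory: str | Path) -> "Store":
        directory = Path(directory)
        with open(directory / "user.tsv", newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        r = rows[0]
        profile = ParticipantProfile(
            user_id=r["user_id"],
            sex=r["sex"],
            hrmax=float(r["hrmax"]),
            baseline_hrrest=float(r["baseline_hrrest"]) if r["baseline_hrrest"] else None,
            start_date=date.fromisoformat(r["start_date"]),
        )
        store = cls(profile)
        days_path = directory / "days.tsv"
        if days_path.exists():
            with open(days_path, newline="") as fh:
                for r in csv.DictReader(fh, delimiter="\t"):
                    d = date.fromisoformat(r["date"])
                    sd = store.day(d)
                    sd.resting_value = (
                        None if r["resting_value"] == "null"
                        else float(r["resting_value"])
                    )
                    sd.activity_min = float(r["activity_min"])
                    sd.activity_min_excluded = float(r["activity_min_excluded"])
                    sd.prescription_downloaded = bool(int(r["prescription_downloaded"]))
                    if int(r["uploaded"]):
                        store.upload_dates.add(d)
        files_path = directory / "files.tsv"
        if files_path.exists():
            with open(files_path, newline="") as fh:
                for r in csv.DictReader(fh, delimiter="\t"):
                    qc = QCResult(
                        accepted=bool(int(r["accepted"])),
                        reason=r["reason"],
                        fraction_filtered=(
                            float(r["fraction_filtered"])
                            if r["fraction_filtered"] else None
                        ),
                        mean_hr=float(r["mean_hr"]) if r["mean_hr"] else None,
                    )
                    store.day(date.fromisoformat(r["date"])).files.append(
                        (r["filename"], r["mode"], qc)
                    )
        fp_path = directory / "fingerprints.tsv"
        if fp_path.exists():
            lines = fp_path.read_text().splitlines()[1:]
            store.fingerprints.update(ln for ln in lines if ln)
        events_path = directory / "events.tsv"
        if events_path.exists():
            with open(events_path, newline="") as fh:
                for r in csv.DictReader(fh, delimiter="\t"):
                    store.events.append(
                        TriggerEvent(date.fromisoformat(r["date"]), r["kind"],
                                     r["detail"])
                    )
        return store


def _week_end(start_date: date, d: date) -> date:
    """Last date of the calendar week containing ``d``."""
    day = (d - start_date).days  # 0-based
    return start_date + timedelta(days=(day // 7) * 7 + 6)


def ingest_uploads(
    files: Sequence[AMFile],
    store: Store,
    upload_date: date,
) -> list[IngestOutcome]:
    """Apply the file-management rules to a batch uploaded on ``upload_date``."""
    outcomes: list[IngestOutcome] = []
    for f in files:
        name = f.source_name or f.default_name
        try:
            fp = file_fingerprint(f)
        except Exception as exc:  # malformed in-memory file
            store.rejects.append((name, str(exc)))
            outcomes.append(IngestOutcome(name, None, None, "error"))
            continue
        store.upload_dates.add(upload_date)
        if fp.empty:
            store.rejects.append((name, "empty file"))
            outcomes.append(IngestOutcome(name, f.file_date, f.mode, "empty"))
            continue
        if fp.digest in store.fingerprints:
            outcomes.append(IngestOutcome(name, f.file_date, f.mode, "duplicate"))
            continue
        store.fingerprints.add(fp.digest)
        sd = store.day(f.file_date)
        late = upload_date > _week_end(store.profile.start_date, f.file_date)
        if f.mode == MODE_RESTING:
            qc = resting_file_qc(f)
            sd.files.append((name, f.mode, qc))
            value = None
            if qc.accepted and sd.resting_value is None:
                try:
                    value = daily_hrrest(f)
                    sd.resting_value = value
                except QCComputationError:
                    value = None
            outcomes.append(
                IngestOutcome(name, f.file_date, f.mode,
                              "stored" if qc.accepted else "rejected",
                              qc=qc, resting_value=value, late=late)
            )
        else:
            qc = activity_file_qc(f)
            sd.files.append((name, f.mode, qc))
            summary = None
            if qc.accepted:
                proxy = PrescriptionRecord(
                    f.file_date, "mandatory", _DEFAULT_WARMUP,
                    max(int(round(f.duration_minutes)) or 1, 1),
                    _DEFAULT_COOLDOWN, 1, 2, 1,
                )
                summary = segment_and_summarize(f, proxy)
                sd.activity_min += summary.endurance_min
                if late:
                    sd.activity_min_excluded += summary.endurance_min
            outcomes.append(
                IngestOutcome(name, f.file_date, f.mode,
                              "stored" if qc.accepted else "rejected",
                              qc=qc, summary=summary, late=late)
            )
    return outcomes


def _streak_ending_at(store: Store, d: date, missing) -> int:
    """Length of the consecutive-day streak ending at ``d`` where ``missing``."""
    start = store.profile.start_date
    streak = 0
    cur = d
    while cur >= start and missing(store.days.get(cur), cur):
        streak += 1
        cur -= timedelta(days=1)
    return streak


def scan_triggers(
    store: Store,
    d: date,
    resting_days: int = RESTING_REMINDER_DAYS,
    upload_days: int = UPLOAD_SURVEY_DAYS,
    no_download_days: int = NO_DOWNLOAD_DAYS,
) -> list[TriggerEvent]:
    """Evaluate the streak triggers as of end-of-day ``d``.

    Each trigger fires exactly when its streak reaches the threshold, so a
    continuing streak does not re-fire until the condition has cleared.
    Appends new events to the store and returns them.
    """
    new: list[TriggerEvent] = []

    def fire(kind: str, detail: str) -> None:
        ev = TriggerEvent(d, kind, detail)
        if store.add_event(ev):
            new.append(ev)

    hr_streak = _streak_ending_at(
        store, d, lambda sd, _c: sd is None or sd.resting_value is None
    )
    if hr_streak == resting_days:
        fire(REMINDER_3DAY_HR,
             f"no accepted resting heart rate for {resting_days} consecutive days")

    up_streak = _streak_ending_at(
        store, d, lambda _sd, cur: cur not in store.upload_dates
    )
    if up_streak == upload_days:
        fire(SURVEY_7DAY, f"no file uploads for {upload_days} consecutive days")

    dl_streak = _streak_ending_at(
        store, d, lambda sd, _c: sd is None or not sd.prescription_downloaded
    )
    if dl_streak == no_download_days:
        fire(ADMIN_NO_DOWNLOAD,
             f"prescriptions not downloaded for {no_download_days} consecutive days")
    return new


def milestone_emails(
    profile: ParticipantProfile,
    account_creation: Optional[date] = None,
) -> list[TriggerEvent]:
    """The four fixed milestone emails, as events."""
    start = profile.start_date
    eft_day = start + timedelta(days=(WEEKS - 1) * 7)  # first activity day, week 12
    events = []
    if account_creation is not None:
        events.append(TriggerEvent(account_creation, MILESTONE_EMAIL,
                                   "account created"))
    events.append(TriggerEvent(start, MILESTONE_EMAIL, "intervention start"))
    events.append(TriggerEvent(eft_day - timedelta(days=1), MILESTONE_EMAIL,
                               "field test tomorrow"))
    events.append(TriggerEvent(start + timedelta(days=WEEKS * 7 - 1),
                               MILESTONE_EMAIL, "intervention complete"))
    return events


def daily_log(store: Store, d: date) -> list[str]:
    """Per-file QC lines plus a one-line summary for date ``d``."""
    lines: list[str] = []
    sd = store.days.get(d)
    if sd is not None:
        for fname, mode, qc in sd.files:
            frac = "" if qc.fraction_filtered is None else f"{qc.fraction_filtered:.4f}"
            mean = "" if qc.mean_hr is None else f"{qc.mean_hr:.2f}"
            lines.append(
                f"{d.isoformat()}\t{fname}\t{mode}\t"
                f"{'accepted' if qc.accepted else 'rejected'}\t{qc.reason}\t"
                f"{frac}\t{mean}"
            )
    resting = "null" if sd is None or sd.resting_value is None else (
        f"{sd.resting_value:.1f}"
    )
    activity = 0.0 if sd is None else sd.activity_min
    downloaded = bool(sd and sd.prescription_downloaded)
    lines.append(
        f"{d.isoformat()}\tSUMMARY\tresting={resting}\t"
        f"activity_min={activity:.1f}\tdownloaded={downloaded}"
    )
    return lines
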