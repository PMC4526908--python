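"""Binary dialects for activity-monitor recordings and daily prescriptions.

The monitor writes two kinds of files: ``activity`` recordings (continuous
triaxial acceleration plus heart rate) and ``resting`` recordings (ten
minutes of supine instantaneous heart rate).  Both share one container, the
AMB file: a 32-byte little-endian header followed by fixed-width 11-byte
rows.  Prescriptions travel the other way as single 16-byte records.

Layouts
-------
AMB header (32 bytes)::

    magic "AMB1" | user_id 8s (ASCII, space padded) | date uint32 YYYYMMDD
    | time uint32 HHMMSS | mode uint8 (1=activity, 2=resting)
    | sample_rate uint8 | reserved 6s | CRC32(payload) uint32

AMB row (11 bytes)::

    t_offset uint32 (deciseconds) | ax,ay,az int16 (milli-g) | hr uint8 (bpm)

Prescription record (16 bytes)::

    date uint32 YYYYMMDD | kind uint8 | warmup uint8 | endurance uint16
    | cooldown uint8 | zone_lo uint8 | zone_hi uint8 | plan_week uint8
    | crc8 uint8 | 3 pad bytes

A row's ``hr`` is the instantaneous heart rate registered at that row and 0
where no beat was detected; acceleration is quantized to milli-g within the
device's ±8 g range.  Writing then reading any valid value is exact.
"""

from __future__ import annotations

import hashlib
import re
import struct
import zlib
from dataclasses import dataclass
from datetime import date, time
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence, Union

import numpy as np

__all__ = [
    "AMB_MAGIC",
    "SAMPLE_RATE",
    "MODE_ACTIVITY",
    "MODE_RESTING",
    "KIND_MANDATORY",
    "KIND_OPTIONAL",
    "KIND_REST",
    "KIND_EFT",
    "ACTIVITY_KINDS",
    "AMFormatError",
    "ValidationError",
    "SampleRecord",
    "AMFile",
    "PrescriptionRecord",
    "Fingerprint",
    "parse_filename",
    "monitor_filename",
    "read_am_file",
    "write_am_file",
    "read_prescription_file",
    "write_prescription_file",
    "file_fingerprint",
]

AMB_MAGIC = b"AMB1"
SAMPLE_RATE = 10  # rows per second, dialect constant

MODE_ACTIVITY = "activity"
MODE_RESTING = "resting"
_MODE_TO_CODE = {MODE_ACTIVITY: 1, MODE_RESTING: 2}
_CODE_TO_MODE = {v: k for k, v in _MODE_TO_CODE.items()}
_MODE_TO_LETTER = {MODE_ACTIVITY: "A", MODE_RESTING: "R"}
_LETTER_TO_MODE = {v: k for k, v in _MODE_TO_LETTER.items()}

KIND_MANDATORY = "mandatory"
KIND_OPTIONAL = "optional"
KIND_REST = "rest"
KIND_EFT = "eft"
ACTIVITY_KINDS = frozenset({KIND_MANDATORY, KIND_OPTIONAL, KIND_EFT})
_KIND_TO_CODE = {KIND_MANDATORY: 1, KIND_OPTIONAL: 2, KIND_REST: 3, KIND_EFT: 4}
_CODE_TO_KIND = {v: k for k, v in _KIND_TO_CODE.items()}

_HEADER = struct.Struct("<4s8sIIBB6sI")  # 32 bytes
_ROW = struct.Struct("<IhhhB")  # 11 bytes
_RX = struct.Struct("<IBBHBBBBB3x")  # 16 bytes

MAX_ACCEL_MG = 8000  # ±8 g device range
HR_MIN, HR_MAX = 20, 250

_FILENAME_RE = re.compile(
    r"^(?P<user>[A-Za-z0-9]{1,8})_(?P<date>\d{8})_(?P<time>\d{6})_(?P<mode>[AR])\.amb$"
)


class AMFormatError(ValueError):
    """Raised when bytes do not conform to the AMB or prescription dialect."""


class ValidationError(ValueError):
    """Raised when an in-memory record violates a dialect invariant."""


class SampleRecord(NamedTuple):
    """One fixed-rate row: seconds from file start, acceleration (g), HR (bpm)."""

    t_offset: float
    ax: float
    ay: float
    az: float
    hr: int


def _crc8(data: bytes, poly: int = 0x07) -> int:
    crc = 0
    for byte in data:
        crc ^= byte
        for _ in range(8):
            crc = ((crc << 1) ^ poly) & 0xFF if crc & 0x80 else (crc << 1) & 0xFF
    return crc


def _encode_date(d: date) -> int:
    return d.year * 10000 + d.month * 100 + d.day


def _decode_date(v: int, what: str) -> date:
    try:
        return date(v // 10000, (v // 100) % 100, v % 100)
    except ValueError as exc:
        raise AMFormatError(f"invalid {what} field {v!r}: {exc}") from None


def _encode_time(t: time) -> int:
    return t.hour * 10000 + t.minute * 100 + t.second


def _decode_time(v: int, what: str) -> time:
    try:
        return time(v // 10000, (v // 100) % 100, v % 100)
    except ValueError as exc:
        raise AMFormatError(f"invalid {what} field {v!r}: {exc}") from None


def parse_filename(name: str) -> tuple[str, date, time, str]:
    """Split ``<user>_<YYYYMMDD>_<HHMMSS>_<A|R>.amb`` into its components.

    The filename is the authority for allocating an upload to its
    intervention date, so every segment is validated strictly.
    """
    m = _FILENAME_RE.match(name)
    if m is None:
        for pat, seg in (
            (r"^[A-Za-z0-9]{1,8}_", "user id"),
            (r"^[A-Za-z0-9]{1,8}_\d{8}_", "date"),
            (r"^[A-Za-z0-9]{1,8}_\d{8}_\d{6}_", "time"),
            (r"^[A-Za-z0-9]{1,8}_\d{8}_\d{6}_[AR]", "mode code"),
        ):
            if not re.match(pat, name):
                raise AMFormatError(f"malformed monitor filename {name!r}: bad {seg}")
        raise AMFormatError(f"malformed monitor filename {name!r}: bad extension")
    d = _decode_date(int(m.group("date")), "filename date")
    t = _decode_time(int(m.group("time")), "filename time")
    return m.group("user"), d, t, _LETTER_TO_MODE[m.group("mode")]


def monitor_filename(user_id: str, d: date, t: time, mode: str) -> str:
    """Inverse of :func:`parse_filename`."""
    return (
        f"{user_id}_{_encode_date(d):08d}_{_encode_time(t):06d}_"
        f"{_MODE_TO_LETTER[mode]}.amb"
    )


@dataclass
class AMFile:
    """A parsed monitor recording.

    Samples are stored in their quantized on-disk units (deciseconds,
    milli-g, integer bpm) so that a write/read cycle is byte-identical.
    """

    user_id: str
    file_date: date
    file_time: time
    mode: str
    t_ds: np.ndarray  # uint32 deciseconds from file start
    accel_mg: np.ndarray  # (n, 3) int16 milli-g
    hr: np.ndarray  # uint8 bpm, 0 = no beat at this row
    sample_rate: int = SAMPLE_RATE
    source_name: str | None = None

    def __post_init__(self) -> None:
        self.t_ds = np.asarray(self.t_ds, dtype=np.uint32)
        self.accel_mg = np.asarray(self.accel_mg, dtype=np.int16).reshape(-1, 3)
        self.hr = np.asarray(self.hr, dtype=np.uint8)

    # -- construction -------------------------------------------------
    @classmethod
    def from_samples(
        cls,
        user_id: str,
        file_date: date,
        file_time: time,
        mode: str,
        samples: Sequence[SampleRecord],
        sample_rate: int = SAMPLE_RATE,
        source_name: str | None = None,
    ) -> "AMFile":
        """Build from physical-unit samples, quantizing to the dialect grid."""
        t = np.array([round(s.t_offset * 10) for s in samples], dtype=np.uint32)
        acc = np.array(
            [
                [round(s.ax * 1000), round(s.ay * 1000), round(s.az * 1000)]
                for s in samples
            ],
            dtype=np.int16,
        ).reshape(-1, 3)
        hr = np.array([s.hr for s in samples], dtype=np.uint8)
        return cls(user_id, file_date, file_time, mode, t, acc, hr,
                   sample_rate, source_name)

    # -- derived views ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.t_ds.size)

    @property
    def t_offset(self) -> np.ndarray:
        """Row times in seconds."""
        return self.t_ds.astype(np.float64) / 10.0

    @property
    def accel_g(self) -> np.ndarray:
        return self.accel_mg.astype(np.float64) / 1000.0

    @property
    def duration_minutes(self) -> float:
        return self.n_samples / (self.sample_rate * 60.0)

    @property
    def is_empty(self) -> bool:
        return self.n_samples == 0

    @property
    def default_name(self) -> str:
        return monitor_filename(self.user_id, self.file_date, self.file_time, self.mode)

    def samples(self) -> Iterator[SampleRecord]:
        for i in range(self.n_samples):
            yield SampleRecord(
                float(self.t_ds[i]) / 10.0,
                float(self.accel_mg[i, 0]) / 1000.0,
                float(self.accel_mg[i, 1]) / 1000.0,
                float(self.accel_mg[i, 2]) / 1000.0,
                int(self.hr[i]),
            )

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        if self.mode not in _MODE_TO_CODE:
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not (1 <= len(self.user_id) <= 8) or not self.user_id.isalnum():
            raise ValidationError(f"user_id {self.user_id!r} must be 1-8 alphanumerics")
        if self.sample_rate < 1 or self.sample_rate > 255:
            raise ValidationError(f"sample_rate {self.sample_rate} out of range")
        if self.accel_mg.shape != (self.n_samples, 3) or self.hr.size != self.n_samples:
            raise ValidationError("sample arrays have inconsistent lengths")
        if self.n_samples:
            if np.any(np.diff(self.t_ds.astype(np.int64)) <= 0):
                i = int(np.flatnonzero(np.diff(self.t_ds.astype(np.int64)) <= 0)[0]) + 1
                raise ValidationError(f"t_offset not strictly increasing at row {i}")
            bad = np.flatnonzero(np.abs(self.accel_mg.astype(np.int64)).max(axis=1)
                                 > MAX_ACCEL_MG)
            if bad.size:
                raise ValidationError(
                    f"acceleration exceeds ±8 g at row {int(bad[0])}"
                )
            hr = self.hr.astype(np.int64)
            bad = np.flatnonzero((hr != 0) & ((hr < HR_MIN) | (hr > HR_MAX)))
            if bad.size:
                raise ValidationError(
                    f"heart rate outside [{HR_MIN}, {HR_MAX}] at row {int(bad[0])}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AMFile):
            return NotImplemented
        return (
            self.user_id == other.user_id
            and self.file_date == other.file_date
            and self.file_time == other.file_time
            and self.mode == other.mode
            and self.sample_rate == other.sample_rate
            and np.array_equal(self.t_ds, other.t_ds)
            and np.array_equal(self.accel_mg, other.accel_mg)
            and np.array_equal(self.hr, other.hr)
        )


def write_am_file(f: AMFile) -> bytes:
    """Serialize an :class:`AMFile`; :func:`read_am_file` inverts it exactly."""
    f.validate()
    payload = bytearray()
    for i in range(f.n_samples):
        payload += _ROW.pack(
            int(f.t_ds[i]),
            int(f.accel_mg[i, 0]),
            int(f.accel_mg[i, 1]),
            int(f.accel_mg[i, 2]),
            int(f.hr[i]),
        )
    header = _HEADER.pack(
        AMB_MAGIC,
        f.user_id.encode("ascii").ljust(8),
        _encode_date(f.file_date),
        _encode_time(f.file_time),
        _MODE_TO_CODE[f.mode],
        f.sample_rate,
        b"\x00" * 6,
        zlib.crc32(bytes(payload)) & 0xFFFFFFFF,
    )
    return header + bytes(payload)


def read_am_file(src: Union[bytes, bytearray, str, Path],
                 source_name: str | None = None) -> AMFile:
    """Parse an AMB payload (bytes or a path) into an :class:`AMFile`."""
    if isinstance(src, (str, Path)):
        path = Path(src)
        data = path.read_bytes()
        if source_name is None:
            source_name = path.name
    else:
        data = bytes(src)
    if len(data) < _HEADER.size:
        raise AMFormatError(
            f"truncated AMB file: {len(data)} bytes, header needs {_HEADER.size}"
        )
    magic, user_raw, date_v, time_v, mode_code, rate, _res, crc = _HEADER.unpack_from(
        data
    )
    if magic != AMB_MAGIC:
        raise AMFormatError(f"bad magic {magic!r}, expected {AMB_MAGIC!r}")
    payload = data[_HEADER.size:]
    if len(payload) % _ROW.size:
        raise AMFormatError(
            f"truncated payload: {len(payload)} bytes is not a multiple of row size "
            f"{_ROW.size}"
        )
    if zlib.crc32(payload) & 0xFFFFFFFF != crc:
        raise AMFormatError("payload CRC32 mismatch")
    if mode_code not in _CODE_TO_MODE:
        raise AMFormatError(f"unknown mode code {mode_code}")
    n = len(payload) // _ROW.size
    rows = np.frombuffer(
        payload,
        dtype=np.dtype(
            [("t", "<u4"), ("ax", "<i2"), ("ay", "<i2"), ("az", "<i2"), ("hr", "u1")]
        ),
        count=n,
    )
    acc = np.empty((n, 3), dtype=np.int16)
    acc[:, 0], acc[:, 1], acc[:, 2] = rows["ax"], rows["ay"], rows["az"]
    f = AMFile(
        user_id=user_raw.decode("ascii").rstrip(),
        file_date=_decode_date(date_v, "header date"),
        file_time=_decode_time(time_v, "header time"),
        mode=_CODE_TO_MODE[mode_code],
        t_ds=rows["t"].copy(),
        accel_mg=acc,
        hr=rows["hr"].copy(),
        sample_rate=int(rate),
        source_name=source_name,
    )
    try:
        f.validate()
    except ValidationError as exc:
        raise AMFormatError(f"invalid sample data: {exc}") from None
    return f


class Fingerprint(NamedTuple):
    """Content digest used to drop repeated uploads; ``empty`` flags 0-sample files."""

    digest: str
    empty: bool


def file_fingerprint(f: AMFile) -> Fingerprint:
    """Deterministic digest over the full serialized content."""
    return Fingerprint(hashlib.sha256(write_am_file(f)).hexdigest(), f.is_empty)


@dataclass(frozen=True)
class PrescriptionRecord:
    """One day's dose: session kind, phase minutes, and target-zone limits."""

    date: date
    kind: str
    warmup_min: int
    endurance_min: int
    cooldown_min: int
    zone_lo_bpm: int
    zone_hi_bpm: int
    plan_week: int

    @property
    def total_min(self) -> int:
        return self.warmup_min + self.endurance_min + self.cooldown_min

    @property
    def is_activity(self) -> bool:
        return self.kind in ACTIVITY_KINDS

    def validate(self) -> None:
        if self.kind not in _KIND_TO_CODE:
            raise ValidationError(f"unknown session kind {self.kind!r}")
        if not (1 <= self.plan_week <= 12):
            raise ValidationError(f"plan_week {self.plan_week} outside 1-12")
        if self.kind == KIND_REST:
            if self.endurance_min != 0 or self.warmup_min != 0 or self.cooldown_min != 0:
                raise ValidationError("rest day must have zero phase minutes")
            return
        if self.endurance_min <= 0:
            raise ValidationError("activity session needs endurance_min > 0")
        if self.kind == KIND_EFT and self.endurance_min != 12:
            raise ValidationError("field-test session endurance must be 12 min")
        if not (0 <= self.zone_lo_bpm < self.zone_hi_bpm <= 255):
            raise ValidationError(
                f"zone limits ({self.zone_lo_bpm}, {self.zone_hi_bpm}) must satisfy "
                "lo < hi"
            )
        for name in ("warmup_min", "cooldown_min"):
            if getattr(self, name) != 5:
                raise ValidationError(f"{name} must be 5 for activity sessions")


def write_prescription_file(p: PrescriptionRecord) -> bytes:
    """Serialize to the fixed 16-byte record."""
    p.validate()
    body = _RX.pack(
        _encode_date(p.date),
        _KIND_TO_CODE[p.kind],
        p.warmup_min,
        p.endurance_min,
        p.cooldown_min,
        p.zone_lo_bpm,
        p.zone_hi_bpm,
        p.plan_week,
        0,
    )
    crc = _crc8(body[:12])
    return body[:12] + bytes([crc]) + body[13:]


def read_prescription_file(data: Union[bytes, bytearray, str, Path]) -> PrescriptionRecord:
    if isinstance(data, (str, Path)):
        data = Path(data).read_bytes()
    data = bytes(data)
    if len(data) != _RX.size:
        raise AMFormatError(
            f"prescription record must be {_RX.size} bytes, got {len(data)}"
        )
    if _crc8(data[:12]) != data[12]:
        raise AMFormatError("prescription CRC8 mismatch")
    date_v, kind_code, wu, end, cd, lo, hi, week, _crc = _RX.unpack(data)
    if kind_code not in _CODE_TO_KIND:
        raise AMFormatError(f"unknown session kind code {kind_code}")
    p = PrescriptionRecord(
        date=_decode_date(date_v, "prescription date"),
        kind=_CODE_TO_KIND[kind_code],
        warmup_min=wu,
        endurance_min=end,
        cooldown_min=cd,
        zone_lo_bpm=lo,
        zone_hi_bpm=hi,
        plan_week=week,
    )
    try:
        p.validate()
    except ValidationError as exc:
        raise AMFormatError(f"invalid prescription record: {exc}") from None
    return p
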