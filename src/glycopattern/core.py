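"""Typed data model for glucose-meter / insulin-pump device downloads.

A :class:`PatientLog` bundles the four record streams a combined device
download contains — glucose readings, insulin boluses, carbohydrate
intakes, and pump events — for one patient over a closed analysis window
of whole calendar days (typically 2 or 4 weeks).  Timestamps are naive
local clock times, as meters record them; no timezone arithmetic is done.

The module also owns the CSV interchange dialect, calendar-day
partitioning, and the time-block scheme (breakfast / lunch / evening meal
/ bedtime / nocturnal with pre-/post-prandial phases) that the pattern
detectors share.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "GlucoseReading",
    "BolusRecord",
    "CarbRecord",
    "PumpEvent",
    "PatientLog",
    "TimeBlock",
    "TimeBlockScheme",
    "DEFAULT_SCHEME",
    "DayRecords",
    "PatientLogError",
    "PatientLogFormatError",
    "PatientLogRowError",
    "PatientLogValidationError",
    "read_patient_log",
    "write_patient_log",
    "validate_patient_log",
    "partition_days",
    "assign_time_block",
]

#: Plausible fingerstick meter range, mg/dL.  Values outside are treated as
#: device artifacts and dropped during validation (with a warning).
METER_RANGE = (10.0, 600.0)

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"

THERAPIES = ("CSII", "MDI")
MARKS = ("pre", "post", "none")
SOURCES = ("meter", "pump", "bolus_calculator")
PUMP_KINDS = ("stop", "resume", "cartridge_change")


class PatientLogError(ValueError):
    """Base class for log construction / IO errors."""


class PatientLogFormatError(PatientLogError):
    """The file does not follow the documented CSV dialect."""


class PatientLogRowError(PatientLogError):
    """A single CSV row could not be parsed or violates an invariant."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


class PatientLogValidationError(PatientLogError):
    """The assembled log violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GlucoseReading:
    """One fingerstick glucose measurement (mg/dL, minute resolution)."""

    timestamp: dt.datetime
    value: float
    mark: str = "none"  # pre | post | none
    source: str = "meter"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise PatientLogValidationError(
                f"glucose value must be positive, got {self.value}")
        if self.mark not in MARKS:
            raise PatientLogValidationError(f"unknown mark {self.mark!r}")
        if self.source not in SOURCES:
            raise PatientLogValidationError(f"unknown source {self.source!r}")


@dataclass(frozen=True, order=True)
class BolusRecord:
    """One insulin bolus (units), with the calculator-use flag."""

    timestamp: dt.datetime
    units: float
    calculator_used: bool = True

    def __post_init__(self) -> None:
        if self.units < 0:
            raise PatientLogValidationError(
                f"bolus units must be >= 0, got {self.units}")


@dataclass(frozen=True, order=True)
class CarbRecord:
    """One carbohydrate intake record (grams)."""

    timestamp: dt.datetime
    grams: float

    def __post_init__(self) -> None:
        if self.grams < 0:
            raise PatientLogValidationError(
                f"carb grams must be >= 0, got {self.grams}")


@dataclass(frozen=True, order=True)
class PumpEvent:
    """A pump stop / resume / cartridge-change event (CSII therapy)."""

    timestamp: dt.datetime
    kind: str  # stop | resume | cartridge_change

    def __post_init__(self) -> None:
        if self.kind not in PUMP_KINDS:
            raise PatientLogValidationError(f"unknown pump event {self.kind!r}")


@dataclass
class PatientLog:
    """Time-sorted device records for one patient and analysis window.

    ``window`` is a closed interval of whole calendar days
    ``(start_date, end_date)``; records are expected to fall inside it
    (:func:`validate_patient_log` clips strays).
    """

    readings: list[GlucoseReading] = field(default_factory=list)
    boluses: list[BolusRecord] = field(default_factory=list)
    carbs: list[CarbRecord] = field(default_factory=list)
    pump_events: list[PumpEvent] = field(default_factory=list)
    therapy: str = "CSII"
    window: tuple[dt.date, dt.date] = (dt.date(2024, 1, 1), dt.date(2024, 1, 28))

    def __post_init__(self) -> None:
        if self.therapy not in THERAPIES:
            raise PatientLogValidationError(f"unknown therapy {self.therapy!r}")
        start, end = self.window
        if end < start:
            raise PatientLogValidationError("window end before start")
        self.readings = sorted(self.readings, key=lambda r: r.timestamp)
        self.boluses = sorted(self.boluses, key=lambda r: r.timestamp)
        self.carbs = sorted(self.carbs, key=lambda r: r.timestamp)
        self.pump_events = sorted(self.pump_events, key=lambda r: r.timestamp)

    @property
    def n_days(self) -> int:
        return (self.window[1] - self.window[0]).days + 1

    def days(self) -> list[dt.date]:
        start = self.window[0]
        return [start + dt.timedelta(days=i) for i in range(self.n_days)]

    def glucose_values(self) -> list[float]:
        return [r.value for r in self.readings]

    def replace(self, **changes) -> "PatientLog":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# Validation

def _in_window(ts: dt.datetime, window: tuple[dt.date, dt.date]) -> bool:
    return window[0] <= ts.date() <= window[1]


def validate_patient_log(
    log: PatientLog, *, require_readings: bool = True
) -> tuple[PatientLog, list[str]]:
    """Return a cleaned copy of ``log`` plus human-readable warnings.

    Cleaning steps, in order: clip records to the analysis window (counted),
    drop duplicate reading timestamps (keep first), drop readings outside
    the meter range, and check stop/resume alternation (warn only).
    """
    warnings: list[str] = []

    def clip(records, label):
        kept = [r for r in records if _in_window(r.timestamp, log.window)]
        dropped = len(records) - len(kept)
        if dropped:
            warnings.append(f"dropped {dropped} {label} record(s) outside window")
        return kept

    readings = clip(log.readings, "glucose")
    boluses = clip(log.boluses, "bolus")
    carbs = clip(log.carbs, "carb")
    pump_events = clip(log.pump_events, "pump")

    seen: set[dt.datetime] = set()
    unique: list[GlucoseReading] = []
    for r in readings:
        if r.timestamp in seen:
            warnings.append(f"duplicate reading timestamp {r.timestamp:%Y-%m-%dT%H:%M}; kept first")
            continue
        seen.add(r.timestamp)
        unique.append(r)
    readings = unique

    in_range = [r for r in readings if METER_RANGE[0] <= r.value <= METER_RANGE[1]]
    n_rejected = len(readings) - len(in_range)
    if n_rejected:
        warnings.append(
            f"rejected {n_rejected} reading(s) outside meter range "
            f"[{METER_RANGE[0]:g}, {METER_RANGE[1]:g}] mg/dL")
    readings = in_range

    if require_readings and not readings:
        raise PatientLogValidationError("log contains no valid glucose readings")

    state = None
    for ev in pump_events:
        if ev.kind == "stop":
            if state == "stop":
                warnings.append(f"pump stop at {ev.timestamp:%Y-%m-%dT%H:%M} without intervening resume")
            state = "stop"
        elif ev.kind == "resume":
            if state != "stop":
                warnings.append(f"pump resume at {ev.timestamp:%Y-%m-%dT%H:%M} without preceding stop")
            state = "resume"

    cleaned = PatientLog(
        readings=readings, boluses=boluses, carbs=carbs,
        pump_events=pump_events, therapy=log.therapy, window=log.window)
    return cleaned, warnings


# ---------------------------------------------------------------------------
# CSV interchange
#
# One record per row:
#   record_type, timestamp, value, mark, calculator_used, pump_kind
# record_type in {glucose, bolus, carb, pump}; timestamp ISO YYYY-MM-DDTHH:MM;
# value carries mg/dL, insulin units or grams depending on record_type.

CSV_COLUMNS = ["record_type", "timestamp", "value", "mark", "calculator_used", "pump_kind"]


def _parse_timestamp(raw: str, line: int) -> dt.datetime:
    try:
        return dt.datetime.strptime(raw.strip(), TIMESTAMP_FORMAT)
    except ValueError:
        raise PatientLogRowError(line, f"unparseable timestamp {raw!r}") from None


def _parse_float(raw: str, line: int, label: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise PatientLogRowError(line, f"unparseable {label} {raw!r}") from None


def read_patient_log(
    path: Union[str, Path],
    therapy: str,
    window: Optional[tuple[dt.date, dt.date]] = None,
) -> PatientLog:
    """Read a patient-log CSV (documented dialect) into a validated log.

    ``window=None`` infers the window from the span of record dates.
    Rows outside the window are dropped (counted in a warning); the cleaned
    log is returned.  Malformed rows raise :class:`PatientLogRowError` with
    the 1-based file line number.
    """
    path = Path(path)
    if not path.exists():
        raise PatientLogFormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise PatientLogFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise PatientLogFormatError(f"missing mandatory column(s): {', '.join(missing)}")

    readings: list[GlucoseReading] = []
    boluses: list[BolusRecord] = []
    carbs: list[CarbRecord] = []
    pump_events: list[PumpEvent] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2  # header is line 1
        kind = getattr(row, "record_type").strip()
        ts = _parse_timestamp(getattr(row, "timestamp"), line)
        if kind == "glucose":
            value = _parse_float(getattr(row, "value"), line, "glucose value")
            if value <= 0:
                raise PatientLogRowError(line, f"glucose value must be positive, got {value:g}")
            mark = getattr(row, "mark").strip() or "none"
            if mark not in MARKS:
                raise PatientLogRowError(line, f"unknown mark {mark!r}")
            readings.append(GlucoseReading(ts, value, mark))
        elif kind == "bolus":
            units = _parse_float(getattr(row, "value"), line, "bolus units")
            if units < 0:
                raise PatientLogRowError(line, f"bolus units must be >= 0, got {units:g}")
            raw_calc = getattr(row, "calculator_used").strip()
            if raw_calc not in ("0", "1", ""):
                raise PatientLogRowError(line, f"calculator_used must be 0/1, got {raw_calc!r}")
            boluses.append(BolusRecord(ts, units, calculator_used=raw_calc != "0"))
        elif kind == "carb":
            grams = _parse_float(getattr(row, "value"), line, "carb grams")
            if grams < 0:
                raise PatientLogRowError(line, f"carb grams must be >= 0, got {grams:g}")
            carbs.append(CarbRecord(ts, grams))
        elif kind == "pump":
            pump_kind = getattr(row, "pump_kind").strip()
            if pump_kind not in PUMP_KINDS:
                raise PatientLogRowError(line, f"unknown pump_kind {pump_kind!r}")
            pump_events.append(PumpEvent(ts, pump_kind))
        else:
            raise PatientLogRowError(line, f"unknown record_type {kind!r}")

    if window is None:
        stamps = ([r.timestamp for r in readings] + [b.timestamp for b in boluses]
                  + [c.timestamp for c in carbs] + [p.timestamp for p in pump_events])
        if not stamps:
            raise PatientLogValidationError(f"{path} contains no records")
        window = (min(stamps).date(), max(stamps).date())

    log = PatientLog(readings=readings, boluses=boluses, carbs=carbs,
                     pump_events=pump_events, therapy=therapy, window=window)
    cleaned, _warnings = validate_patient_log(log)
    return cleaned


def write_patient_log(log: PatientLog, path: Union[str, Path]) -> None:
    """Write ``log`` to the CSV interchange dialect (re-readable round trip)."""
    rows = []
    for r in log.readings:
        rows.append(("glucose", r.timestamp, f"{r.value:.1f}",
                     "" if r.mark == "none" else r.mark, "", ""))
    for b in log.boluses:
        rows.append(("bolus", b.timestamp, f"{b.units:.2f}", "",
                     "1" if b.calculator_used else "0", ""))
    for c in log.carbs:
        rows.append(("carb", c.timestamp, f"{c.grams:.1f}", "", "", ""))
    for p in log.pump_events:
        rows.append(("pump", p.timestamp, "", "", "", p.kind))
    rows.sort(key=lambda row: row[1])
    frame = pd.DataFrame(
        [(k, ts.strftime(TIMESTAMP_FORMAT), *rest) for (k, ts, *rest) in rows],
        columns=CSV_COLUMNS)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Calendar-day partition

@dataclass
class DayRecords:
    """Records of one calendar day (may be empty)."""

    readings: list[GlucoseReading] = field(default_factory=list)
    boluses: list[BolusRecord] = field(default_factory=list)
    carbs: list[CarbRecord] = field(default_factory=list)
    pump_events: list[PumpEvent] = field(default_factory=list)


def partition_days(log: PatientLog) -> list[tuple[dt.date, DayRecords]]:
    """One entry per calendar day of the window (empty days included).

    Each record belongs to exactly one day, split at local midnight.
    """
    table = {day: DayRecords() for day in log.days()}
    for r in log.readings:
        table[r.timestamp.date()].readings.append(r)
    for b in log.boluses:
        table[b.timestamp.date()].boluses.append(b)
    for c in log.carbs:
        table[c.timestamp.date()].carbs.append(c)
    for p in log.pump_events:
        table[p.timestamp.date()].pump_events.append(p)
    return [(day, table[day]) for day in log.days()]


# ---------------------------------------------------------------------------
# Time blocks

@dataclass(frozen=True)
class TimeBlock:
    """A named clock interval [start_min, end_min) in minutes since midnight."""

    name: str
    start_min: int
    end_min: int  # exclusive; up to 1440


@dataclass(frozen=True)
class TimeBlockScheme:
    """Ordered day segmentation used by the time-block patterns.

    Also carries the phase-inference windows for unmarked readings: a
    reading is inferred preprandial if a carb record follows within
    ``pre_inference_min`` minutes, postprandial if one precedes it by
    ``post_inference_min`` (a [low, high] minutes interval, inclusive).
    """

    blocks: tuple[TimeBlock, ...]
    pre_inference_min: float = 30.0
    post_inference_min: tuple[float, float] = (60.0, 120.0)

    def __post_init__(self) -> None:
        covered = sorted(self.blocks, key=lambda b: b.start_min)
        cursor = 0
        for block in covered:
            if block.start_min != cursor:
                raise PatientLogValidationError(
                    f"time blocks must cover 24 h without overlap "
                    f"(gap/overlap at minute {cursor})")
            if block.end_min <= block.start_min:
                raise PatientLogValidationError(f"empty time block {block.name!r}")
            cursor = block.end_min
        if cursor != 1440:
            raise PatientLogValidationError("time blocks must end at 24:00")
        if not any(b.name == "nocturnal" for b in self.blocks):
            raise PatientLogValidationError("a nocturnal block is required")

    def block_of(self, when: Union[dt.datetime, dt.time]) -> str:
        t = when.time() if isinstance(when, dt.datetime) else when
        minute = t.hour * 60 + t.minute
        for block in self.blocks:
            if block.start_min <= minute < block.end_min:
                return block.name
        raise AssertionError("blocks cover 24 h")  # pragma: no cover

    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]


#: Default clock boundaries.  The block names are standard; the clock
#: boundaries are a configurable convention (nocturnal 00-06, breakfast
#: 06-11, lunch 11-16, evening meal 16-21, bedtime 21-24).
DEFAULT_SCHEME = TimeBlockScheme(blocks=(
    TimeBlock("nocturnal", 0, 6 * 60),
    TimeBlock("breakfast", 6 * 60, 11 * 60),
    TimeBlock("lunch", 11 * 60, 16 * 60),
    TimeBlock("evening_meal", 16 * 60, 21 * 60),
    TimeBlock("bedtime", 21 * 60, 24 * 60),
))


def assign_time_block(
    reading: GlucoseReading,
    scheme: TimeBlockScheme = DEFAULT_SCHEME,
    carbs: Sequence[CarbRecord] = (),
) -> tuple[str, str]:
    """Return ``(block_name, phase)`` for one reading.

    The phase is the reading's own pre/post mark when present; otherwise it
    is inferred from nearby carb records (pre takes precedence), else
    ``"none"``.
    """
    block = scheme.block_of(reading.timestamp)
    if reading.mark in ("pre", "post"):
        return block, reading.mark
    for carb in carbs:
        delta_min = (carb.timestamp - reading.timestamp).total_seconds() / 60.0
        if 0 <= delta_min <= scheme.pre_inference_min:
            return block, "pre"
    low, high = scheme.post_inference_min
    for carb in carbs:
        delta_min = (reading.timestamp - carb.timestamp).total_seconds() / 60.0
        if low <= delta_min <= high:
            return block, "post"
    return block, "none"
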