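"""Seeded synthetic patient logs with controllable pattern injection.

The baseline generator emulates a 2-4-week combined device download
(glucose + carbohydrate + insulin + pump events) for a well-controlled
patient on pump (CSII) or injection (MDI) therapy:

* 6 scheduled readings/day around the three main meals (pre/post marked),
  plus an occasional unmarked bedtime reading;
* glucose drawn lognormal (right-skewed, as SMBG marginals are) around a
  target mean of 120 mg/dL with 15 % CV, clipped to a conservative
  euglycemic support of [85, 150] mg/dL;
* three carb intakes and three calculator-assisted boluses per day, each
  bolus preceded by a fingerstick within 30 min;
* for CSII, a cartridge change exactly every 7 days and no pump stops.

Under these conservative defaults *no* dashboard pattern triggers: the
baseline is a negative control.  :func:`inject_pattern` then edits a
baseline log constructively — inserting or altering records so the
targeted pattern's printed rule is satisfied with margin — which makes
the injection -> detection round trip deterministic per seed.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .agreement import RatingTable
from .core import (BolusRecord, CarbRecord, GlucoseReading, PatientLog,
                   PumpEvent, validate_patient_log)
from .patterns import CSII_ONLY, PATTERN_IDS

__all__ = [
    "GeneratorParams",
    "generate_baseline_log",
    "inject_pattern",
    "generate_rating_table",
    "INJECTABLE_PATTERNS",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Study-condition defaults for the baseline generator."""

    days: int = 28
    start_date: dt.date = dt.date(2024, 3, 4)
    glucose_mean: float = 120.0       # mg/dL, lognormal target mean
    glucose_cv_percent: float = 15.0  # target coefficient of variation
    glucose_support: tuple[float, float] = (85.0, 150.0)  # clip bounds
    meal_times: tuple[tuple[int, int], ...] = ((7, 30), (12, 30), (19, 0))
    carb_grams_mean: float = 50.0
    carb_grams_sd: float = 10.0
    bedtime_reading_prob: float = 0.5
    calculator_prob: float = 1.0      # share of boluses using the calculator
    cartridge_interval_days: int = 7
    change_time: tuple[int, int] = (1, 0)  # 01:00, away from meal activity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not (0 <= self.bedtime_reading_prob <= 1):
            raise ValueError("bedtime_reading_prob must be in [0, 1]")
        if self.glucose_support[0] >= self.glucose_support[1]:
            raise ValueError("glucose_support must be an increasing interval")


#: Reading schedule around the three meals: (hour, minute, mark).
_READING_SLOTS = (
    (7, 25, "pre"), (9, 30, "post"),
    (12, 25, "pre"), (14, 30, "post"),
    (18, 55, "pre"), (21, 0, "post"),
)
_BEDTIME_SLOT = (22, 30)


def _lognormal_params(mean: float, cv_percent: float) -> tuple[float, float]:
    cv = cv_percent / 100.0
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_baseline_log(
    params: Optional[GeneratorParams] = None,
    therapy: str = "CSII",
) -> PatientLog:
    """Deterministic (per seed) pattern-free baseline log."""
    params = params or GeneratorParams()
    root = np.random.SeedSequence([int(params.seed), 0x51])
    rng_glucose, rng_carbs, rng_bedtime = (
        np.random.default_rng(s) for s in root.spawn(3))
    mu, sigma = _lognormal_params(params.glucose_mean, params.glucose_cv_percent)
    low, high = params.glucose_support

    readings: list[GlucoseReading] = []
    carbs: list[CarbRecord] = []
    boluses: list[BolusRecord] = []
    pump_events: list[PumpEvent] = []

    def draw_glucose() -> float:
        value = float(np.exp(rng_glucose.normal(mu, sigma)))
        return round(min(max(value, low), high), 1)

    for day_index in range(params.days):
        day = params.start_date + dt.timedelta(days=day_index)
        for hour, minute, mark in _READING_SLOTS:
            ts = dt.datetime.combine(day, dt.time(hour, minute))
            readings.append(GlucoseReading(ts, draw_glucose(), mark))
        if rng_bedtime.random() < params.bedtime_reading_prob:
            ts = dt.datetime.combine(day, dt.time(*_BEDTIME_SLOT))
            readings.append(GlucoseReading(ts, draw_glucose(), "none"))
        for hour, minute in params.meal_times:
            ts = dt.datetime.combine(day, dt.time(hour, minute))
            grams = float(np.clip(
                rng_carbs.normal(params.carb_grams_mean, params.carb_grams_sd),
                25.0, 90.0))
            carbs.append(CarbRecord(ts, round(grams, 1)))
            used = bool(rng_carbs.random() < params.calculator_prob)
            boluses.append(BolusRecord(ts, round(grams / 10.0, 2),
                                       calculator_used=used))
        if therapy == "CSII" and day_index % params.cartridge_interval_days == 0:
            ts = dt.datetime.combine(day, dt.time(*params.change_time))
            pump_events.append(PumpEvent(ts, "cartridge_change"))

    window = (params.start_date,
              params.start_date + dt.timedelta(days=params.days - 1))
    log = PatientLog(readings=readings, boluses=boluses, carbs=carbs,
                     pump_events=pump_events, therapy=therapy, window=window)
    cleaned, _ = validate_patient_log(log)
    return cleaned


# ---------------------------------------------------------------------------
# Pattern injection
#
# Injectors are constructive: they place records that satisfy the printed
# rule with margin, at clock times chosen off the baseline grid so no
# timestamps collide and so that unrelated detectors stay quiet (documented
# couplings excepted — see INJECTION_COUPLINGS).

#: Other patterns an injector is allowed to flip as a physiological side
#: effect (e.g. readings extreme enough to move SD also move HBGI).
INJECTION_COUPLINGS: dict[str, frozenset] = {
    "hbgi": frozenset({"sd"}),
}

INJECTABLE_PATTERNS = PATTERN_IDS


def _ts(log: PatientLog, day_offset: int, hour: int, minute: int) -> dt.datetime:
    return dt.datetime.combine(
        log.window[0] + dt.timedelta(days=day_offset), dt.time(hour, minute))


def _spread_days(n_days: int, count: int, first: int = 1) -> list[int]:
    """``count`` day offsets spread over the window, >= ~n/count apart."""
    span = max(n_days - first - 1, 1)
    return [first + int(round(k * span / max(count - 1, 1)))
            for k in range(count)]


def _add_readings(log: PatientLog, new: Sequence[GlucoseReading]) -> PatientLog:
    return log.replace(readings=sorted(log.readings + list(new),
                                       key=lambda r: r.timestamp))


def _require_days(log: PatientLog, minimum: int, pattern_id: str) -> None:
    if log.n_days < minimum:
        raise ValueError(
            f"injector {pattern_id!r} needs a window of >= {minimum} days, "
            f"got {log.n_days}")


def _inject_sd(log: PatientLog, rng) -> PatientLog:
    # 8 isolated extreme-high readings push window SD past 70 mg/dL while
    # staying below the moderate HBGI band; rotated clock slots keep any
    # one time block below the time-block trigger.
    slots = [(3, 10), (8, 40), (13, 10), (18, 10), (22, 40)]
    days = _spread_days(log.n_days, 8)
    new = [GlucoseReading(_ts(log, day, *slots[i % len(slots)]), 500.0)
           for i, day in enumerate(days)]
    return _add_readings(log, new)


def _inject_lbgi(log: PatientLog, rng) -> PatientLog:
    # 14 isolated readings at 40 mg/dL lift LBGI into the moderate band
    # (r(40) ~ 36) at about one hypo event every other day: too sparse for
    # the trend, time-block or cartridge-association rules.
    slots = [(8, 50), (13, 20), (18, 20), (22, 50)]
    days = _spread_days(log.n_days, 14)
    new = [GlucoseReading(_ts(log, day, *slots[i % len(slots)]), 40.0)
           for i, day in enumerate(days)]
    return _add_readings(log, new)


def _inject_hbgi(log: PatientLog, rng) -> PatientLog:
    # 16 readings at 400 mg/dL lift HBGI past the moderate band edge; the
    # same excursions necessarily raise SD past 70 (whitelisted coupling).
    slots = [(3, 20), (8, 45), (13, 15), (18, 15), (22, 45)]
    days = _spread_days(log.n_days, 16)
    new = [GlucoseReading(_ts(log, day, *slots[i % len(slots)]), 400.0)
           for i, day in enumerate(days)]
    return _add_readings(log, new)


def _inject_hypo_trend(log: PatientLog, rng) -> PatientLog:
    # 2 hypo events/day (>1) on 3 consecutive days, 8 h apart so the merge
    # gap keeps them distinct.
    _require_days(log, 8, "hypo_trend")
    new = [GlucoseReading(_ts(log, day, hour, 5), 60.0)
           for day in (5, 6, 7) for hour in (9, 17)]
    return _add_readings(log, new)


def _inject_hypo_overcorrection(log: PatientLog, rng) -> PatientLog:
    # Hyper (250) then hypo (60) 90 min later: every hypo event is preceded
    # by a hyperglycemic event within the 3 h lookback (3/3 > 25 %).
    days = [d for d in (6, 13, 20) if d < log.n_days]
    new = []
    for day in days:
        new.append(GlucoseReading(_ts(log, day, 10, 0), 250.0))
        new.append(GlucoseReading(_ts(log, day, 11, 30), 60.0))
    return _add_readings(log, new)


def _inject_hypo_time_block(log: PatientLog, rng) -> PatientLog:
    # 5 nocturnal hypo events inside one 7-day window (>3 in one block).
    _require_days(log, 14, "hypo_time_block")
    new = [GlucoseReading(_ts(log, day, 3, 30), 60.0) for day in range(9, 14)]
    return _add_readings(log, new)


def _inject_hypo_cartridge_change(log: PatientLog, rng) -> PatientLog:
    # A hypo event 2 h after every cartridge change (100 % > 80 %).
    changes = [e.timestamp for e in log.pump_events
               if e.kind == "cartridge_change"]
    if not changes:
        raise ValueError("hypo_cartridge_change injector needs cartridge changes")
    new = [GlucoseReading(change + dt.timedelta(hours=2), 60.0)
           for change in changes]
    return _add_readings(log, new)


def _inject_hyper_trend(log: PatientLog, rng) -> PatientLog:
    # 3 hyper events/day (>2) for 7 consecutive days.  Value 170 marked
    # postprandial: above the 160 event threshold but below the 180
    # postprandial time-block threshold, so the time-block rule stays quiet.
    _require_days(log, 15, "hyper_trend")
    new = [GlucoseReading(_ts(log, day, hour, 50), 170.0, "post")
           for day in range(8, 15) for hour in (7, 13, 19)]
    return _add_readings(log, new)


def _inject_hyper_cartridge_delay(log: PatientLog, rng) -> PatientLog:
    # Delay the last cartridge change by 2 days (>1) and fill the delay
    # period with postprandial-marked readings at 170 so >50 % of the
    # delay-period readings are hyperglycemic; an extra on-time change at
    # the window end keeps the delayed share of cycles at 25 % (<30 %).
    _require_days(log, 28, "hyper_cartridge_delay")
    changes = [e for e in log.pump_events if e.kind == "cartridge_change"]
    others = [e for e in log.pump_events if e.kind != "cartridge_change"]
    if len(changes) < 4:
        raise ValueError("hyper_cartridge_delay injector needs >= 4 changes")
    moved = PumpEvent(changes[-1].timestamp + dt.timedelta(days=2),
                      "cartridge_change")
    extra = PumpEvent(_ts(log, log.n_days - 1, 1, 0), "cartridge_change")
    pump_events = sorted(others + changes[:-1] + [moved, extra],
                         key=lambda e: e.timestamp)
    delay_day = (changes[-1].timestamp.date() - log.window[0]).days
    minutes = [(8, 0), (9, 30), (11, 0), (12, 35), (14, 5),
               (15, 35), (17, 5), (18, 35), (20, 5)]
    new = [GlucoseReading(_ts(log, delay_day + d, h, m), 170.0, "post")
           for d in (0, 1) for (h, m) in minutes]
    return _add_readings(log.replace(pump_events=pump_events), new)


def _inject_hyper_overcorrection(log: PatientLog, rng) -> PatientLog:
    # Hypo (60) then hyper >200 (250) 90 min later: every primary
    # hyperglycemia is preceded by a hypoglycemia within <3 h.
    days = [d for d in (5, 12, 19) if d < log.n_days]
    new = []
    for day in days:
        new.append(GlucoseReading(_ts(log, day, 9, 0), 60.0))
        new.append(GlucoseReading(_ts(log, day, 10, 30), 250.0))
    return _add_readings(log, new)


def _inject_hyper_time_block(log: PatientLog, rng) -> PatientLog:
    # 5 postprandial readings at 250 (>180) in the lunch block inside one
    # 7-day window.
    _require_days(log, 14, "hyper_time_block")
    new = [GlucoseReading(_ts(log, day, 14, 35), 250.0, "post")
           for day in range(9, 14)]
    return _add_readings(log, new)


def _inject_hyper_missed_bolus(log: PatientLog, rng) -> PatientLog:
    # 4 unbolused >20 g intakes each followed 90 min later by a
    # hyperglycemia (220 > 160); weekly spacing keeps the time-block and
    # trend rules quiet.
    _require_days(log, 25, "hyper_missed_bolus")
    new_readings = []
    new_carbs = list(log.carbs)
    for day in (3, 10, 17, 24):
        new_carbs.append(CarbRecord(_ts(log, day, 10, 0), 50.0))
        new_readings.append(GlucoseReading(_ts(log, day, 11, 30), 220.0))
    out = log.replace(carbs=sorted(new_carbs, key=lambda c: c.timestamp))
    return _add_readings(out, new_readings)


def _deficient_days(log: PatientLog, share: float = 0.5) -> list[dt.date]:
    count = int(log.n_days * share) + 1
    return [log.window[0] + dt.timedelta(days=i) for i in range(count)]


def _inject_marks_usage(log: PatientLog, rng) -> PatientLog:
    # Strip marks down to 2 marked readings/day (<3) on >50 % of days.
    target = set(_deficient_days(log))
    readings = []
    for r in log.readings:
        if r.timestamp.date() in target and r.mark != "none":
            keep_marked = r.timestamp.time() <= dt.time(9, 30)
            readings.append(r if keep_marked
                            else GlucoseReading(r.timestamp, r.value, "none"))
        else:
            readings.append(r)
    return log.replace(readings=readings)


def _inject_record_count(log: PatientLog, rng) -> PatientLog:
    # Keep only the breakfast bolus + carb (2 records/day < 3) on >50 % of
    # days.
    target = set(_deficient_days(log))
    keep_before = dt.time(8, 0)

    def keep(record) -> bool:
        return (record.timestamp.date() not in target
                or record.timestamp.time() <= keep_before)

    return log.replace(boluses=[b for b in log.boluses if keep(b)],
                       carbs=[c for c in log.carbs if keep(c)])


def _inject_pump_stops(log: PatientLog, rng) -> PatientLog:
    # 3 stop/resume pairs (>2 stops) on >50 % of days.
    new = []
    for day in _deficient_days(log):
        for hour in (6, 10, 15):
            base = dt.datetime.combine(day, dt.time(hour, 5))
            new.append(PumpEvent(base, "stop"))
            new.append(PumpEvent(base + dt.timedelta(minutes=30), "resume"))
    events = sorted(log.pump_events + new, key=lambda e: e.timestamp)
    return log.replace(pump_events=events)


def _inject_cartridge_frequency(log: PatientLog, rng) -> PatientLog:
    # Rebuild the change schedule so 2 of 3 cycles run 1.5 days late
    # (>30 % delayed); the delay periods stay euglycemic so the
    # hyperglycemia cartridge-delay rule is untouched.
    _require_days(log, 25, "cartridge_frequency")
    others = [e for e in log.pump_events if e.kind != "cartridge_change"]
    changes = [PumpEvent(_ts(log, 0, 1, 0), "cartridge_change"),
               PumpEvent(_ts(log, 8, 13, 0), "cartridge_change"),
               PumpEvent(_ts(log, 17, 1, 0), "cartridge_change"),
               PumpEvent(_ts(log, 24, 1, 0), "cartridge_change")]
    return log.replace(pump_events=sorted(others + changes,
                                          key=lambda e: e.timestamp))


def _inject_bg_test_frequency(log: PatientLog, rng) -> PatientLog:
    # Keep only the 3 preprandial readings (<4/day) on >=80 % of days.
    count = math.ceil(log.n_days * 0.8)
    if count == log.n_days * 0.8:
        count += 1  # stay clear of the inclusive 80 % boundary
    target = {log.window[0] + dt.timedelta(days=i) for i in range(count)}
    readings = [r for r in log.readings
                if r.timestamp.date() not in target or r.mark == "pre"]
    return log.replace(readings=readings)


def _inject_bg_before_bolus(log: PatientLog, rng) -> PatientLog:
    # Remove the pre-lunch and pre-dinner fingersticks on >50 % of days:
    # those boluses then lack a reading in the prior 30 min (~36 % > 25 %).
    target = set(_deficient_days(log))
    drop_times = {dt.time(12, 25), dt.time(18, 55)}
    readings = [r for r in log.readings
                if not (r.timestamp.date() in target
                        and r.timestamp.time() in drop_times)]
    return log.replace(readings=readings)


def _inject_bolus_calculator(log: PatientLog, rng) -> PatientLog:
    # Flip ~30 % of boluses (> 25 %) to manual entry.
    n_manual = int(0.3 * len(log.boluses)) + 1
    boluses = [replace(b, calculator_used=False) if i < n_manual else b
               for i, b in enumerate(log.boluses)]
    return log.replace(boluses=boluses)


_INJECTORS = {
    "sd": _inject_sd,
    "lbgi": _inject_lbgi,
    "hbgi": _inject_hbgi,
    "hypo_trend": _inject_hypo_trend,
    "hypo_overcorrection": _inject_hypo_overcorrection,
    "hypo_time_block": _inject_hypo_time_block,
    "hypo_cartridge_change": _inject_hypo_cartridge_change,
    "hyper_trend": _inject_hyper_trend,
    "hyper_cartridge_delay": _inject_hyper_cartridge_delay,
    "hyper_overcorrection": _inject_hyper_overcorrection,
    "hyper_time_block": _inject_hyper_time_block,
    "hyper_missed_bolus": _inject_hyper_missed_bolus,
    "marks_usage": _inject_marks_usage,
    "record_count": _inject_record_count,
    "pump_stops": _inject_pump_stops,
    "cartridge_frequency": _inject_cartridge_frequency,
    "bg_test_frequency": _inject_bg_test_frequency,
    "bg_before_bolus": _inject_bg_before_bolus,
    "bolus_calculator": _inject_bolus_calculator,
}


def inject_pattern(
    log: PatientLog,
    pattern_id: str,
    strength: float = 1.0,
    seed: int = 0,
) -> PatientLog:
    """Return a copy of ``log`` that triggers ``pattern_id`` by design.

    ``strength=0`` is the identity.  Requesting a pump-only pattern for an
    MDI log raises ``ValueError``.
    """
    if pattern_id not in _INJECTORS:
        raise ValueError(f"unknown pattern id {pattern_id!r}")
    if pattern_id in CSII_ONLY and log.therapy != "CSII":
        raise ValueError(f"pattern {pattern_id!r} applies to CSII therapy only")
    if strength == 0:
        return log
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA7]))
    injected = _INJECTORS[pattern_id](log, rng)
    cleaned, _ = validate_patient_log(injected)
    return cleaned


def generate_rating_table(
    reference: Sequence[bool],
    rater_accuracy: float,
    n_raters: int,
    seed: int = 0,
) -> RatingTable:
    """Synthetic clinician panel: each rating matches the automated
    reference independently with probability ``rater_accuracy``."""
    if not (0.0 <= rater_accuracy <= 1.0):
        raise ValueError("rater_accuracy must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC3]))
    ref = np.asarray(reference, dtype=bool)
    match = rng.random((n_raters, ref.size)) < rater_accuracy
    ratings = np.where(match, ref[None, :], ~ref[None, :]).astype(float)
    return RatingTable(
        items=[f"item_{i + 1}" for i in range(ref.size)],
        reference=ref,
        ratings=ratings,
        rater_ids=[f"rater_{j + 1}" for j in range(n_raters)],
    )
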