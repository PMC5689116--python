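"""Shared builders for constructing small hand-crafted patient logs."""

from __future__ import annotations

import datetime as dt

from glycopattern.core import (BolusRecord, CarbRecord, GlucoseReading,
                               PatientLog, PumpEvent)

START = dt.date(2024, 3, 4)


def ts(day: int, clock: str, start: dt.date = START) -> dt.datetime:
    hour, minute = map(int, clock.split(":"))
    return dt.datetime.combine(start + dt.timedelta(days=day),
                               dt.time(hour, minute))


def make_log(days=10, therapy="CSII", readings=(), boluses=(), carbs=(),
             pump=(), start: dt.date = START) -> PatientLog:
    """Build a log from compact record tuples.

    readings: (day, "HH:MM", value[, mark])
    boluses:  (day, "HH:MM", units[, calculator_used])
    carbs:    (day, "HH:MM", grams)
    pump:     (day, "HH:MM", kind)
    """
    return PatientLog(
        readings=[GlucoseReading(ts(r[0], r[1], start), r[2],
                                 r[3] if len(r) > 3 else "none")
                  for r in readings],
        boluses=[BolusRecord(ts(b[0], b[1], start), b[2],
                             b[3] if len(b) > 3 else True)
                 for b in boluses],
        carbs=[CarbRecord(ts(c[0], c[1], start), c[2]) for c in carbs],
        pump_events=[PumpEvent(ts(p[0], p[1], start), p[2]) for p in pump],
        therapy=therapy,
        window=(start, start + dt.timedelta(days=days - 1)),
    )
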