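"""Discrete glycemic events and the temporal primitives detectors share."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

from .core import GlucoseReading, PumpEvent

__all__ = [
    "GlycemicEvent",
    "CartridgeCycle",
    "PrecededFraction",
    "detect_glycemic_events",
    "daily_counts",
    "longest_qualifying_run",
    "preceded_fraction",
    "cartridge_cycles",
    "pump_stop_daily_counts",
]


@dataclass(frozen=True)
class GlycemicEvent:
    """A merged run of qualifying readings of one kind (hypo or hyper)."""

    kind: str  # hypo | hyper
    start: dt.datetime
    end: dt.datetime
    readings: tuple[GlucoseReading, ...]
    extremum: float  # min value for hypo, max for hyper

    def __post_init__(self) -> None:
        if self.kind not in ("hypo", "hyper"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError("event end before start")


@dataclass(frozen=True)
class CartridgeCycle:
    """Interval between successive cartridge changes."""

    previous_change: dt.datetime
    change: dt.datetime
    interval_days: float
    delay_days: float  # max(0, interval - expected_interval)


@dataclass(frozen=True)
class PrecededFraction:
    fraction: float
    numerator: int
    denominator: int

    @property
    def empty(self) -> bool:
        return self.denominator == 0


def detect_glycemic_events(
    readings: Sequence[GlucoseReading],
    qualifies,
    kind: str,
    merge_gap_min: float = 60.0,
) -> list[GlycemicEvent]:
    """Group qualifying readings into events.

    ``qualifies(value) -> bool`` decides membership (strict comparisons as
    printed in the pattern definitions, e.g. value < 70 for hypo).
    Successive qualifying readings closer than ``merge_gap_min`` minutes
    belong to one event; intervening normal readings do not split an event.
    """
    gap = dt.timedelta(minutes=merge_gap_min)
    events: list[GlycemicEvent] = []
    current: list[GlucoseReading] = []
    for reading in readings:
        if not qualifies(reading.value):
            continue
        if current and reading.timestamp - current[-1].timestamp >= gap:
            events.append(_make_event(kind, current))
            current = []
        current.append(reading)
    if current:
        events.append(_make_event(kind, current))
    return events


def _make_event(kind: str, members: list[GlucoseReading]) -> GlycemicEvent:
    values = [r.value for r in members]
    extremum = min(values) if kind == "hypo" else max(values)
    return GlycemicEvent(kind=kind, start=members[0].timestamp,
                         end=members[-1].timestamp,
                         readings=tuple(members), extremum=extremum)


def daily_counts(events: Sequence[GlycemicEvent], days: Sequence[dt.date]) -> list[int]:
    """Events per calendar day; an event counts on its start day only."""
    index = {day: i for i, day in enumerate(days)}
    counts = [0] * len(days)
    for event in events:
        i = index.get(event.start.date())
        if i is not None:
            counts[i] += 1
    return counts


def longest_qualifying_run(
    counts: Sequence[int],
    per_day,
    days_required: int,
) -> tuple[bool, Optional[tuple[int, int]]]:
    """Is there a run of >= days_required consecutive days each satisfying
    ``per_day(count)``?  Returns the first such run's (start, end) indices.
    """
    run_start = None
    for i, count in enumerate(counts):
        if per_day(count):
            if run_start is None:
                run_start = i
            if i - run_start + 1 >= days_required:
                return True, (run_start, run_start + days_required - 1)
        else:
            run_start = None
    return False, None


def preceded_fraction(
    primary: Sequence[GlycemicEvent],
    opposite: Sequence[GlycemicEvent],
    lookback_min: float,
) -> PrecededFraction:
    """Fraction of primary events with an opposite event ending within
    ``lookback_min`` minutes before the primary start (strictly less than
    the lookback, matching the printed "within <3 h").

    0/0 is reported as fraction 0 with the empty-denominator flag set.
    """
    if not primary:
        return PrecededFraction(0.0, 0, 0)
    lookback = dt.timedelta(minutes=lookback_min)
    numerator = 0
    for event in primary:
        for opp in opposite:
            delta = event.start - opp.end
            if dt.timedelta(0) <= delta < lookback:
                numerator += 1
                break
    return PrecededFraction(numerator / len(primary), numerator, len(primary))


def cartridge_cycles(
    pump_events: Sequence[PumpEvent],
    expected_interval_days: float = 7.0,
) -> list[CartridgeCycle]:
    """Cycles between successive cartridge changes (empty for < 2 changes)."""
    changes = sorted(e.timestamp for e in pump_events if e.kind == "cartridge_change")
    cycles = []
    for prev, curr in zip(changes, changes[1:]):
        interval = (curr - prev).total_seconds() / 86400.0
        cycles.append(CartridgeCycle(
            previous_change=prev, change=curr, interval_days=interval,
            delay_days=max(0.0, interval - expected_interval_days)))
    return cycles


def pump_stop_daily_counts(
    pump_events: Sequence[PumpEvent], days: Sequence[dt.date]
) -> list[int]:
    index = {day: i for i, day in enumerate(days)}
    counts = [0] * len(days)
    for event in pump_events:
        if event.kind != "stop":
            continue
        i = index.get(event.timestamp.date())
        if i is not None:
            counts[i] += 1
    return counts
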