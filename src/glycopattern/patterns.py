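"""The dashboard rule engine: 19 pattern detectors in 5 blocks.

Each detector turns one clinically defined rule into a red/green flag
(``present`` True = red) with the evidence that produced the decision.
The five blocks are:

* **variability** — SD > 70 mg/dL; LBGI / HBGI at moderate-or-high risk;
  optionally %CV > 36 % when enabled.
* **hypoglycemia** (reading < 70 mg/dL) — trend (>1 event/day on 3
  consecutive days); overcorrection (>25 % of hypo events preceded by a
  hyperglycemic event); time block (>3 events in one block over 7 days);
  association with cartridge changes (>80 % of changes followed by a
  hypo; pump therapy only).
* **hyperglycemia** (reading > 160 mg/dL) — trend (>2/day for 7
  consecutive days); cartridge-change delay (>1 day late while >50 % of
  readings are hyperglycemic); overcorrection (>25 % of hyperglycemias
  >200 mg/dL preceded by a hypo within <3 h); time block (>3 in one
  block over 7 days, preprandial >150 / postprandial >180); missed bolus
  (>3 hyperglycemias over 4 weeks after >20 g carbs with no bolus).
* **use_of_system** — <3 marked readings/day on >50 % of days; <3
  insulin+carb records/day on >50 % of days; >2 pump stops/day on >50 %
  of days; cartridge change delayed in >30 % of changes.
* **adherence** — <4 readings/day on 80 % of days; >25 % of boluses
  without a reading in the prior 30 min; calculator unused in >25 % of
  boluses.

Seven patterns only apply to pump (CSII) therapy; for MDI logs they are
reported with ``applicable=False``.  Patterns that cannot be evaluated on
the data at hand (e.g. bolus patterns with zero boluses) render green
with an explicit ``reason``, never silently.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import Comparison, PatternConfig, default_config
from .core import (DEFAULT_SCHEME, PatientLog, TimeBlockScheme,
                   assign_time_block, partition_days)
from .events import (GlycemicEvent, cartridge_cycles, daily_counts,
                     detect_glycemic_events, longest_qualifying_run,
                     preceded_fraction, pump_stop_daily_counts)
from .indices import classify_risk, glucose_summary

__all__ = [
    "PatternSpec",
    "PATTERNS",
    "PATTERN_IDS",
    "CSII_ONLY",
    "BLOCKS",
    "PatternResult",
    "Dashboard",
    "detect_variability",
    "detect_hypo_patterns",
    "detect_hyper_patterns",
    "detect_usage_patterns",
    "detect_adherence_patterns",
    "run_dashboard",
    "compare_dashboards",
]

BLOCKS = ("variability", "hypoglycemia", "hyperglycemia",
          "use_of_system", "adherence")


@dataclass(frozen=True)
class PatternSpec:
    id: str
    block: str
    csii_only: bool = False
    optional: bool = False  # excluded from the default 19 unless enabled


PATTERNS: tuple[PatternSpec, ...] = (
    PatternSpec("sd", "variability"),
    PatternSpec("lbgi", "variability"),
    PatternSpec("hbgi", "variability"),
    PatternSpec("cv", "variability", optional=True),
    PatternSpec("hypo_trend", "hypoglycemia"),
    PatternSpec("hypo_overcorrection", "hypoglycemia"),
    PatternSpec("hypo_time_block", "hypoglycemia"),
    PatternSpec("hypo_cartridge_change", "hypoglycemia", csii_only=True),
    PatternSpec("hyper_trend", "hyperglycemia"),
    PatternSpec("hyper_cartridge_delay", "hyperglycemia", csii_only=True),
    PatternSpec("hyper_overcorrection", "hyperglycemia"),
    PatternSpec("hyper_time_block", "hyperglycemia"),
    PatternSpec("hyper_missed_bolus", "hyperglycemia", csii_only=True),
    PatternSpec("marks_usage", "use_of_system"),
    PatternSpec("record_count", "use_of_system"),
    PatternSpec("pump_stops", "use_of_system", csii_only=True),
    PatternSpec("cartridge_frequency", "use_of_system", csii_only=True),
    PatternSpec("bg_test_frequency", "adherence"),
    PatternSpec("bg_before_bolus", "adherence", csii_only=True),
    PatternSpec("bolus_calculator", "adherence", csii_only=True),
)

PATTERN_IDS = tuple(p.id for p in PATTERNS if not p.optional)
CSII_ONLY = frozenset(p.id for p in PATTERNS if p.csii_only)
_SPEC_BY_ID = {p.id: p for p in PATTERNS}


@dataclass
class PatternResult:
    """Outcome of one detector: flag, applicability, and evidence."""

    id: str
    block: str
    applicable: bool
    present: bool
    evaluable: bool = True
    reason: Optional[str] = None
    evidence: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "block": self.block,
            "applicable": self.applicable,
            "present": self.present,
            "evaluable": self.evaluable,
            "reason": self.reason,
            "evidence": self.evidence,
            "config": self.config,
        }


def _not_applicable(spec: PatternSpec, therapy: str) -> PatternResult:
    return PatternResult(
        id=spec.id, block=spec.block, applicable=False, present=False,
        evaluable=False, reason=f"not applicable to {therapy} therapy")


def _not_evaluable(spec: PatternSpec, reason: str, cfg: dict) -> PatternResult:
    return PatternResult(
        id=spec.id, block=spec.block, applicable=True, present=False,
        evaluable=False, reason=reason, config=cfg)


def _result(spec: PatternSpec, present: bool, evidence: dict, cfg: dict) -> PatternResult:
    return PatternResult(id=spec.id, block=spec.block, applicable=True,
                         present=present, evidence=evidence, config=cfg)


def _cmp(c: Comparison) -> dict:
    return {"value": c.value, "op": c.op}


# ---------------------------------------------------------------------------
# Shared event extraction

def _hypo_events(log: PatientLog, config: PatternConfig) -> list[GlycemicEvent]:
    return detect_glycemic_events(
        log.readings, config.hypo_threshold.check, "hypo", config.merge_gap_min)


def _hyper_events(log: PatientLog, config: PatternConfig) -> list[GlycemicEvent]:
    return detect_glycemic_events(
        log.readings, config.hyper_threshold.check, "hyper", config.merge_gap_min)


def _rolling_block_max(
    stamps_by_block: dict[str, list[dt.date]],
    days: Sequence[dt.date],
    window_days: int,
) -> dict[str, int]:
    """Max count per block over any run of ``window_days`` consecutive days."""
    index = {day: i for i, day in enumerate(days)}
    n = len(days)
    w = min(window_days, n)
    out: dict[str, int] = {}
    for block, stamps in stamps_by_block.items():
        per_day = [0] * n
        for day in stamps:
            i = index.get(day)
            if i is not None:
                per_day[i] += 1
        total = sum(per_day[:w])
        best = total
        for i in range(w, n):
            total += per_day[i] - per_day[i - w]
            best = max(best, total)
        out[block] = best
    return out


# ---------------------------------------------------------------------------
# Block detectors

def detect_variability(
    log: PatientLog,
    config: Optional[PatternConfig] = None,
    scheme: TimeBlockScheme = DEFAULT_SCHEME,
) -> list[PatternResult]:
    """SD, LBGI, HBGI and (optionally) %CV flags."""
    config = config or default_config()
    v = config.variability
    specs = [_SPEC_BY_ID[i] for i in ("sd", "lbgi", "hbgi")]
    if v.cv_enabled:
        specs.append(_SPEC_BY_ID["cv"])
    values = log.glucose_values()
    if len(values) < 2:
        reason = "fewer than 2 glucose readings"
        return [_not_evaluable(s, reason, {}) for s in specs]
    summary = glucose_summary(values, v.lbgi_edges, v.hbgi_edges)
    results = [
        _result(_SPEC_BY_ID["sd"], v.sd.check(summary.sd),
                {"sd": summary.sd, "n": summary.n, "mean": summary.mean},
                {"sd": _cmp(v.sd)}),
        _result(_SPEC_BY_ID["lbgi"], summary.lbgi_category in ("moderate", "high"),
                {"lbgi": summary.lbgi, "category": summary.lbgi_category},
                {"edges": list(v.lbgi_edges)}),
        _result(_SPEC_BY_ID["hbgi"], summary.hbgi_category in ("moderate", "high"),
                {"hbgi": summary.hbgi, "category": summary.hbgi_category},
                {"edges": list(v.hbgi_edges)}),
    ]
    if v.cv_enabled:
        results.append(_result(
            _SPEC_BY_ID["cv"], v.cv.check(summary.cv_percent),
            {"cv_percent": summary.cv_percent}, {"cv": _cmp(v.cv)}))
    return results


def detect_hypo_patterns(
    log: PatientLog,
    config: Optional[PatternConfig] = None,
    scheme: TimeBlockScheme = DEFAULT_SCHEME,
) -> list[PatternResult]:
    """Hypoglycemia block: trend, overcorrection, time block, cartridge."""
    config = config or default_config()
    days = log.days()
    hypo = _hypo_events(log, config)
    hyper = _hyper_events(log, config)
    results = []

    # Trend: >1 event/day on 3 consecutive days (default).
    counts = daily_counts(hypo, days)
    satisfied, run = longest_qualifying_run(
        counts, config.hypo_trend.per_day.check, config.hypo_trend.run_days)
    results.append(_result(
        _SPEC_BY_ID["hypo_trend"], satisfied,
        {"daily_counts": counts, "run": list(run) if run else None,
         "n_events": len(hypo)},
        {"per_day": _cmp(config.hypo_trend.per_day),
         "run_days": config.hypo_trend.run_days}))

    # Overcorrection: >25% of hypo events preceded by a hyperglycemic event.
    oc = config.hypo_overcorrection
    frac = preceded_fraction(hypo, hyper, oc.lookback_min)
    results.append(_result(
        _SPEC_BY_ID["hypo_overcorrection"],
        not frac.empty and oc.fraction.check(frac.fraction),
        {"fraction": frac.fraction, "numerator": frac.numerator,
         "denominator": frac.denominator, "empty": frac.empty},
        {"fraction": _cmp(oc.fraction), "lookback_min": oc.lookback_min}))

    # Time block: >3 hypo events in one block within any 7-day window.
    tb = config.time_block
    by_block = {name: [] for name in scheme.block_names()}
    for event in hypo:
        by_block[scheme.block_of(event.start)].append(event.start.date())
    block_max = _rolling_block_max(by_block, days, tb.window_days)
    triggered = {b: c for b, c in block_max.items() if tb.count.check(c)}
    results.append(_result(
        _SPEC_BY_ID["hypo_time_block"], bool(triggered),
        {"max_per_block": block_max, "triggered_blocks": sorted(triggered)},
        {"count": _cmp(tb.count), "window_days": tb.window_days}))

    # Cartridge association: hypo within the association window after >80%
    # of cartridge changes (CSII only).
    spec = _SPEC_BY_ID["hypo_cartridge_change"]
    if log.therapy != "CSII":
        results.append(_not_applicable(spec, log.therapy))
    else:
        cart = config.cartridge
        changes = [e.timestamp for e in log.pump_events
                   if e.kind == "cartridge_change"]
        if not changes:
            results.append(_not_evaluable(
                spec, "no cartridge changes recorded",
                {"hypo_fraction": _cmp(cart.hypo_fraction)}))
        else:
            window = dt.timedelta(hours=cart.assoc_window_h)
            hits = sum(
                1 for change in changes
                if any(change < ev.start <= change + window for ev in hypo))
            share = hits / len(changes)
            results.append(_result(
                spec, cart.hypo_fraction.check(share),
                {"fraction": share, "changes_with_hypo": hits,
                 "n_changes": len(changes)},
                {"hypo_fraction": _cmp(cart.hypo_fraction),
                 "assoc_window_h": cart.assoc_window_h}))
    return results


def detect_hyper_patterns(
    log: PatientLog,
    config: Optional[PatternConfig] = None,
    scheme: TimeBlockScheme = DEFAULT_SCHEME,
) -> list[PatternResult]:
    """Hyperglycemia block: trend, cartridge delay, overcorrection,
    time block, missed bolus."""
    config = config or default_config()
    days = log.days()
    hypo = _hypo_events(log, config)
    hyper = _hyper_events(log, config)
    results = []

    # Trend: >2 hyperglycemias/day for 7 consecutive days (default).
    counts = daily_counts(hyper, days)
    satisfied, run = longest_qualifying_run(
        counts, config.hyper_trend.per_day.check, config.hyper_trend.run_days)
    results.append(_result(
        _SPEC_BY_ID["hyper_trend"], satisfied,
        {"daily_counts": counts, "run": list(run) if run else None,
         "n_events": len(hyper)},
        {"per_day": _cmp(config.hyper_trend.per_day),
         "run_days": config.hyper_trend.run_days}))

    # Cartridge delay: a cycle >1 day late with >50% of the delay-period
    # readings in the hyperglycemia range (CSII only).
    spec = _SPEC_BY_ID["hyper_cartridge_delay"]
    cart = config.cartridge
    if log.therapy != "CSII":
        results.append(_not_applicable(spec, log.therapy))
    else:
        cycles = cartridge_cycles(log.pump_events, cart.expected_interval_days)
        if not cycles:
            results.append(_not_evaluable(
                spec, "fewer than 2 cartridge changes recorded",
                {"delay_days": _cmp(cart.delay_days)}))
        else:
            cycle_rows = []
            present = False
            for cycle in cycles:
                row = {"interval_days": cycle.interval_days,
                       "delay_days": cycle.delay_days,
                       "hyper_fraction": None}
                if cart.delay_days.check(cycle.delay_days):
                    expected = cycle.previous_change + dt.timedelta(
                        days=cart.expected_interval_days)
                    in_delay = [r.value for r in log.readings
                                if expected <= r.timestamp <= cycle.change]
                    if in_delay:
                        frac = sum(1 for v in in_delay
                                   if config.hyper_threshold.check(v)) / len(in_delay)
                        row["hyper_fraction"] = frac
                        if cart.delay_hyper_fraction.check(frac):
                            present = True
                cycle_rows.append(row)
            results.append(_result(
                spec, present, {"cycles": cycle_rows},
                {"delay_days": _cmp(cart.delay_days),
                 "delay_hyper_fraction": _cmp(cart.delay_hyper_fraction),
                 "expected_interval_days": cart.expected_interval_days}))

    # Overcorrection: >25% of hyperglycemias >200 mg/dL preceded by a
    # hypoglycemia within <3 h.
    oc = config.hyper_overcorrection
    primary_cmp = oc.primary_threshold or config.hyper_threshold
    primaries = detect_glycemic_events(
        log.readings, primary_cmp.check, "hyper", config.merge_gap_min)
    frac = preceded_fraction(primaries, hypo, oc.lookback_min)
    results.append(_result(
        _SPEC_BY_ID["hyper_overcorrection"],
        not frac.empty and oc.fraction.check(frac.fraction),
        {"fraction": frac.fraction, "numerator": frac.numerator,
         "denominator": frac.denominator, "empty": frac.empty},
        {"fraction": _cmp(oc.fraction), "lookback_min": oc.lookback_min,
         "primary_threshold": _cmp(primary_cmp)}))

    # Time block: >3 hyperglycemic readings in one block over any 7-day
    # window, with phase-specific thresholds (pre >150, post >180, unmarked
    # readings judged against the block hyperglycemia threshold).
    tb = config.time_block
    by_block = {name: [] for name in scheme.block_names()}
    for reading in log.readings:
        block, phase = assign_time_block(reading, scheme, log.carbs)
        if phase == "pre":
            qualifies = tb.pre_threshold.check(reading.value)
        elif phase == "post":
            qualifies = tb.post_threshold.check(reading.value)
        else:
            qualifies = config.hyper_threshold.check(reading.value)
        if qualifies:
            by_block[block].append(reading.timestamp.date())
    block_max = _rolling_block_max(by_block, days, tb.window_days)
    triggered = {b: c for b, c in block_max.items() if tb.count.check(c)}
    results.append(_result(
        _SPEC_BY_ID["hyper_time_block"], bool(triggered),
        {"max_per_block": block_max, "triggered_blocks": sorted(triggered)},
        {"count": _cmp(tb.count), "window_days": tb.window_days,
         "pre_threshold": _cmp(tb.pre_threshold),
         "post_threshold": _cmp(tb.post_threshold)}))

    # Missed bolus: >3 hyperglycemias over 4 weeks each explained by >20 g
    # of carbs in the prior 2 h with no bolus in that interval, the intake
    # not being rescue carbs for a preceding hypoglycemia (CSII only).
    spec = _SPEC_BY_ID["hyper_missed_bolus"]
    if log.therapy != "CSII":
        results.append(_not_applicable(spec, log.therapy))
    else:
        mb = config.missed_bolus
        lookback = dt.timedelta(minutes=mb.bolus_lookback_min)
        rescue = dt.timedelta(minutes=mb.rescue_window_min)
        hypo_stamps = [r.timestamp for r in log.readings
                       if config.hypo_threshold.check(r.value)]
        qualifying_days: list[dt.date] = []
        for reading in log.readings:
            if not config.hyper_threshold.check(reading.value):
                continue
            carbs_before = [
                c for c in log.carbs
                if reading.timestamp - lookback <= c.timestamp < reading.timestamp
                and mb.carb_grams.check(c.grams)
                and not any(dt.timedelta(0) <= c.timestamp - h <= rescue
                            for h in hypo_stamps)]
            if not carbs_before:
                continue
            if any(reading.timestamp - lookback <= b.timestamp < reading.timestamp
                   for b in log.boluses):
                continue
            qualifying_days.append(reading.timestamp.date())
        block_max = _rolling_block_max({"all": qualifying_days}, days,
                                       mb.window_days)["all"]
        results.append(_result(
            spec, mb.count.check(block_max),
            {"max_in_window": block_max, "n_qualifying": len(qualifying_days)},
            {"count": _cmp(mb.count), "window_days": mb.window_days,
             "carb_grams": _cmp(mb.carb_grams),
             "bolus_lookback_min": mb.bolus_lookback_min}))
    return results


def _deficient_day_share(
    per_day: Sequence[int], per_day_cmp: Comparison, share_cmp: Comparison,
) -> tuple[bool, dict]:
    n_days = len(per_day)
    deficient = sum(1 for c in per_day if per_day_cmp.check(c))
    share = deficient / n_days if n_days else 0.0
    present = n_days > 0 and share_cmp.check(share)
    return present, {"day_share": share, "deficient_days": deficient,
                     "n_days": n_days}


def detect_usage_patterns(
    log: PatientLog,
    config: Optional[PatternConfig] = None,
    scheme: TimeBlockScheme = DEFAULT_SCHEME,
) -> list[PatternResult]:
    """Use-of-system block: marks, record count, pump stops, cartridge
    change frequency."""
    config = config or default_config()
    u = config.usage
    days = partition_days(log)
    results = []

    marked = [sum(1 for r in recs.readings if r.mark != "none")
              for _, recs in days]
    present, evidence = _deficient_day_share(
        marked, u.marks_per_day, u.marks_day_share)
    results.append(_result(
        _SPEC_BY_ID["marks_usage"], present, evidence,
        {"per_day": _cmp(u.marks_per_day), "day_share": _cmp(u.marks_day_share)}))

    records = [len(recs.boluses) + len(recs.carbs) for _, recs in days]
    present, evidence = _deficient_day_share(
        records, u.records_per_day, u.records_day_share)
    results.append(_result(
        _SPEC_BY_ID["record_count"], present, evidence,
        {"per_day": _cmp(u.records_per_day),
         "day_share": _cmp(u.records_day_share)}))

    spec = _SPEC_BY_ID["pump_stops"]
    if log.therapy != "CSII":
        results.append(_not_applicable(spec, log.therapy))
    else:
        stops = pump_stop_daily_counts(log.pump_events, log.days())
        present, evidence = _deficient_day_share(
            stops, u.stops_per_day, u.stops_day_share)
        results.append(_result(
            spec, present, evidence,
            {"per_day": _cmp(u.stops_per_day),
             "day_share": _cmp(u.stops_day_share)}))

    spec = _SPEC_BY_ID["cartridge_frequency"]
    cart = config.cartridge
    if log.therapy != "CSII":
        results.append(_not_applicable(spec, log.therapy))
    else:
        cycles = cartridge_cycles(log.pump_events, cart.expected_interval_days)
        if not cycles:
            results.append(_not_evaluable(
                spec, "fewer than 2 cartridge changes recorded",
                {"delayed_fraction": _cmp(cart.delayed_fraction)}))
        else:
            delayed = sum(1 for c in cycles if c.delay_days > 0)
            share = delayed / len(cycles)
            results.append(_result(
                spec, cart.delayed_fraction.check(share),
                {"fraction": share, "delayed_cycles": delayed,
                 "n_cycles": len(cycles)},
                {"delayed_fraction": _cmp(cart.delayed_fraction),
                 "expected_interval_days": cart.expected_interval_days}))
    return results


def detect_adherence_patterns(
    log: PatientLog,
    config: Optional[PatternConfig] = None,
    scheme: TimeBlockScheme = DEFAULT_SCHEME,
) -> list[PatternResult]:
    """Adherence block: BG test frequency, BG before bolus, calculator use."""
    config = config or default_config()
    a = config.adherence
    days = partition_days(log)
    results = []

    per_day = [len(recs.readings) for _, recs in days]
    present, evidence = _deficient_day_share(per_day, a.bg_per_day, a.bg_day_share)
    results.append(_result(
        _SPEC_BY_ID["bg_test_frequency"], present, evidence,
        {"per_day": _cmp(a.bg_per_day), "day_share": _cmp(a.bg_day_share)}))

    bolus_gate_csii = a.bolus_patterns_csii_only and log.therapy != "CSII"

    spec = _SPEC_BY_ID["bg_before_bolus"]
    if bolus_gate_csii:
        results.append(_not_applicable(spec, log.therapy))
    elif not log.boluses:
        results.append(_not_evaluable(spec, "no boluses recorded",
                                      {"fraction": _cmp(a.before_bolus_fraction)}))
    else:
        lookback = dt.timedelta(minutes=a.before_bolus_lookback_min)
        unmeasured = sum(
            1 for b in log.boluses
            if not any(b.timestamp - lookback <= r.timestamp <= b.timestamp
                       for r in log.readings))
        share = unmeasured / len(log.boluses)
        results.append(_result(
            spec, a.before_bolus_fraction.check(share),
            {"fraction": share, "boluses_without_bg": unmeasured,
             "n_boluses": len(log.boluses)},
            {"fraction": _cmp(a.before_bolus_fraction),
             "lookback_min": a.before_bolus_lookback_min}))

    spec = _SPEC_BY_ID["bolus_calculator"]
    if bolus_gate_csii:
        results.append(_not_applicable(spec, log.therapy))
    elif not log.boluses:
        results.append(_not_evaluable(spec, "no boluses recorded",
                                      {"fraction": _cmp(a.calculator_fraction)}))
    else:
        manual = sum(1 for b in log.boluses if not b.calculator_used)
        share = manual / len(log.boluses)
        results.append(_result(
            spec, a.calculator_fraction.check(share),
            {"fraction": share, "manual_boluses": manual,
             "n_boluses": len(log.boluses)},
            {"fraction": _cmp(a.calculator_fraction)}))
    return results


# ---------------------------------------------------------------------------
# Dashboard

@dataclass
class Dashboard:
    """All pattern results for one patient window, grouped by block."""

    therapy: str
    window: tuple[dt.date, dt.date]
    results: list[PatternResult]
    config: dict

    def __getitem__(self, pattern_id: str) -> PatternResult:
        for result in self.results:
            if result.id == pattern_id:
                return result
        raise KeyError(pattern_id)

    def present_ids(self) -> list[str]:
        return [r.id for r in self.results if r.present]

    def applicable_ids(self) -> list[str]:
        return [r.id for r in self.results if r.applicable]

    def by_block(self) -> dict[str, list[PatternResult]]:
        grouped: dict[str, list[PatternResult]] = {b: [] for b in BLOCKS}
        for result in self.results:
            grouped[result.block].append(result)
        return grouped

    def to_dict(self) -> dict:
        return {
            "therapy": self.therapy,
            "window": [self.window[0].isoformat(), self.window[1].isoformat()],
            "blocks": {
                block: [r.to_dict() for r in results]
                for block, results in self.by_block().items()
            },
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def run_dashboard(
    log: PatientLog,
    config: Optional[PatternConfig] = None,
    scheme: TimeBlockScheme = DEFAULT_SCHEME,
) -> Dashboard:
    """Run every block detector and assemble the dashboard.

    Deterministic: identical log + config yield an identical dashboard.
    """
    config = config or default_config()
    results = (detect_variability(log, config, scheme)
               + detect_hypo_patterns(log, config, scheme)
               + detect_hyper_patterns(log, config, scheme)
               + detect_usage_patterns(log, config, scheme)
               + detect_adherence_patterns(log, config, scheme))
    order = {p.id: i for i, p in enumerate(PATTERNS)}
    results.sort(key=lambda r: order[r.id])
    return Dashboard(therapy=log.therapy, window=log.window,
                     results=results, config=config.to_dict())


def compare_dashboards(a: Dashboard, b: Dashboard) -> list[dict]:
    """Per-pattern change list from dashboard ``a`` to ``b``.

    Status is ``new`` (absent -> present), ``resolved`` (present ->
    absent) or ``unchanged``.  Requires matching therapy and config.
    """
    if a.therapy != b.therapy:
        raise ValueError("cannot compare dashboards of different therapies")
    if a.config != b.config:
        raise ValueError("cannot compare dashboards with different configs")
    changes = []
    ids_b = {r.id for r in b.results}
    for result in a.results:
        if result.id not in ids_b:
            continue
        after = b[result.id]
        if result.present == after.present:
            status = "unchanged"
        elif after.present:
            status = "new"
        else:
            status = "resolved"
        changes.append({"id": result.id, "block": result.block,
                        "status": status, "before": result.present,
                        "after": after.present})
    return changes
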