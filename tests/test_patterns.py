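"""The 19 dashboard detectors, therapy gating and dashboard mechanics."""

import pytest

from glycopattern.config import default_config, preset_config
from glycopattern.patterns import (CSII_ONLY, PATTERN_IDS, compare_dashboards,
                                   detect_adherence_patterns,
                                   detect_hyper_patterns, detect_hypo_patterns,
                                   detect_usage_patterns, detect_variability,
                                   run_dashboard)
from helpers import make_log


def result_of(results, pattern_id):
    return next(r for r in results if r.id == pattern_id)


class TestVariability:
    def test_high_sd_flags_the_pattern(self):
        # mean 170, deviations (-100, 0, +100): sd ~ 100 > 70
        log = make_log(readings=[(0, "08:00", 70.0), (1, "08:00", 170.0),
                                 (2, "08:00", 270.0)])
        assert result_of(detect_variability(log), "sd").present

    def test_sd_exactly_at_threshold_is_absent(self):
        # deviations (-70, 0, +70) with n-1 denominator: sd = 70 exactly
        log = make_log(readings=[(0, "08:00", 100.0), (1, "08:00", 170.0),
                                 (2, "08:00", 240.0)])
        result = result_of(detect_variability(log), "sd")
        assert result.evidence["sd"] == pytest.approx(70.0)
        assert not result.present

    def test_risk_neutral_series_clears_both_indices(self):
        log = make_log(readings=[(d, "08:00", 112.5) for d in range(5)])
        results = detect_variability(log)
        assert not result_of(results, "lbgi").present
        assert not result_of(results, "hbgi").present

    def test_single_reading_not_evaluable_renders_absent_with_reason(self):
        log = make_log(readings=[(0, "08:00", 100.0)])
        result = result_of(detect_variability(log), "sd")
        assert not result.present and not result.evaluable
        assert result.reason

    def test_cv_pattern_only_when_enabled(self):
        log = make_log(readings=[(0, "08:00", 64.0), (1, "08:00", 100.0),
                                 (2, "08:00", 136.0)])  # cv exactly 36%
        assert all(r.id != "cv" for r in detect_variability(log))
        cfg = default_config().with_overrides({"variability.cv_enabled": True})
        result = result_of(detect_variability(log, cfg), "cv")
        assert result.evidence["cv_percent"] == pytest.approx(36.0)
        assert not result.present  # strict >36
        log_above = make_log(readings=[(0, "08:00", 63.0), (1, "08:00", 100.0),
                                       (2, "08:00", 137.0)])
        assert result_of(detect_variability(log_above, cfg), "cv").present


class TestHypoPatterns:
    def test_two_events_per_day_on_three_days_triggers_trend(self):
        log = make_log(readings=[(d, clock, 60.0)
                                 for d in (2, 3, 4) for clock in ("09:00", "17:00")])
        assert result_of(detect_hypo_patterns(log), "hypo_trend").present

    def test_one_event_per_day_does_not_trigger_strict_trend(self):
        log = make_log(readings=[(d, "09:00", 60.0) for d in (2, 3, 4)])
        assert not result_of(detect_hypo_patterns(log), "hypo_trend").present

    def test_relaxed_preset_flips_trend_present_only(self):
        log = make_log(readings=[(d, "09:00", 60.0) for d in (2, 3, 4)])
        strict = result_of(detect_hypo_patterns(log), "hypo_trend")
        relaxed = result_of(
            detect_hypo_patterns(log, preset_config("trend_relaxed")),
            "hypo_trend")
        assert (strict.present, relaxed.present) == (False, True)

    def test_overcorrection_at_exactly_25_percent_is_absent(self):
        hypos = [(d, "12:00", 60.0) for d in range(4)]
        log = make_log(readings=hypos + [(0, "10:00", 200.0)])
        result = result_of(detect_hypo_patterns(log), "hypo_overcorrection")
        assert result.evidence["fraction"] == 0.25
        assert not result.present

    def test_overcorrection_above_25_percent_is_present(self):
        hypos = [(d, "12:00", 60.0) for d in range(4)]
        log = make_log(readings=hypos + [(0, "10:00", 200.0),
                                         (1, "10:00", 200.0)])
        assert result_of(detect_hypo_patterns(log), "hypo_overcorrection").present

    def test_no_hypo_events_reports_empty_denominator(self):
        log = make_log(readings=[(0, "08:00", 100.0)])
        result = result_of(detect_hypo_patterns(log), "hypo_overcorrection")
        assert result.evidence["empty"] and not result.present

    def test_time_block_needs_more_than_three_events_in_one_block(self):
        at_limit = make_log(readings=[(d, "03:30", 60.0) for d in range(2, 5)])
        beyond = make_log(readings=[(d, "03:30", 60.0) for d in range(2, 6)])
        assert not result_of(detect_hypo_patterns(at_limit),
                             "hypo_time_block").present
        result = result_of(detect_hypo_patterns(beyond), "hypo_time_block")
        assert result.present
        assert result.evidence["triggered_blocks"] == ["nocturnal"]

    def test_time_block_window_is_rolling_seven_days(self):
        # 4 nocturnal events spread over 9 days never share a 7-day window
        log = make_log(days=12, readings=[(d, "03:30", 60.0)
                                          for d in (0, 3, 6, 9)])
        assert not result_of(detect_hypo_patterns(log), "hypo_time_block").present

    def test_cartridge_association_gated_for_mdi(self):
        log = make_log(therapy="MDI", readings=[(0, "08:00", 100.0)])
        result = result_of(detect_hypo_patterns(log), "hypo_cartridge_change")
        assert not result.applicable and not result.present

    def test_cartridge_association_fraction(self):
        pump = [(d, "01:00", "cartridge_change") for d in (0, 2, 4, 6, 8)]
        hypo_after = [(d, "03:00", 60.0) for d in (0, 2, 4, 6)]
        log = make_log(readings=hypo_after + [(9, "12:00", 100.0)], pump=pump)
        result = result_of(detect_hypo_patterns(log), "hypo_cartridge_change")
        assert result.evidence["fraction"] == 0.8  # exactly 80%: absent
        assert not result.present
        log_all = make_log(readings=[(d, "03:00", 60.0) for d in (0, 2, 4, 6, 8)],
                           pump=pump)
        assert result_of(detect_hypo_patterns(log_all),
                         "hypo_cartridge_change").present


class TestHyperPatterns:
    def test_three_events_daily_for_seven_days_triggers_trend(self):
        log = make_log(readings=[(d, clock, 200.0) for d in range(7)
                                 for clock in ("08:00", "13:00", "19:00")])
        assert result_of(detect_hyper_patterns(log), "hyper_trend").present

    def test_two_events_daily_is_not_enough_for_strict_trend(self):
        log = make_log(readings=[(d, clock, 200.0) for d in range(7)
                                 for clock in ("08:00", "19:00")])
        assert not result_of(detect_hyper_patterns(log), "hyper_trend").present

    def test_cartridge_delay_requires_both_clauses(self):
        pump = [(0, "01:00", "cartridge_change"), (9, "01:00", "cartridge_change")]
        # delay 2 days; 3 of 5 delay-period readings hyper (60% > 50%)
        hyper_rich = make_log(
            readings=[(7, "08:00", 200.0), (7, "14:00", 200.0),
                      (8, "08:00", 200.0), (8, "14:00", 100.0),
                      (8, "20:00", 100.0)],
            pump=pump)
        assert result_of(detect_hyper_patterns(hyper_rich),
                         "hyper_cartridge_delay").present
        # same delay but exactly 50% hyper: absent (strict >50%)
        balanced = make_log(
            readings=[(7, "08:00", 200.0), (7, "14:00", 200.0),
                      (8, "08:00", 100.0), (8, "14:00", 100.0)],
            pump=pump)
        assert not result_of(detect_hyper_patterns(balanced),
                             "hyper_cartridge_delay").present
        # delay of exactly 1 day never qualifies (strict >1)
        on_time = make_log(
            readings=[(7, "08:00", 200.0), (7, "14:00", 200.0)],
            pump=[(0, "01:00", "cartridge_change"),
                  (8, "01:00", "cartridge_change")])
        assert not result_of(detect_hyper_patterns(on_time),
                             "hyper_cartridge_delay").present

    def test_overcorrection_primaries_are_above_200(self):
        # hyper at 180 is an event but not an overcorrection primary
        log = make_log(readings=[(0, "09:00", 60.0), (0, "10:30", 180.0)])
        result = result_of(detect_hyper_patterns(log), "hyper_overcorrection")
        assert result.evidence["denominator"] == 0
        log2 = make_log(readings=[(0, "09:00", 60.0), (0, "10:30", 201.0)])
        assert result_of(detect_hyper_patterns(log2), "hyper_overcorrection").present

    def test_time_block_uses_phase_specific_thresholds(self):
        # preprandial 151 > 150 qualifies; postprandial 151 does not
        pre = make_log(readings=[(d, "07:30", 151.0, "pre") for d in range(4)])
        post = make_log(readings=[(d, "07:30", 151.0, "post") for d in range(4)])
        assert result_of(detect_hyper_patterns(pre), "hyper_time_block").present
        assert not result_of(detect_hyper_patterns(post), "hyper_time_block").present

    def test_missed_bolus_counts_unbolused_carb_hyperglycemias(self):
        carbs = [(d, "10:00", 50.0) for d in (0, 2, 4, 6)]
        hypers = [(d, "11:30", 220.0) for d in (0, 2, 4, 6)]
        log = make_log(readings=hypers, carbs=carbs)
        assert result_of(detect_hyper_patterns(log), "hyper_missed_bolus").present

    def test_missed_bolus_three_is_not_enough(self):
        carbs = [(d, "10:00", 50.0) for d in (0, 2, 4)]
        hypers = [(d, "11:30", 220.0) for d in (0, 2, 4)]
        log = make_log(readings=hypers, carbs=carbs)
        assert not result_of(detect_hyper_patterns(log), "hyper_missed_bolus").present

    def test_missed_bolus_cleared_by_a_bolus_in_the_window(self):
        carbs = [(d, "10:00", 50.0) for d in (0, 2, 4, 6)]
        hypers = [(d, "11:30", 220.0) for d in (0, 2, 4, 6)]
        boluses = [(d, "10:05", 5.0) for d in (0, 2, 4, 6)]
        log = make_log(readings=hypers, carbs=carbs, boluses=boluses)
        assert not result_of(detect_hyper_patterns(log), "hyper_missed_bolus").present

    def test_missed_bolus_rescue_carbs_excluded(self):
        # each intake follows a hypoglycemia within 60 min: rescue, not missed
        lows = [(d, "09:30", 60.0) for d in (0, 2, 4, 6)]
        carbs = [(d, "10:00", 50.0) for d in (0, 2, 4, 6)]
        hypers = [(d, "11:30", 220.0) for d in (0, 2, 4, 6)]
        log = make_log(readings=lows + hypers, carbs=carbs)
        assert not result_of(detect_hyper_patterns(log), "hyper_missed_bolus").present


class TestUsagePatterns:
    def test_marks_pattern_share_above_half(self):
        # 10 days: 6 days with 2 marked readings, 4 days with 3
        readings = []
        for d in range(6):
            readings += [(d, "08:00", 100.0, "pre"), (d, "13:00", 100.0, "post")]
        for d in range(6, 10):
            readings += [(d, "08:00", 100.0, "pre"), (d, "13:00", 100.0, "post"),
                         (d, "20:00", 100.0, "pre")]
        log = make_log(readings=readings)
        result = result_of(detect_usage_patterns(log), "marks_usage")
        assert result.present and result.evidence["day_share"] == 0.6

    def test_marks_share_of_exactly_half_is_absent(self):
        readings = []
        for d in range(5):
            readings += [(d, "08:00", 100.0, "pre")]
        for d in range(5, 10):
            readings += [(d, "08:00", 100.0, "pre"), (d, "13:00", 100.0, "post"),
                         (d, "20:00", 100.0, "pre")]
        log = make_log(readings=readings)
        assert not result_of(detect_usage_patterns(log), "marks_usage").present

    def test_record_count_pattern(self):
        boluses = [(d, "08:00", 5.0) for d in range(10)]
        carbs = [(d, "08:00", 40.0) for d in range(4)]  # 6 days have 1 record
        log = make_log(readings=[(0, "08:00", 100.0)],
                       boluses=boluses, carbs=carbs)
        assert result_of(detect_usage_patterns(log), "record_count").present

    def test_pump_stop_pattern_and_boundary(self):
        def stops(n_days_with_three):
            events = []
            for d in range(n_days_with_three):
                for clock in ("06:00", "10:00", "15:00"):
                    events.append((d, clock, "stop"))
            return events

        present = make_log(readings=[(0, "08:00", 100.0)], pump=stops(6))
        absent = make_log(readings=[(0, "08:00", 100.0)], pump=stops(5))
        assert result_of(detect_usage_patterns(present), "pump_stops").present
        assert not result_of(detect_usage_patterns(absent), "pump_stops").present

    def test_cartridge_frequency_40_percent_delayed(self):
        days = [0, 7, 14, 21, 30, 39, 48, 57, 64, 71, 78]  # 10 cycles, 4 late
        pump = [(d, "01:00", "cartridge_change") for d in days]
        log = make_log(days=80, readings=[(0, "08:00", 100.0)], pump=pump)
        result = result_of(detect_usage_patterns(log), "cartridge_frequency")
        assert result.present and result.evidence["fraction"] == 0.4

    def test_cartridge_patterns_not_evaluable_without_changes(self):
        log = make_log(readings=[(0, "08:00", 100.0)])
        result = result_of(detect_usage_patterns(log), "cartridge_frequency")
        assert not result.present and not result.evaluable and result.reason


class TestAdherencePatterns:
    def test_bg_frequency_at_80_percent_of_days_is_present(self):
        # inclusive comparator: exactly 80% of days deficient triggers
        readings = []
        for d in range(8):
            readings += [(d, "08:00", 100.0), (d, "12:00", 100.0),
                         (d, "18:00", 100.0)]
        for d in range(8, 10):
            readings += [(d, f"{h:02d}:00", 100.0) for h in (7, 11, 15, 20)]
        log = make_log(readings=readings)
        result = result_of(detect_adherence_patterns(log), "bg_test_frequency")
        assert result.evidence["day_share"] == 0.8
        assert result.present

    def test_bg_frequency_below_80_percent_is_absent(self):
        readings = []
        for d in range(7):
            readings += [(d, "08:00", 100.0)]
        for d in range(7, 10):
            readings += [(d, f"{h:02d}:00", 100.0) for h in (7, 11, 15, 20)]
        log = make_log(readings=readings)
        assert not result_of(detect_adherence_patterns(log),
                             "bg_test_frequency").present

    def test_before_bolus_at_exactly_25_percent_is_absent(self):
        # 8 boluses, 2 without a reading in the prior 30 min
        boluses = [(d, "12:30", 5.0) for d in range(8)]
        readings = [(d, "12:10", 100.0) for d in range(6)]
        log = make_log(readings=readings + [(9, "08:00", 100.0)], boluses=boluses)
        result = result_of(detect_adherence_patterns(log), "bg_before_bolus")
        assert result.evidence["fraction"] == 0.25
        assert not result.present

    def test_calculator_disuse_above_25_percent(self):
        boluses = [(d, "12:30", 5.0, d >= 3) for d in range(8)]  # 3 manual
        log = make_log(readings=[(0, "08:00", 100.0)], boluses=boluses)
        result = result_of(detect_adherence_patterns(log), "bolus_calculator")
        assert result.evidence["fraction"] == 0.375
        assert result.present

    def test_zero_boluses_not_evaluable(self):
        log = make_log(readings=[(0, "08:00", 100.0)])
        for pid in ("bg_before_bolus", "bolus_calculator"):
            result = result_of(detect_adherence_patterns(log), pid)
            assert not result.present and not result.evaluable and result.reason


class TestDashboard:
    def test_csii_dashboard_has_19_applicable_patterns_in_5_blocks(self):
        log = make_log(readings=[(d, "08:00", 100.0) for d in range(5)])
        dash = run_dashboard(log)
        assert len(dash.applicable_ids()) == 19
        assert set(dash.by_block()) == {"variability", "hypoglycemia",
                                        "hyperglycemia", "use_of_system",
                                        "adherence"}

    def test_mdi_dashboard_has_12_applicable_patterns(self):
        log = make_log(therapy="MDI",
                       readings=[(d, "08:00", 100.0) for d in range(5)])
        dash = run_dashboard(log)
        assert len(dash.applicable_ids()) == 12
        for pid in CSII_ONLY:
            assert not dash[pid].applicable

    def test_present_implies_applicable(self):
        log = make_log(therapy="MDI",
                       readings=[(d, clock, 60.0)
                                 for d in range(3) for clock in ("09:00", "17:00")])
        for result in run_dashboard(log).results:
            if result.present:
                assert result.applicable

    def test_dashboard_is_deterministic_json(self):
        log = make_log(readings=[(d, "08:00", 100.0 + d) for d in range(5)])
        assert run_dashboard(log).to_json() == run_dashboard(log).to_json()

    def test_evidence_recomputes_the_decision(self):
        log = make_log(readings=[(d, clock, 60.0)
                                 for d in (2, 3, 4) for clock in ("09:00", "17:00")])
        result = run_dashboard(log)["hypo_trend"]
        counts = result.evidence["daily_counts"]
        run_days = result.config["run_days"]
        assert any(all(c > 1 for c in counts[i:i + run_days])
                   for i in range(len(counts) - run_days + 1))


class TestCompareDashboards:
    def _dash(self, readings):
        return run_dashboard(make_log(readings=readings))

    def test_identical_dashboards_all_unchanged(self):
        base = [(d, "08:00", 100.0) for d in range(5)]
        changes = compare_dashboards(self._dash(base), self._dash(base))
        assert {c["status"] for c in changes} == {"unchanged"}
        assert len(changes) == 19

    def test_flag_flip_reported_as_new(self):
        # dense euglycemic base so the added lows flip only the trend flag
        base = [(d, clock, 100.0) for d in range(10)
                for clock in ("06:30", "10:00", "13:30", "16:30", "20:00", "22:00")]
        trend = base + [(d, clock, 65.0)
                        for d in (2, 3, 4) for clock in ("09:00", "17:00")]
        changes = compare_dashboards(self._dash(base), self._dash(trend))
        new = [c for c in changes if c["status"] == "new"]
        assert [c["id"] for c in new] == ["hypo_trend"]

    def test_mismatched_configs_rejected(self):
        base = [(d, "08:00", 100.0) for d in range(5)]
        other = run_dashboard(make_log(readings=base),
                              preset_config("trend_relaxed"))
        with pytest.raises(ValueError, match="config"):
            compare_dashboards(self._dash(base), other)

    def test_mdi_and_csii_dashboards_not_comparable(self):
        base = [(d, "08:00", 100.0) for d in range(5)]
        mdi = run_dashboard(make_log(therapy="MDI", readings=base))
        with pytest.raises(ValueError, match="therap"):
            compare_dashboards(self._dash(base), mdi)
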