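"""Published clinician-agreement data for the automated dashboard.

In the multicenter validation of the automated pattern-detection
dashboard, a panel of 37 endocrinologists each reviewed up to four real
patient reports (two pump-therapy cases, two injection-therapy cases) and
called every pattern present or absent; the published agreement table
reports, per pattern and case, the percentage of clinicians whose call
matched the automated tool.  The two pump cases were reviewed by 35 and
36 clinicians, the two injection cases by all 37, for 145 evaluations in
total.

These constants let :func:`glycopattern.agreement.pooled_agreement`
reconstruct the published per-pattern global agreement column by
n-weighted pooling of the per-case percentages (pump-only patterns pool
over the two pump cases only).
"""

from __future__ import annotations

__all__ = [
    "CASES",
    "CASE_N_RATERS",
    "PER_CASE_AGREEMENT_PCT",
    "GLOBAL_AGREEMENT_PCT",
    "pooled_inputs",
]

#: Case identifiers in table order.
CASES = ("csii_1", "csii_2", "mdi_1", "mdi_2")

#: Clinicians who reviewed each case.
CASE_N_RATERS = {"csii_1": 35, "csii_2": 36, "mdi_1": 37, "mdi_2": 37}

#: Percent of clinicians agreeing with the automated call, per pattern and
#: case.  ``None`` marks pump-only patterns not assessed on injection cases.
PER_CASE_AGREEMENT_PCT = {
    "sd":                    (100.0, 100.0, 83.8, 100.0),
    "lbgi":                  (97.1, 86.1, 94.6, 81.1),
    "hbgi":                  (91.4, 94.4, 94.6, 86.5),
    "hypo_trend":            (88.6, 63.9, 89.2, 27.0),
    "hypo_overcorrection":   (91.4, 33.3, 64.9, 64.9),
    "hypo_time_block":       (74.3, 55.6, 97.3, 86.5),
    "hypo_cartridge_change": (94.3, 100.0, None, None),
    "hyper_trend":           (2.9, 91.7, 70.3, 10.8),
    "hyper_cartridge_delay": (60.0, 77.8, None, None),
    "hyper_overcorrection":  (85.7, 52.8, 73.0, 64.9),
    "hyper_time_block":      (97.1, 91.7, 24.3, 86.5),
    "hyper_missed_bolus":    (74.3, 86.1, None, None),
    "marks_usage":           (82.9, 22.2, 73.0, 81.1),
    "record_count":          (77.1, 66.7, 78.4, 89.2),
    "pump_stops":            (71.4, 61.1, None, None),
    "cartridge_frequency":   (57.1, 75.0, None, None),
    "bg_test_frequency":     (71.4, 69.4, 59.5, 70.3),
    "bg_before_bolus":       (71.4, 63.9, None, None),
    "bolus_calculator":      (82.9, 66.7, None, None),
}

#: The published global (pooled) agreement column, percent.
GLOBAL_AGREEMENT_PCT = {
    "sd": 95.9,
    "lbgi": 89.7,
    "hbgi": 91.7,
    "hypo_trend": 66.9,
    "hypo_overcorrection": 63.4,
    "hypo_time_block": 78.6,
    "hypo_cartridge_change": 97.2,
    "hyper_trend": 44.1,
    "hyper_cartridge_delay": 69.0,
    "hyper_overcorrection": 69.0,
    "hyper_time_block": 74.5,
    "hyper_missed_bolus": 80.3,
    "marks_usage": 64.8,
    "record_count": 77.9,
    "pump_stops": 66.2,
    "cartridge_frequency": 66.3,
    "bg_test_frequency": 67.5,
    "bg_before_bolus": 67.6,
    "bolus_calculator": 74.6,
}


def pooled_inputs(pattern_id: str) -> list[tuple[float, int]]:
    """(fraction, n) pairs for pooling one pattern across its rated cases."""
    pairs = []
    for case, pct in zip(CASES, PER_CASE_AGREEMENT_PCT[pattern_id]):
        if pct is not None:
            pairs.append((pct / 100.0, CASE_N_RATERS[case]))
    return pairs
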