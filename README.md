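# glycopattern

Rule-based glycemic pattern detection for combined self-monitored blood
glucose (SMBG), insulin, carbohydrate and insulin-pump logs — plus the
inter-rater agreement statistics used to validate automated detection
against clinician panels.

## Who this is for

Clinicians and diabetes-informatics developers who work with fingerstick
meter / pump downloads rather than CGM traces. Reviewing 2–4 weeks of
combined device data by hand is slow and error-prone; this package encodes
the systematic "pattern management" reading of such logs as an explicit,
configurable rule engine and renders the result as a red/green dashboard:
**red = pattern present, green = absent**.

## The rules

19 patterns in 5 blocks, every threshold configurable (defaults shown;
comparators are exactly as printed — a strict `>` never fires at equality):

| Block | Pattern | Default rule |
|---|---|---|
| Variability | SD | SD > 70 mg/dL |
| | LBGI / HBGI | moderate-or-high risk category |
| | %CV (optional) | 100·SD/mean > 36 % |
| Hypoglycemia (<70 mg/dL) | trend | >1 event/day on 3 consecutive days |
| | overcorrection | >25 % of hypo events preceded by a hyperglycemic event |
| | time block | >3 events in one block over 7 days |
| | cartridge association* | hypo after >80 % of cartridge changes |
| Hyperglycemia (>160 mg/dL) | trend | >2 events/day for 7 consecutive days |
| | cartridge delay* | change >1 day late while >50 % of readings are hyper |
| | overcorrection | >25 % of hyperglycemias >200 mg/dL preceded by a hypo within <3 h |
| | time block | >3 in one block over 7 days (pre >150, post >180 mg/dL) |
| | missed bolus* | >3 over 4 weeks after >20 g carbs with no bolus in the prior 2 h |
| Use of system | marks | <3 marked readings/day on >50 % of days |
| | records | <3 insulin+carb records/day on >50 % of days |
| | pump stops* | >2 stops/day on >50 % of days |
| | cartridge frequency* | change delayed in >30 % of changes |
| Adherence | BG frequency | <4 readings/day on 80 % of days |
| | BG before bolus* | >25 % of boluses without a reading in the prior 30 min |
| | calculator use* | calculator unused for >25 % of boluses |

\* pump (CSII) therapy only — MDI dashboards report 12 applicable patterns.

The variability block rests on the Low/High Blood Glucose Indices built on
the symmetrizing transform of glucose (mg/dL)

    f(bg) = 1.509·((ln bg)^1.084 − 5.381),   r(bg) = 10·f(bg)²,

with LBGI the mean of `r` over readings with `f < 0` and HBGI the mean over
`f > 0` (both means over all readings). Both vanish at the risk-neutral
glucose ≈ 112.5 mg/dL.

The agreement module provides percent agreement, Cohen's κ
(κ = (p_o − p_e)/(1 − p_e), 95 % CI from the Fleiss–Cohen–Everitt
large-sample variance) and n-weighted pooling Σfᵢnᵢ/Σnᵢ across cases, the
statistics used when a clinician panel's present/absent calls are compared
with the automated dashboard.

## Worked example

Simulate a 4-week pump log with an injected hypoglycemic trend, then run
the dashboard:

```sh
glycopattern simulate --therapy csii --days 28 --seed 7 \
    --inject hypo_trend --out example.csv
glycopattern detect --log example.csv --therapy csii --out dashboard.json
```

or equivalently in Python:

```python
import glycopattern as gp

log = gp.read_patient_log("example.csv", "CSII")
dash = gp.run_dashboard(log)
print(dash.present_ids())
print(dash["hypo_trend"].evidence)
```

which prints

```
['hypo_trend']
{'daily_counts': [0, 0, 0, 0, 0, 2, 2, 2, 0, ...], 'run': [5, 7], 'n_events': 6}
```

— of the 19 applicable patterns only the hypoglycemic trend is red: the log
contains 6 hypoglycemic events, 2 per day on the 3 consecutive days at day
indices 5–7, which satisfies ">1 event/day on 3 consecutive days". The
window summary for this log (`gp.glucose_summary(log.glucose_values())`) is
n=187, mean 118.4 mg/dL, SD 19.5 mg/dL, %CV 16.5, LBGI 0.61, HBGI 0.60 —
all below their flag thresholds, so the variability block stays green.

Named presets capture revised trend definitions
(`--preset trend_relaxed`: hypo trend ≥1/3 days, hyper trend ≥2/4 days),
and any threshold can be overridden through a partial JSON config
(`--config my.json`, e.g. `{"hypo_threshold": {"value": 60, "op": "lt"}}`).

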