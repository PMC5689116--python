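# Methods

## Data model and conventions

A `PatientLog` holds four record streams — glucose readings (mg/dL),
insulin boluses (units, with a calculator-use flag), carbohydrate intakes
(grams) and pump events (stop / resume / cartridge change) — over a closed
window of whole calendar days. Timestamps are naive local clock times at
minute resolution, as meters record them; no timezone or DST arithmetic is
attempted. Days split at local midnight, and anything assigned "per day"
(event counts, record counts) uses that boundary; an event spanning
midnight counts on its start day, which keeps per-day denominators well
defined.

Validation clips records to the window (counted in warnings), keeps the
first of duplicate reading timestamps, drops readings outside the
plausible meter range [10, 600] mg/dL, and warns on non-alternating
stop/resume sequences. CSV is the interchange format (one record per row:
`record_type, timestamp, value, mark, calculator_used, pump_kind`);
vendor binary/PDF exports are out of scope.

**Time blocks.** The five named blocks have no canonical clock
boundaries, so the defaults are a documented convention: nocturnal
00:00–06:00, breakfast 06:00–11:00, lunch 11:00–16:00, evening meal
16:00–21:00, bedtime 21:00–24:00 — fully configurable. A reading's
pre/post phase is its own mark when present; unmarked readings are
inferred preprandial when a carb record follows within 30 min, else
postprandial when one precedes it by 60–120 min (pre checked first), else
no phase. The inference windows exist because several rules need pre/post
semantics even on sparsely marked logs.

## Glycemic indices

SD uses the sample (n−1) denominator, the clinical convention for SMBG
variability, computed over the whole analysis window (a single SD
threshold implies a single window statistic). %CV = 100·SD/mean. With
fewer than two readings SD and %CV are *undefined* (never reported as 0)
and the variability patterns render green with an explicit reason.

LBGI/HBGI use the standard symmetrizing transform
`f(bg) = 1.509·((ln bg)^1.084 − 5.381)` (bg in mg/dL), squared risk
`r = 10·f²`, and one-sided means over all readings. `f` is strictly
increasing with root ≈ 112.52 mg/dL, so series entirely above the root
have LBGI exactly 0 (and symmetrically). Default risk bands, lower edge
inclusive: LBGI minimal <1.1, low 1.1–2.5, moderate 2.5–5, high ≥5; HBGI
low <4.5, moderate 4.5–9, high ≥9. A flag is raised when the category is
moderate or high. The band edges are configurable; all band-edge
comparisons are lower-inclusive / upper-exclusive.

## Event semantics

Qualifying readings (strictly beyond the hypo/hyper threshold, exactly as
the rules print `<`/`>`) merge into one event when successive qualifying
readings are closer than `merge_gap` (default 60 min): the rules count
*episodes*, not fingersticks, and successive low readings within an hour
are one clinical episode. Setting `merge_gap = 0` reproduces
reading-level counting. Intervening normal readings do not split an
event.

"Preceded by" means an opposite-kind event ending within the lookback
*strictly* before the lookback bound and at-or-before the primary start
(`0 ≤ start − end < lookback`), matching the printed "within <3 h". The
hypo-overcorrection rule has no printed window; 3 h is adopted by
symmetry with the hyper-overcorrection rule, configurable. The
hypo-overcorrection qualifier is a hyperglycemic event at the block
threshold (160); hyper-overcorrection primaries use their own printed
threshold (>200) with preceding hypos at the block threshold (70).

Cartridge cycles are the intervals between successive changes; the delay
is `max(0, interval − expected)` with the expected interval defaulting to
the 7-day replacement schedule (configurable — 3 days is also common
practice). Rules needing cycles are "not evaluable" (green, with reason)
when fewer than two changes exist.

## Detector decisions that the rules leave open

* **Time-block rules** evaluate *every* rolling 7-day window inside the
  analysis window ("over 7 days" anchors no specific week); any
  block/window exceeding the count triggers, and per-block maxima are
  returned as evidence. The hypo rule counts events (assigned to the
  block of their start); the hyper rule counts qualifying readings with
  phase-specific thresholds (pre >150, post >180, unmarked readings
  against the block threshold 160).
* **Missed bolus**: a hyperglycemic reading qualifies when a >20 g carb
  record lies in the prior 2 h, no bolus lies in that interval, and the
  intake is not rescue carbs (within 60 min after a hypoglycemic
  reading — configurable). Counting uses a rolling 28-day window.
* **Cartridge-association window** for hypoglycemia after a change is
  unspecified upstream; 6 h after the change is the documented default.
* **"Insulin and CH record <3/day"** states no day share; >50 % of days
  is adopted, mirroring the marks pattern.
* **"On 80 % of days"** (BG frequency) states no comparator; ≥80 % is
  adopted — the single inclusive day-share comparison in the default
  configuration.
* The hyperglycemia block threshold is 160 mg/dL (one published table
  header prints 100 mg/dL, clinically implausible as a hyperglycemia
  bound); configurable.
* Bolus-based adherence patterns are gated to pump therapy by default,
  following the validation study's applicability table, with a config
  switch (`adherence.bolus_patterns_csii_only`) for MDI patients who use
  calculators.
* The advertised-but-undefined 3 further patterns are out of scope; the
  dashboard carries exactly the 19 defined ones (plus %CV when enabled).

Determinism: identical log + config yield a bit-identical dashboard JSON.
`compare_dashboards` is a set difference on present flags between two
runs with matching therapy and config.

## Agreement statistics

Cohen's κ is computed from the 2×2 paired table with p_e from the row and
column marginals. The upstream reports give CIs without a method; the
Fleiss–Cohen–Everitt (1969) large-sample variance with a normal 95 %
interval (truncated to [−1, 1]) is used, cross-checked in tests against
statsmodels. Degenerate cases are reported, not hidden: one constant
rater gives κ = 0 exactly; two identical constant raters give undefined κ
with p_o attached. Missing ratings drop pairwise. Pooling across cases is
n-weighted (Σfᵢnᵢ/Σnᵢ), which equals percent agreement on the
concatenated evaluations. Any adjustment for reviewer sequence or country
is out of scope (model unspecified upstream); statistics here are
unadjusted and documented as such. Interpretation bands: no agreement
(κ<0), not significant (≤0.20), medium (≤0.40), moderate (≤0.60),
substantial (≤0.80), almost perfect (>0.80).

One pooling caveat: reconstructing the published global agreement column
from the published per-case percentages reproduces 18 of 19 rows within
0.1 percentage point; the cartridge-change-frequency row differs by
0.12 pp, consistent with the per-case inputs themselves being rounded to
one decimal.

## Synthetic data

The generator emulates the study's report conditions: 2–4-week combined
downloads (default 28 days) with ~6 meal-anchored marked readings/day
plus an occasional unmarked bedtime stick, three carb intakes and three
calculator-assisted boluses daily (each bolus preceded by a fingerstick
within 30 min), and — for pump therapy — a cartridge change exactly every
7 days. Glucose is lognormal (right-skewed, as SMBG marginals are) with
target mean 120 mg/dL and 15 % CV, clipped to [85, 150] mg/dL. The upper
clip sits at the preprandial time-block threshold rather than at the
hyperglycemia threshold so that marked- or inferred-pre readings can
never leak into the time-block count: the baseline is a guaranteed
negative control under the default configuration, over any seed.

Injectors are constructive, not sampled: each places records satisfying
its pattern's printed rule with margin (e.g. the SD injector adds 8
isolated readings at 500 mg/dL; the hyper-trend injector adds 3 daily
postprandial readings at 170 mg/dL — above the event threshold, below
the postprandial time-block threshold), at clock slots chosen off the
baseline grid and rotated across blocks/days so unrelated detectors stay
quiet. One physiological coupling is unavoidable and whitelisted:
excursions large enough to move HBGI past its band also push SD past
70 mg/dL. A single seed drives per-stream sub-seeds
(`numpy.random.SeedSequence`), so logs are reproducible field-for-field.

What passing round-trip tests show — and what they do not: they verify
the detectors' logic against constructed positives/negatives under clean,
regularly sampled logs. Real downloads have irregular sampling, missing
days, ambiguous marks and concurrent patterns; detection performance
there is a clinical-validation question, not something these synthetic
tests establish.

## Problem sizes and numerics

The round-trip suites run 19 patterns × 20 seeds plus 50 (specificity)
baseline logs of 28 days each — sizes chosen so the full check remains a
matter of seconds while exercising every injector across distinct
baselines. The kappa oracle covers 1 000 random 2×2 tables (agreement to
1e−12); risk-index monotonicity is checked on 200 random series. Exact
threshold-boundary fixtures are built from integer-valued series whose
statistics are floating-point exact (e.g. deviations (−70, 0, +70) give
SD = 70.0 exactly), so strictness tests do not hinge on rounding.

## Known limitations

* CGM traces, basal-rate analytics, temporary basals and suspend-on-low
  semantics are out of scope.
* Phase inference is heuristic; heavily unmarked logs with irregular
  meals may misclassify pre/post phases.
* Multi-rater agreement (Fleiss κ, weighted κ) is not implemented; the
  panel evaluation treats each rater pairwise against the reference.
* The engine flags patterns; it does not recommend therapy adjustments.
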