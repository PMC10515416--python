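# Methods

`ehival` evaluates a three-level (low / moderate / high) predictive alert
stream against episodes of hemodynamic instability (EHI) derived from
vital signs. This note records the models, the estimators, the numerical
conventions and the design choices, in the order the pipeline applies
them.

## Episode definition and detection

An instant is *unstable* when tachycardia and hypotension co-occur:

    HR >= 100 bpm  AND  (SBP < 90 mmHg  OR  MAP < 70 mmHg)

The heart-rate threshold is inclusive by default (`hr_inclusive=False`
gives the strict variant); the pressure thresholds qualify strictly
below. A sample missing heart rate, or missing both pressures, cannot be
evaluated; such samples are skipped and — on continuous streams — break
runs, which is the conservative direction (no instability is fabricated
across unevaluable data).

Detection is modality specific, because the two blood-pressure sources
have incomparable sampling structure:

* **IAP (continuous arterial line, 0.5 Hz).** An episode is a maximal run
  of consecutive qualifying samples whose *time span* (last minus first
  qualifying time) is at least `sustain_s` = 600 s. "Consecutive" means
  inter-sample spacing at most `gap_tol_s` = 4 s, i.e. two nominal
  sample intervals; a larger gap breaks the run. Span, not sample count,
  is compared to the threshold so the rule is robust to sampling jitter.
  The span comparison is inclusive (>= 600 s).
* **NIBP (intermittent cuff, roughly hourly, nurse-validated).** Every
  qualifying recorded measurement is an episode anchor; adjacent
  qualifying measurements (no non-qualifying measurement between them)
  merge into one episode, and a lone qualifying measurement is a point
  episode (onset == offset). No sustain requirement is imposed — it would
  be unverifiable at hourly cadence — and nothing is interpolated between
  validated readings.

Lead-time and prevalence analyses use only the **first** episode per
patient, so an alert run is never ambiguously attributed across episodes.

## Window-level evaluation

Each alert output at time `t` opens a forward-looking window
`[t, t + 3600 s)` (half-open, so an onset at exactly `t + 3600` is not
double-counted). The window's label is positive when any episode interval
intersects the horizon (`overlap` mode, the default — an ongoing episode
counts as an event in the horizon) or when an episode *onset* falls in the
horizon (`onset` mode, provided because the two readings of "presence of
an episode in the next hour" differ exactly on ongoing episodes).
Windows whose horizon extends past the end of monitoring are dropped and
counted, never labelled negative: absence of observation is not absence of
an event.

Predictions are binarised by grouping low with moderate against high
(`positive_set={"high"}`, configurable). From the pooled confusion
counts the suite is standard: sensitivity, specificity, PPV, NPV,
FPR = 1 − specificity, FNR = 1 − sensitivity, F1, incidence. Ratios with
a zero denominator are reported as NaN with a warning, never as zero.

**Ordinal AUC.** With only three score levels, ties dominate, so the AUC
is computed as the Mann–Whitney probability
`P(score_pos > score_neg) + ½ P(score_pos = score_neg)` over all
positive–negative window pairs — equivalent to the trapezoidal area
through the two interior points of the three-level ROC. **AUPRC** is the
area under the precision–recall polygon through the operating points at
thresholds {>= high, >= moderate, >= low}, with linear-in-recall
interpolation and an anchor at (recall 0, precision of the first
non-empty point); an uninformative score then scores exactly the
incidence, the correct PR baseline.

**Patient-level bootstrap.** Confidence intervals resample *patients*
(not windows) with replacement, 1000 times by default, recomputing the
statistic on each resample's pooled windows; the interval is the
percentile interval at (1±level)/2. Resamples where a statistic is
undefined are dropped and counted. Implementation note: every statistic
above — including AUC and AUPRC — is a function of the pooled 3×2
(category × label) contingency table, so each patient is reduced to a
table once and a resample is a sum of tables; this makes 1000 resamples
on millions of windows a vectorised operation with results identical to
literally pooling resampled windows.

**Reconstruction from published summaries** (`metrics_from_summary`):
per-category output counts plus incidence and sensitivity determine the
confusion table — `N = n_low + n_mod + n_high`,
`positives = round(incidence·N)`, `tp = round(sensitivity·positives)`,
`fp = n_high − tp`, `fn = positives − tp`, `tn = N − n_high − fn` — from
which all derived measures follow. Because the inputs are printed at 3
significant figures, derived percentages carry roughly ±0.25 percentage
points of rounding uncertainty. Inconsistent inputs (negative implied
counts) raise an error rather than clipping.

## Lead time

The lead time of an episode patient is the duration of the *unbroken* run
of high-risk outputs immediately preceding the first onset: walking
backward from the latest output strictly before onset, the run extends
while each output is high and the gap to the previous kept output is at
most `cadence_s + gap_tol_s` (defaults 120 s + 0 s). A single
lower-category output or an over-cadence gap ends the run; earlier,
non-contiguous high runs earn no credit — deliberately conservative. A
patient whose latest pre-onset output is not high counts in the
denominator of the lead fraction but contributes no lead value.
Summaries report the lead fraction, then median/Q1/Q3 (linear
interpolation), mean, sample SD (n−1), min and max of the lead hours, and
the same summaries for monitoring time available before onset.

## Risk stratification and pre-event prevalence

Per-category risks are computed on *exactly* the window set the
window-level evaluation uses (same horizon, same truncation exclusions),
so the window-weighted mean of category risks equals the overall
incidence by construction; risk ratios are taken against the low
category. Pre-event prevalence cuts the hours before first onset into
disjoint backward bins `[onset−(k+1)h, onset−k h)` (an output exactly at
onset belongs to no bin); a patient enters a bin's summary only with at
least one output in it, which is why bin patient-counts decline with
distance as monitoring-before-onset runs out. Group contrasts of
per-patient high-risk fractions use a two-sided Wilcoxon rank-sum (exact
enumeration with midrank ties for combined n <= 12, tie-corrected normal
approximation otherwise) and a two-sided Welch t-test — Welch because the
two groups' spreads plainly differ; the pooled-variance variant is a
flag.

## Synthetic cohorts

The clinical data this design targets are restricted and the alert
analytic is proprietary, so the generator reproduces the *statistical
structure* the pipeline assumes, giving every estimator a known target:

* modality drawn per patient (default 14.5% arterial line), monitoring
  duration log-normal (default median 12 h, sigma 0.8 — the defaults are
  deliberately exposed, as no public duration distribution exists);
* per-patient event probability 9.6% (NIBP) / 46.4% (IAP); at most one
  event per patient, placed at a uniform fraction (0.3–0.8) of the
  monitoring duration, default duration 30 min;
* vitals at the modality cadence (0.5 Hz, or hourly with ±20% uniform
  jitter) from per-sample Gaussians — baseline HR 75±8 bpm and SBP
  125±10 mmHg, chosen so that the joint probability of a *spurious*
  qualifying sample is ~3·10⁻⁶ and chance episodes are negligible even
  at cohort scale; MAP = (SBP + 2·DBP)/3 with DBP = SBP − pulse-pressure
  draw (40±5 mmHg), so MAP <= SBP always;
* inside the event interval every sample satisfies the instability
  predicate by construction (HR clamped >= 100.5, SBP clamped <= 89);
  transitions occupy at most 5 minutes on each side, during which heart
  rate ramps toward the event level while the pressures hold just above
  the hypotension thresholds and collapse only at the event boundary —
  compensated tachycardia preceding abrupt decompensation. This clamp is
  what makes the qualifying interval *exactly* the event interval, so
  detected episodes align with ground truth and construction-implied
  estimands are exact rather than approximate;
* cuff-monitored event patients additionally get one charted measurement
  at the exact onset (a nurse charting during deterioration); hourly
  sampling would otherwise miss most sub-hour events entirely and no
  point-rule detector could recover them;
* alerts every 120 s, independent draws given the regime: P(high) =
  `p_high_pre` over `[onset − lead_hours, offset]` and `p_high_stable`
  elsewhere, with P(moderate) = `p_mod_stable` throughout. The elevated
  regime deliberately covers the event itself, not only the pre-onset
  lead interval: windows during the event are positive, and only with
  this coverage does the construction-implied window sensitivity equal
  `p_high_pre` exactly (with `lead_hours` >= the horizon), the property
  the recovery and coverage tests rely on.

What the generator does **not** model: alert autocorrelation (real
analytics smooth over time; independent draws make recovered lead-time
medians much shorter than `lead_hours` unless `p_high_pre = 1`),
multi-event patients, treatment effects that avert events, waveform or
HRV physiology, and measurement error on vitals. Passing recovery tests
therefore demonstrates correctness of the *estimators* under the assumed
coupling structure, not clinical performance of any analytic on real
patients.

## Problem sizes and numerical conventions

Recovery checks use 500-patient cohorts (≈ 10⁵–2.5·10⁵ windows), where
binomial error on a recovered proportion is well under the ±0.03
tolerance; bootstrap coverage uses 200 replicate 100-patient cohorts with
1000 resamples each, sizes at which the whole suite runs in a few minutes
on one CPU. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); the pipeline derives per-stage seeds from a
single root seed via `SeedSequence`, so identical configuration yields
byte-identical output bundles. Quantiles use numpy's linear
interpolation; SDs are sample SDs; times are stored as float seconds from
per-patient monitoring start (the source data are deidentified and every
statistic is a duration), serialised with 3 decimal places.

## Known limitations

* The NIBP point rule inherits the charting convention of the source
  data; if recorded times lag measurement times, labels shift by the
  charting delay. The schema assumes recorded time == measurement time.
* With three score levels the ROC has only two interior points; AUC
  comparisons against continuous-score analytics are not like-for-like.
* Percentile intervals (chosen over BCa for transparency and because the
  reference analysis specifies patient-level resampling only) undercover
  slightly at 100 patients — measured ≈ 94% for a nominal 95% interval in
  the coverage suite.
* `metrics_from_summary` is exact arithmetic on rounded inputs; it cannot
  recover more precision than the summaries carry.
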