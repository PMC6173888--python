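# Methods

## Scope and data model

`swaft` models a two-phase, single-ward wearable feedback study: a
non-randomised observation phase (no feedback for anyone) followed by a
parallel pilot RCT with 1:1 concealed allocation to feedback or no-feedback
(control). The atomic analytic unit is the **epoch record** — one
(patient, date, period) row holding an activity score, a worn flag and the
worn fraction. All analytics consume tidy pandas frames in the documented
CSV dialects; dates are ISO-8601, times local clock with no daylight-saving
handling (single site, single timezone).

## Epoch schedule

The monitored day is 08:00–17:00, tiled by four 2-hour periods and one final
1-hour period (a battery-life compromise on the original hardware). Windows
are half-open `[start, end)`, so every daytime instant belongs to exactly one
period. The fifth period's variable real-world duration is modelled as
missing data rather than a variable-length window; analytics exclude period 5
from daily totals regardless (see below).

## Activity score

No standard formula exists for the arbitrary-unit activity score such
watches report, and its absolute scale is not meaningful; only day-to-day
relative comparisons are. The score implemented here is the rectified,
gravity-subtracted signal vector magnitude with a dead-band, integrated over
the window:

    AS = sum_i m_i * dt,   m_i = | ||a_i|| - 1 |  if m_i >= dead_band else 0

* `dead_band` (default 0.05 g) suppresses accelerometer noise when the wrist
  is still; the comparison is inclusive (≥), as are all thresholds in the
  package.
* `dt` is the median inter-sample gap, making the score robust to occasional
  dropped samples.

The construction gives the properties analytics rely on: non-negativity,
exact additivity over a partition of the window, zero for a perfectly
stationary trace in any orientation, and insensitivity to the direction of
the constant gravity component. Absolute magnitudes are **not** comparable
to any published device's units.

## Wear detection

Wear is inferred from movement: the window is tiled into 60 s sub-windows,
one counts as *active* when the variance of the vector magnitude of its
samples is ≥ 1e-4 g², and the watch is deemed worn when ≥ 25 % of
sub-windows are active. Tiles (rather than overlapping strides) keep the
sub-window count well-defined and make the fraction exactly the proportion
of active minutes. The thresholds are deliberately conservative:
movement-based detection cannot distinguish a worn-but-motionless wrist from
an unworn watch, so wear time is under- rather than over-estimated. The
fraction is monotone in movement amplitude by construction.

## Goal rule and feedback display

After the baseline day (intervention day 1, which never shows feedback in
any mode), each period's goal is 1.05 × the activity recorded in the same
period the preceding weekday; Friday's scores feed Monday's goals, and
weekend recordings never enter the goal chain. The goal deliberately tracks
the previous day rather than a running maximum, so it can ratchet down after
a low-activity day — faithful to the stated rule rather than to a
monotone-goal idealisation.

Gaps are resolved in a fixed fallback order: most recent recorded
same-period score → baseline score → a configured default (0 AS, i.e. an
always-met goal), with the source flagged on every emitted event so
downstream reports can identify fallback days.

The display is a four-level bar: level 1 below ⅓ of the goal, level 2 from
⅓, level 3 from ⅔, level 4 at or above the goal; a zero goal is already met
(level 4). State is recomputed at every ingested sample, so within a period
the emitted level is non-decreasing. Control mode carries no bar information
at any point — the `FeedbackState` type makes a control-mode bar level
unrepresentable. Period 5 runs through the same machinery symmetrically, but
analytics exclude it.

## Screening and randomisation

Screening is a pure conjunction of eight criteria; "less than 4 months after
stroke onset" is operationalised as < 122 days (configurable). A candidate
failing *only* the two-stage-command criterion is flagged for a 3-day
re-screen instead of exclusion. Simple (Bernoulli) randomisation from a
seeded, pre-generated sequence is the default — it reproduces the
imbalanced splits (e.g. 14/16 at n = 30) that spreadsheet-style sequences
produce — with permuted blocks as an option. The sequence is generated
entirely from the seed before any registration, so allocations are
independent of anything observed later; registration of an ineligible
candidate requires an explicit override and flags the record invalid so it
can be excluded post hoc, with the deviation recorded.

## Feasibility analytics

* **Daily total**: sum of AS over periods 1–4 only (08:00–16:00); period 5
  is excluded because its duration varies with battery life. Partial days
  are summed and flagged.
* **Exceedance**: a post-baseline day exceeds baseline when its total
  strictly exceeds the day-1 total; the baseline day therefore counts in the
  recorded-day denominator but can never count in the numerator. Patients
  without a recorded baseline day are excluded. If day 1 itself was not
  recorded, the first recorded day serves as the baseline (it is the first
  day the watch could have measured).
* **Adherence**: each recorded day falls in exactly one category by the
  number of worn analysis periods {4, 3, 2, 1, 0}. Percentages are reported
  on *both* denominators — expected weekdays (from first watch day to last
  trial day) and recorded days — because published adherence tables mix the
  two bases between rows; the package computes both and leaves the choice
  explicit. Weekend recording can push recorded days above the weekday
  count, so ≥1-period rates may legitimately exceed 100 %.
* **Flow rates**: recruitment = recruited/admitted; retention at discharge
  and follow-up divide by valid patients; follow-up among discharged divides
  by discharge completers. Integer percent, round-half-up. Adherence and
  exceedance rates are reported to 1 decimal.
* **Activity summary**: median and quartiles (inclusive linear-interpolation
  convention) of daily totals per group at selected watch-day indices, where
  the day index counts weekdays from the first watch day.
* A patient's trial end is the discharge date when recorded, else the last
  recorded watch day (length of stay estimated from the watch data).

## Synthetic cohort

The simulator generates a full trial from one seed: admissions over a
30-week accrual window, screening and consent (defaults 0.20 × 0.55 ≈ 11 %
recruitment), a 40 % observation-phase share, lognormal length of stay
(mean 24 d), and an intervention of up to 15 watch weekdays within 21
elapsed days or until discharge.

Activity is a per-patient lognormal level (log-mean ln 120, log-sd 0.8 —
wide, matching the high inter-personal variability of ward populations)
× a daily trend (default flat) × an arm effect (multiplicative uplift on
post-baseline days in the feedback arm, default 0.15) × per-epoch lognormal
noise (log-sd 0.45), with period 5 weighted half. Wear is Bernoulli per
period (default 0.95, giving ≈ 81 % all-four-period daily adherence, the
high-adherence regime the RCT arms showed); a day with no worn period
produces no records. Weekend days are recorded with probability 0.25 and
never carry goals. Dropout is missing-at-random given arm and day: 22 %
of recruits drop post-baseline, and 62 % of completers are contactable at
3 months.

What the simulator does *not* emulate: within-day autocorrelation of
activity, therapy-session structure, wear-time that varies with illness
severity, informative (outcome-dependent) dropout, and clinical outcome
trajectories beyond completion flags. Passing tests on simulator output
therefore demonstrate the correctness and statistical behaviour of the
pipeline, not claims about real patients.

`simulate_accel_trace` closes the loop at the signal level: it emits a trace
whose computed score lands on a requested level (rectangular supra-dead-band
bursts spread evenly over the worn stretches; quantisation keeps the error
well inside 5 % for levels ≳ 1 AS) and whose non-worn stretches have exactly
zero variance. Levels so small that the implied burst amplitude falls below
the dead-band cannot be represented and round away from the target.

## File QC

Download folders are audited the way a coordinating centre would: duplicate
files detected by hashing each per-(patient, date) payload, patient ids
validated against the registry, and each patient checked for a single
consolidated file spanning their recorded dates (the end-of-intervention
full download). Unparseable files are listed, never fatal.

## Problem sizes and numerical choices

The test suite and the acceptance script run the simulator at n = 1000
recruits for retention recovery and n = 200 RCT patients for arm-effect
checks, with 3-standard-error bands computed from the realised samples
(patient-level proportions for the clustered exceedance comparison). Rate
reproductions from published counts are exact arithmetic. All randomness is
driven by explicit seeds; identical configuration and seed give
byte-identical simulator output.
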