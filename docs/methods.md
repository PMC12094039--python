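# Methods

## Data model

A **visit record** is one preprocessed GreenFeed visit: animal and unit
identifiers, start/end timestamps in naive local trial time (the
behavioural time windows are farm-local, so no timezone conversion is
applied), the usable measurement duration in minutes, and per-gas
production rates in g/d for CH₄, CO₂, O₂ and H₂.  A gas cell that is
blank, non-numeric, non-finite or exactly zero is treated as *missing
for that gas only*: a live animal never produces exactly 0 g/d, and
partial gas coverage is a normal state of these exports, so a record may
carry CO₂ but no CH₄.  A **feed event** is one pellet-drop log line
(animal, unit, timestamp, drop count ≥ 0).

Readers accept a configurable column map because C-Lock export dialects
vary; durations parse either as decimal minutes or `HH:MM:SS` text.
Malformed rows (bad ID, unparseable timestamp, end before start,
duration exceeding the visit interval beyond a 1 µs-scale tolerance) are
dropped and tallied by reason, never raised — mid-trial monitoring must
keep working on dirty files, and the ingest report preserves
`kept + dropped = read` accounting.

Animal IDs are canonicalized (trim whitespace; strip leading zeros from
all-digit IDs) and optionally mapped RFID → farm ID through a roster.
Both sides of the roster are canonicalized and chained mappings are
rejected, which makes canonicalization idempotent — applying it twice
can never change an ID again.  Whether visit files carry RFIDs or farm
IDs is installation-dependent; the roster mechanism covers both, and by
default every ID present in a file is processed (a roster restricts and
relabels but is never required).

## Filtering and aggregation

The pipeline runs four stages in a fixed order:

1. **Duration filter.** Keep records with usable duration ≥ `min_time`
   minutes, boundary inclusive ("minimum duration to be included").
   `min_time < 2` is rejected: shorter visits do not yield a valid
   measurement.
2. **Outlier masking.** Per gas, compute the mean and sample SD over
   *all* non-missing values (globally, across animals) and mask values
   outside `mean ± k·SD` (default `k = 3`).  This is a single pass —
   statistics are deliberately not recomputed after masking, because the
   procedure is a one-shot removal, not an iterative trim.  Masking is
   per gas; a record that loses every gas is dropped.  With fewer than
   two values the SD is undefined and nothing is masked; an SD of zero
   masks nothing (the zero-width band contains its centre).
3. **Daily averages.** Group by animal and the calendar date of the
   visit start.  Per gas, the mean is weighted by each record's usable
   minutes, over records where the gas is present.  Animal-days with
   fewer than `param1` records are suppressed.  A gas with no valid
   contributors is missing, never 0.
4. **Weekly averages.** Weeks are consecutive 7-day blocks anchored at
   the study start date (`week = (date − start)//7 + 1`), so a 46-day
   trial has exactly 7 study weeks; ISO calendar weeks would split the
   trial arbitrarily depending on its start weekday.  Per gas, daily
   means are weighted by the day's total retained visit minutes, and
   animal-weeks with fewer than `param2` distinct days are suppressed.

The weekly weight is the day's *total* minutes, not gas-specific
minutes.  This matches the description of the weighting as based on
total visit record minutes, and keeps one weight per day; it is flagged
as the one place a gas-specific-minutes implementation would differ
slightly when gas coverage is very uneven within a day.

`param1` counts records that survived both filters, since aggregation
operates on the filtered set.  All groupings sort by animal then
date/week, so identical inputs give identical outputs with no hidden
iteration-order dependence.

Descriptive summaries report the sample SD (n−1); a single value reports
SD 0 rather than missing so report tables stay total, and CV = 100·SD/mean
is 0 whenever the mean is not positive.

### Parameter sweep

`param_grid` evaluates every `param1 × param2 × min_time` combination on
the same data, reporting daily/weekly record and animal counts and the
mean ± SD of the chosen gas across daily and weekly rows (missing when a
cell retains nothing).  Retention is provably non-increasing in each
parameter, which the test suite asserts across seeded simulations.
`grid_correlation` returns the Pearson correlation of any grid column
against any parameter, undefined (None) with fewer than 3 usable rows or
zero variance.

## Reports, intake, visitation

The monitoring report bins visits into four behavioural windows
(22–04 h, 04–10 h, 10–16 h, 16–22 h; half-open on the right, the first
wrapping midnight), tabulates records per day (zero-filled over the
study window) and per animal (records/day divides by the *study length*,
not days visited), summarizes per-animal gas distributions by the
boxplot five-number summary with 1.5·IQR whiskers, and — in final mode —
adds an unfiltered per-hour diurnal profile.  Every printed number comes
from the corresponding library function; rendering is deterministic.

Pellet intake is `drops × grams_per_drop` summed per animal-day across
units.  `grams_per_drop` is mandatory: cup masses vary by feed and
calibration, and a built-in default would silently corrupt intakes.
Drops are summed by each event's own calendar date, so total intake
equals `grams_per_drop × total drops` exactly; the auxiliary `n_visits`
column counts gap-delimited visits (events ≤ 300 s apart belong to one
visit, configurable) dated by their first drop, so a visit spanning
midnight contributes drops to both dates but is counted once.  Intake
totals never depend on the gap rule.

Visitation monitoring prefers feedtimes over visit records because
early-trial visits are often too short to survive preprocessing; any
drop-receiving head entry counts as visiting.  Non-visitors are rostered
animals with zero visits in the trailing monitoring window.

## The simulator

The generator emulates a dairy trial of the motivating kind: 32
mid-lactation cows, 46 consecutive days, one unit.  Components:

- **Visit process.** Per animal-day, visit count ~ Poisson(rate); the
  default rate 2.32 visits/animal/day reproduces a ~3,400-record trial
  of that shape.  Visit hour follows a 24-bin intensity (quiet
  overnight, busiest morning-to-afternoon), with the start second
  uniform within the hour.
- **Durations.** Lognormal in minutes (μ = 1.45, σ = 0.45 on the log
  scale: mode ≈ 3.5 min, ~5 % of visits below 2 min), so the duration
  filter has realistic work to do.
- **Gas values.** Each animal draws a latent mean per gas,
  `herd_mean + N(0, animal_sd)`; a visit observes
  `animal_mean × (1 + a·(c(t) − c̄)) + N(0, visit_sd)` where `c(t)` is a
  24-h cosine and `c̄` its average under the visit-time distribution.
  Mean-centring the modulation makes the latent animal mean equal the
  expected record-level value, so the returned truth is exact, not
  asymptotic.  The cosine peaks at 14:00 by default, placing its
  minimum at 02:00: emissions are lowest before morning feeding and
  rise from ~07:00 through the afternoon.  (A mid-morning peak was
  considered, but a single harmonic would then bottom out near 22:00,
  contradicting the observed early-morning minimum; the afternoon peak
  keeps both features with one harmonic.)
- **Contamination.** With probability 1 % a record is an outlier: with
  equal odds a *spike* (all gases × 3) or a *dropout* (× 0.02, a
  near-total signal loss, as when an analyzer fails mid-visit).  A
  symmetric ÷3 low tail was rejected on arithmetic grounds: at the
  herd's 31 % record-level CV, a ÷3 value sits only ~2.1 SD below the
  mean and would never be masked, leaving the 3·SD filter nothing to
  catch on the low side.
- **Calibration.** `paper_like` sets the visit-level noise SD per gas by
  analytically inverting the variance decomposition (between-animal +
  diurnal + visit noise, then the multiplicative outlier factor) so the
  simulated record-level SD hits the herd targets — CH₄ 375 ± 118 g/d
  and CO₂ 12,264 ± 1,967 g/d.  For CH₄ the inversion succeeds; for CO₂
  (CV 16 %) the ×3 spikes alone exceed the target spread, the noise term
  clamps at zero, and the realized record-level SD is ≈ 2,500 g/d — a
  known, documented divergence.  O₂ (8,900 g/d) and H₂ (2 g/d) herd
  means are not herd-reported quantities and are set to physiologically
  plausible values (O₂ via a respiratory quotient near 1 against CO₂).
  The between/within variance split (between-animal SD 60 g/d CH₄) is a
  modelling choice; real data do not pin it down.
- **Feed events.** One per visit, drops uniform on {2,…,8}.

All randomness flows through one `numpy` Generator seeded from the
config; identical configs give bit-identical records, events and files.
Gas values and durations are rounded to 2 decimals and timestamps to
whole seconds so that written CSVs round-trip field-identically.

What the simulator does **not** model: unit competition and queueing,
airflow-dependent measurement quality, day-to-day (e.g. diet-change)
drift in true emissions, RFID misreads, and within-visit rate dynamics.
Passing tests therefore demonstrate the correctness and calibration of
the *processing* under a realistic visit/emission structure, not the
behaviour of any particular farm's data.

## Problem sizes and numerical choices

The test suite and acceptance script run simulated trials at the study's
native scale (32 animals × 46 days, ~3,400 records) for pipeline checks,
~50,000 records (300 animals) for record-level moment checks, and ~10,000
records per replicate for masking-rate calibration (pooled over many
seeds).  Weighted means are plain floating-point sums (convex
combinations of g/d-scale values; no compensated summation is needed at
these magnitudes), verified against brute-force recomputation to 1e-9
relative.  Duration-interval consistency uses a 1e-6 min tolerance.  The
diurnal mean/variance under the visit-time law is evaluated on a
1-minute grid (error ~1e-6, far below the 5 % calibration bands).

## Known limitations

- Time-window and per-day tables assign records outside an explicitly
  given study window to no row; with the default (data-spanning) window
  this cannot occur.
- The single-pass outlier filter is not robust in the statistical sense:
  heavy contamination inflates the SD and widens the band.  That is a
  property of the procedure itself, preserved intentionally.
- CO₂'s simulated record-level spread exceeds its target (see
  Calibration above).
- XLSX output is value-stable but not byte-stable across library
  versions; CSV output is byte-stable.
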