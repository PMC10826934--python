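# Methods

This note records the models, conventions and numerical choices behind
`actspace`, and what the synthetic-data experiments do and do not show.

## Study design being modeled

A seven-day passive-sensing protocol: participants' phones report location
fixes (timestamp, WGS84 lon/lat, accuracy radius = 68% confidence in
meters) continuously, plus three EMA prompts per day asking whether the
participant is at home. Participants are classified urban (RUCA codes 1–3
of the residence county) or non-urban (4–10). All timestamps are stored in
UTC; one study-level IANA timezone (default `America/New_York`) drives
calendar-day and wake-window logic. The study window is half-open
`[start, end)`.

## Cleaning

Order is fixed: window restriction → distance filter → speed filter.

*Normalization.* Fixes are sorted by time; exact duplicates collapse; when
two fixes share a timestamp, the smaller accuracy radius (more certain fix)
wins, so timestamps are strictly increasing afterwards.

*Distance filter.* The pooled distance-gap SD (sample SD, ddof = 1) is
computed once over all participants' consecutive gaps and frozen;
threshold = k·SD with k = 3 by default. An absolute threshold in meters can
replace k·SD, e.g. to reproduce a cut-off published from other data. The
scan is a single forward pass per trajectory that keeps a fix iff its
distance to the last **retained** fix is within threshold. This
"sequential survivor" rule means one corrupted fix costs exactly one
point: the clean fix after a jump is re-anchored to the survivor before
it, rather than being condemned by its gap to the artifact. If the pooled
SD is zero (degenerate, all gaps identical) the filter is a guarded no-op.

*Speed filter.* Same survivor scan on the recomputed gaps with an absolute
cut of 250 m/s, strict inequality (a gap at exactly 250 m/s survives).

*Accounting.* The cleaning report reconciles exactly:
`retained = input − outside_window − distance_outliers − speed_outliers`
(input counted after duplicate collapse).

*Known property of SD-based thresholds.* The distance filter is **not**
idempotent under a recomputed threshold: artifacts inflate the first-pass
SD, so after their removal the recomputed 3·SD can collapse to
ordinary-movement scale and a second pass would then remove genuine trip
fixes. Re-cleaning already-cleaned data is therefore only stable with the
threshold frozen from the first pass (the absolute-threshold override);
the test suite asserts exactly that. The absolute speed filter is
idempotent unconditionally.

*Degenerate noiseless data.* With perfectly noiseless fixes most distance
gaps are exactly zero, the SD collapses, and a 3·SD rule flags ordinary
movement. This is a property of the statistic, not of the code; the
filter presumes GPS noise gives the gap distribution realistic spread.
Recovery experiments on noiseless cohorts therefore skip cleaning (there
is nothing to clean).

## Quality metrics

Two pooling universes are deliberately distinct:

* Cohort quality tables are **statistics of participant-level statistics**
  (each metric computed per participant first, then mean/SD/median across
  participants per group). Participant stats are flagged undefined (NaN,
  never zero) below two gaps.
* The outlier-incidence table pools at the **GPS-point level** within each
  residence × activity-setting cell. A gap inherits the setting label of
  its later fix. Default outlier cut-offs: time gap > 1 h, distance gap
  > 1 km, accuracy > 1 km.

Temporal coverage counts distinct whole minutes (indexed from the window
start) containing at least one fix, divided by total window minutes
(10,080 for seven days). Participation days are distinct local calendar
dates with at least one fix.

## Home geofencing and wake time

Buffers (20/50/100 m) are built by projecting the footprint into a
spherical azimuthal-equidistant frame centered on its centroid, buffering
in meters (64 quadrant segments), and reprojecting. At building scale the
projection distortion is orders of magnitude below GPS accuracy; the
Minkowski-sum area test verifies ~10⁻⁵ relative error for a 10 m square
with a 20 m buffer. Buffer 0 is the raw footprint; containment is boundary
inclusive. Buffers are nested by construction, which makes the wake-time
proportion and the at-home concordance diagonal non-decreasing in buffer
size.

Each minute of the 08:00–20:30 local wake window is labeled by the single
fix nearest the minute midpoint (a majority-vote option exists for
sensitivity analysis); minutes without a fix are `no_data` and excluded
from the denominator rather than imputed — the conservative analogue of
self-reported time use. The proportion is undefined when no minute can be
labeled. Group 95% CIs are the normal approximation mean ± 1.96·SD/√n,
clipped to [0, 1], undefined below n = 2.

Wall-clock wake windows assume no daylight-saving transition inside the
study window; the default synthetic start date (2021-04-05) satisfies
this.

## EMA–GPS concordance

Self-report and sensor clocks never agree to the second, so "same
timestamp" is operationalized as the same whole minute, with the fix
nearest the EMA second chosen when several share the minute and a
configurable tolerance (default 60 s). Unmatched EMA records are counted,
never dropped silently. Tables are 2×2 (GPS rows × EMA columns) with
column percentages (columns sum to 100%); empty columns give undefined
percentages. Strata are overlapping marginal views (urban, non-urban,
android, ios), not a four-way cross. `actspace.reference` carries the
published validation-study counts used as fixed benchmark inputs; the
package computes their percentages at run time and fits nothing to them.

## Synthetic cohort generator

The generator's defaults mirror the study design: 122 urban + 40
non-urban participants, iOS fractions 0.623/0.675, 7 days, 3 EMA
prompts/day, 60% of wake time at home, 5% day-dropout, 15% designed
GPS-silent EMA minutes. Device models are log-normal for both cadence and
accuracy (right-skewed, median ≪ mean, as passively sensed GPS shows);
default medians are 2 s / 7 m (iOS) and 30 s / 19 m (Android), preserving
the iOS-denser-and-more-accurate ordering. Test and acceptance cohorts use
coarser cadences (10 s / 40 s medians) and smaller n so experiments run in
seconds to minutes; the ordering and every structural property are
unchanged by that scaling.

Trips are straight-line, constant-speed, out-and-back excursions to
destinations 0.2–10 km away, aligned to whole minutes so the ground-truth
minute schedule is exact; the setting layer is two labeled rectangles and
all positions (homes, trips, noise-clipped fixes) stay strictly inside
their rectangle, making setting labels exactly recoverable. Position noise
is isotropic Gaussian (default SD 10 m, clipped at 100 m); 0 disables it.

Artifacts: *jumps* replace a fix's coordinates with a location 50–100 km
away (each produces two huge gaps, in and out); *teleports* insert a fix
one second after an anchor, 300–500 m away — above 250 m/s but far below
any plausible jump threshold, so only the speed filter can catch them.
Labels record every injection; `recovery_stats` compares surviving
timestamps against the labels.

What the generator does **not** emulate: road networks, multi-day travel,
device-specific burst/sleep sampling patterns, urban-canyon accuracy
degradation, EMA misreporting, or clock drift. Passing recovery tests
therefore demonstrate the pipeline's correctness on data satisfying the
generator's assumptions, not the field behavior of any particular device.

A labeling caveat: in a trip's departure or return minute the chosen fix
can lie in the first or last seconds of travel, still inside the home
buffer, so the minute is labeled home while the schedule truth says away.
This affects at most `2 × trips/day` minutes per day and is why minute
labels are asserted to agree with the schedule up to a 0.1% mismatch rate
rather than exactly.

## Numerical conventions

* Distances: haversine on a sphere of radius 6,371,008.8 m (mean Earth
  radius); verified against a spherical-law-of-cosines oracle to 1e−6
  relative (the oracle itself carries a ~0.1 m absolute roundoff floor
  near zero distance).
* Sample SDs use ddof = 1 throughout; medians are numpy's linear
  interpolation.
* Point-in-polygon is boundary-inclusive (`covers`), first-containing
  polygon wins in layered lookups.
* All randomness flows from numpy `default_rng` seeds; per-participant
  child seeds are drawn once from the cohort seed, so cohorts are
  reproducible and participant streams independent.

## Problem sizes

The test suite simulates cohorts of 5–10 participants at 10–40 s cadences
(~10⁵–10⁶ fixes) and the artifact-recovery experiment uses 50
participants × 7 days (~1.3 million fixes, ~16,000 labeled artifacts);
`scripts/acceptance.py` uses the same sizes. These were chosen as the
smallest cohorts at which the binomial error on the recovery rates is
negligible against the 99% / 0.5% margins being demonstrated.
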