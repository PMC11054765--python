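# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `cpts` package in one place. It states nothing the test
suite or `scripts/acceptance.py` does not itself compute.

## The quantity being estimated

Cumulative plantar tissue stress is a daily mechanical dose at the ulcer
site. For conditions c ∈ {in-device, non-device}:

- model 1: `CPTS_day = Σ_c PTI_c · strides_c / 1000` (kPa·s × strides →
  MPa·s; the /1000 conversion is applied explicitly),
- model 2 additionally multiplies each condition's term by its thermal
  stress response, a dimensionless shear surrogate.

A participant's summary is the arithmetic mean over *valid* monitoring days,
in MPa·s/day. Stride counts are used as the cycle unit throughout (one full
gait cycle of a limb); outputs are labelled strides/day. The two terms of
the sum come from different sensors, so each factor carries its own
completion status and the fusion degrades gracefully: a participant with a
failed thermal measurement still gets model 1; a participant with fewer than
4 valid activity days gets a "non-adherent" status and no CPTS.

## Plantar pressure (PTI, PPP)

Stance phases are contiguous runs of frames whose total force
(Σ pressure × sensor area; kPa·cm² × 0.1 = N) stays at or above a threshold
for at least `min_stance_s`. Defaults: threshold 5% of body weight (34.3 N
for the 70 kg default), `min_stance_s` 0.1 s. Detected runs are then
expanded outward to a noise floor (5% of the threshold, capped at the
neighbouring phase) so the phase spans the full loading curve from foot
contact to lift-off; without this, the force threshold truncates the low
tails of each stance and biases PTI low by several percent — the expansion
brings the trapezoidal PTI of a half-sine stance within 1% of the closed
form 2PT/π at 50 Hz.

The regional curve at the ulcer site is, per frame, the **maximum** over the
masked sensors (cluster-peak reduction, the convention of in-shoe analysis
software); an area-weighted mean is available via `reduction="mean"`. PPP is
the maximum of that curve over the stance, PTI its trapezoidal integral.
Whether the original analyses averaged or maximised across steps is not
derivable from the published tables, so both are exposed; the default
aggregates steps by the **mean**, which is more stable for small trials.

Walking protocol: the first and last `trim=2` steps are dropped
(gait initiation/termination) and at least 12 midgait steps are required,
otherwise the trial is invalid. Two-step barefoot protocol: exactly four
single-contact platform trials, averaged. The platform ulcer mask is all
grid cells within 10 mm of the configured ulcer coordinate (the region size
is this package's choice; published analyses used vendor software whose
region definition is not stated). Walking speed is kept as metadata only; no
speed correction is applied.

## Weight-bearing activity

The vendor stride-extraction and monitor-wear algorithms for trunk
accelerometers are proprietary; the package uses documented stand-ins,
validated only against synthetic ground truth and not claimed equivalent:

- stride detection: 4th-order Butterworth band-pass (0.5–3 Hz) on the
  vertical channel, `scipy.signal.find_peaks` with 0.4 s minimum distance
  and 0.2 g prominence;
- monitor wear: non-overlapping 60 s windows are "worn" when the standard
  deviation of the acceleration magnitude is ≥ 0.02 g; adjacent worn windows
  merge.

Valid-day rule: a day counts iff monitor wear ≥ 12 h; ≥ 4 valid days are
required, else the participant is non-adherent to the measurement protocol.
Partial days at the record edges are included and subject to the same rule.
When activity arrives as a pre-extracted stride-event file (no raw
accelerometry), daily wear hours are approximated by the first-to-last
stride span of the day — a stand-in, stated as such in the output
provenance. Mean strides/day is computed over valid days only.

## Device wear from temperature, and adherence

An in-device logger samples absolute temperature every 15 min. Donning
drives the reading first-order from ambient toward skin temperature, doffing
back toward ambient. The wear detector is a hysteresis state machine with
slope assistance (the published wear-time algorithm for these loggers is
external to this package):

- wear starts at the first sample with T ≥ 27 °C, or T ≥ 25 °C while rising
  ≥ 0.5 °C/sample;
- wear ends at the first sample with T < 25 °C, or T < 27 °C while falling
  ≥ 0.5 °C/sample;
- a triggered boundary is back-dated to the base of the contiguous monotone
  run that triggered it: a first-order sensor begins its transient
  immediately after the don/doff event, so the event sits at the start of
  the observed rise/fall. On noise-free synthetic logs this recovers on/off
  within one sample (15 min); a plain hysteresis rule that ends wear only at the
  first sub-threshold sample is 3 samples late for a 30-min time constant.

All thresholds are config-exposed. Intervals snap to sample timestamps; log
gaps > 2 h split any spanning interval and emit a warning. Strides are
classified in-device iff their timestamp falls in a half-open [on, off)
interval (a stride exactly at `off` is non-device); strides outside the
log's span are counted non-device with a coverage warning. Adherence is
100 × in-device strides / total strides over valid days. The 15-min
quantisation bounds achievable accuracy: misclassification is concentrated
in the ≤ one sample around each don/doff event, giving a median absolute
adherence error of ~1–2 percentage points on the synthetic cohort.

## Thermal stress response

`TSR = [(post−pre)/pre]_index / [(post−pre)/pre]_contra`, evaluated in °C
exactly as defined — no Kelvin conversion. The definition is therefore not
translation-invariant (adding a constant to all four temperatures changes
the value); this is a property of the printed definition, documented and
passed through rather than corrected, and a unit test pins it. Negative
values (one foot cooled while the other warmed) are legal, propagate into
model 2 unmodified, and are flagged per participant. TSR is undefined when
the contralateral temperature did not change (division by zero) — a
structured error, which downgrades model 2 only.

## Synthetic cohort generator

The generator emulates the study conditions of a two-cohort offloading
study; its defaults are the published cohort IQRs (`cpts.datasets`), drawn
uniformly per participant: AU-style (thermal imaging, insole trials for both
conditions) strides 1015–12456/day, adherence 26.6–68.7%, PTI in-device
60.0–74.7 kPa·s / footwear 67.2–86.3 kPa·s, TSR 0.30–1.07 / −0.15–2.54;
NL-style (no thermal, barefoot platform 2-step for non-device) strides
1400–4232/day, adherence 16.8–85.5%, PTI in-device 48.5–111.0 kPa·s /
barefoot 235.7–626.1 kPa·s. Monitoring spans 7 days with one daily wear
interval (onset 07:30–09:00, duration 11–13 h, uniform). Healed
participants' PTI/PPP targets are scaled by 0.75 so cohort-level group
comparisons have a known direction.

Stream construction and its deliberate idealisations:

- **Pressure**: every stance is a half-sine pulse with P set to the target
  PPP and T = π·PTI/(2P), so the analytic PTI (2PT/π) equals the target
  exactly; one frame lands exactly on each pulse peak (the stance may start
  between frames), making PPP exact too. Mask sensors carry the full pulse,
  a ring of neighbours 40% of it, swing phases are zero. Insole dialect:
  50 Hz, 99 sensors of 2 cm²; platform dialect: 100 Hz, 5 mm grid
  (4 sensors/cm²). Real pressure maps are anatomically structured and noisy;
  none of that is modelled, by design — the half-sine gives a closed-form
  oracle.
- **Strides**: per-day counts are drawn with a 1% coefficient of variation
  around the participant mean, placed in bouts (Poisson mean 30 strides) on
  a 1.1 s cadence grid, a fraction `true_adherence` (to rounding
  granularity) inside the wear intervals and the rest in waking non-wear
  windows; no strides between 00:00 and 06:00. Real day-to-day activity
  varies far more (CV ~0.3); the small CV is what makes "mean strides/day
  recovered within 2%" an identifiable target over 6–7 days, so passing that
  check validates the counting/fusion chain, not robustness to behavioural
  variance.
- **Temperature**: first-order relaxation, exactly integrated across
  don/doff events, between ambient (21 °C) and skin (32 °C) set-points with
  a 30-min time constant, Gaussian measurement noise (0.3 °C default) on the
  recorded values. These constants are physiological
  convention; the source study never describes its loggers' thermal physics.
- **Thermal pairs**: constructed so the TSR ratio equals the target exactly
  in noise-free mode (contralateral relative change 0.05).
- **Activity stream on disk** is a stride-event CSV (the form a vendor
  stride extractor emits): writing a cohort's raw 100 Hz accelerometry as
  text would be gigabytes for no validation benefit. Raw acceleration
  synthesis (gravity + one Gaussian peak per stride, ±6 g clipping, optional
  near-zero-variance non-wear windows) exists and is exercised on short
  windows by the detector tests.

Everything is deterministic: identical (n, seed, config) reproduces
byte-identical stream files and manifest digest; per-participant seeds
derive from a `SeedSequence` of the cohort seed.

Passing the recovery tests therefore shows the *pipeline* is correct on
idealised signals with known truth; it does not show robustness to real
sensor artefacts (drift, device swaps, anatomical pressure distributions,
irregular gait), which the generator deliberately does not model.

## Statistics

- Mann–Whitney U: own implementation returning (U, z, p, r), since r =
  |z|/√n requires the z-score. z is the tie-corrected normal approximation
  with continuity correction (the R `wilcox.test` convention; the SPSS-style
  uncorrected z is available via `continuity=False`). With the correction,
  the approximation stays within 0.03 of exact enumeration for all
  attainable U at group sizes 5–8 (verified exhaustively in the tests).
  Below 5 per group the discreteness of U defeats any continuous
  approximation — at 2 vs 2 the exact two-sided p can only be 1/3, 2/3 or
  1 — so `mann_whitney_exact_p` (full enumeration) should be used there.
- Effect size bands are half-open: [0,0.1) none, [0.1,0.3) small, [0.3,0.5)
  moderate, [0.5,∞) large.
- Chi-square: Pearson without continuity correction, all-zero rows/columns
  dropped before expected counts and df. This reproduces the published
  baseline-table p-values to three decimals — with one exception: the
  published ulcer-site row (p = 0.231) is not reproduced by Pearson,
  likelihood-ratio or Yates variants on the printed counts (all give 0.296);
  it is left as a documented discrepancy of the source tables and not
  asserted.
- Medians/quartiles use numpy's "weibull" method ((n+1)-weighted
  interpolation, SPSS HAVERAGE); the convention is configurable because the
  original software's setting cannot be confirmed from printed values.
- No multiplicity adjustment is applied (none was in the source analyses).

## Numerical and interface conventions

- Timestamps are naive `datetime64[ns]` on the participant's local clock;
  all fusion happens in that single clock and day boundaries are local
  midnight. Files carry ISO-8601 strings without offsets.
- Wear intervals are half-open [on, off) everywhere; shifting all clocks by
  a constant leaves every count unchanged (tested).
- Problem sizes in the checked-in tests and the acceptance script are chosen
  for a single-CPU laptop: a 20-participant cohort (7 days each, 16-step
  walking trials, four platform contacts) generates and runs end-to-end in
  well under a minute.

## Known limitations

- Only walking contributes to the dose: standing and other weight-bearing
  activities are out of scope, although standing is known to add substantial
  load in this population.
- The stride and wear detectors are stand-ins for proprietary algorithms and
  are validated only on synthetic signals.
- One offloading device per participant; mid-study device changes appear
  only as data gaps.
- CPTS model 2 inherits the TSR's unit-dependence and sign behaviour; days
  with negative TSR can produce negative dose contributions, which are
  retained and flagged rather than clipped.
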