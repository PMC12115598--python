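# Methods

## Problem and data model

A collar-mounted IMU on a grazing cow reports, at 10 Hz: tri-axial
specific force in the sensor's body frame (BF), the same samples rotated
into the Earth-fixed world frame (WF) by the on-board fusion quaternion,
tri-axial angular rate, magnetometer readings and the quaternion itself.
Events are labeled segments of one of five behaviors; *active mounting* is
the positive class of a binary detection task (estrus indicator), all
other behaviors are negatives. The database is a folder per behavior, one
CSV per event, with the event's class, cow id and start time encoded in
the filename (`<Behavior>_<cowID>_<YYYY-MM-DD>_<hh-mm-ss>.csv`; the
grammar is a configurable regex because field conventions vary).

## Unit scaling and frame rotation

Raw ADC counts scale linearly: a = raw · Range_a/2^{b_a} · 9.807 m/s² and
ω = raw · Range_ω/2^{b_ω} °/s. Two presets ship: Range_a = 8 g / 14 bit
with a 2000 °/s / 16 bit gyroscope, and 16 g / 16 bit with the same
gyroscope. Whether a "±8 g" sensor maps to Range = 8 or 16 is a
sensor-dialect question that cannot be settled from the formula alone;
the presets are editable and the synthetic encoder/decoder pair is
self-consistent by construction (round trip within half an LSB, which the
tests enforce).

Quaternions are scalar-first, right-handed, Hamilton convention, and are
normalized before use. `quat_to_rotation` is the standard unit-quaternion
to SO(3) map; it is written out explicitly (9 polynomial entries) and
cross-checked in the tests against an independent library implementation
and against the sandwich product q·(0,v)·q\*. Rotation preserves norms to
1e-9 and composing with the conjugate restores the input. The rotated
quantity keeps gravity (specific force): a stationary collar in WF reads
(0, 0, 9.807). Only accelerations exist in both frames; gyro and
magnetometer channels are never rotated.

## Windowing and features

A fixed 7-s window (70 samples) is the minimum event duration in the
field data, so `mode="first"` — one window at the event start — is the
default and yields one sample per labeled event; `mode="tiled"` cuts
⌊duration/7 s⌋ consecutive windows for users who want more samples from
long grazing events. Windows shorter than 7 s are skipped with a warning.

Fourteen features on eight channels give 112 columns named
`<channel>__<feature>`, ordered channel-major so column indices are
stable. Conventions the feature definitions leave open were fixed once:

* population (divisor N) standard deviation and central moments; RMS² =
  mean² + std² then holds exactly;
* Fisher (excess) kurtosis; zero-variance windows define skewness and
  kurtosis as 0;
* zero-crossing rate on the mean-centered signal, with exact zeros
  transparent: crossings are counted between consecutive *nonzero* signs
  and divided by N−1. (Counting a literal sign product < 0 would miss
  every crossing that lands exactly on a zero sample — a sampled 1 Hz
  sine at 10 Hz would score 0 instead of its 13 true crossings.)
* "time between maximum peaks" = mean gap between interior local maxima
  (strictly greater than both neighbors, plateau → first index), no
  prominence threshold, < 2 peaks → 0;
* spectral features from the mean-removed, one-sided, boxcar (untapered)
  periodogram; the DC bin is excluded from the argmax and ties break
  toward the lower frequency, so a flat spectrum reports the lowest
  non-DC bin (fs/N) with density 0.

## Classification and evaluation

With 21 mounts among 415 events, the negatives are undersampled once per
experiment (without replacement, seeded) to the mount count; a per-fold
balancing option exists for leakage-averse use. The classifier is a
linear-kernel SVM behind a per-fold standardizer — features mix m/s², °/s
and dimensionless quantities, so a margin classifier needs the scaling
(toggleable). C is grid-searched over {0.01, 0.1, 1, 10, 100} by
stratified 5-fold mean F1 on a stratified 80 % training split, ties to
the smallest C. Reported performance is the distribution of the four
metrics over stratified 5-fold CV repeated 20 times (100 fits) on the
balanced set; zero-denominator precision/recall/F1 are defined as 0. The
per-behavior confusion table fits one model on the balanced set and
counts false positives among all non-mount windows of the full database.

BF and WF runs inside one experiment share the balancing draw and the
fold seed, so the two 100-value F1 samples are paired on identical
events. All randomness derives from one root seed through named
substreams (balance, grid, folds, SBS, permutation, simulate), making
every stage independently reproducible.

## Feature selection

SBS starts from the full set and greedily removes the feature whose
removal leaves the highest evaluator F1 (ties → first column), recording
the full elimination path; the best subset is the argmax over visited
sizes, and any visited size (e.g. 13) can be read off the trace. The
evaluator defaults to single-repeat stratified 5-fold F1: a full 112 → 1
elimination is ~6,000 subset evaluations, and multiplying that by a 5×20
scheme (~60,000 fits) buys little for subset ranking. The analysis driver
prescreens to the top 28 features by permutation importance (mean F1 drop
over seeded column shuffles) before running SBS to 13 survivors.

## Statistical comparison

Shapiro–Wilk per group and Brown–Forsythe Levene (median-centered — the
robust variant) gate the location test: both groups normal → two-sample
t-test (pooled or Welch per the variance check), otherwise Mann–Whitney
U with midrank ties, exact null enumeration for min(n₁,n₂) ≤ 8 without
ties and a tie- and continuity-corrected normal approximation otherwise.
Effect size is the rank-biserial correlation 1 − 2U/(n₁n₂); the CI of the
location difference is Hodges–Lehmann (order statistics of pairwise
differences) on the nonparametric branch and a normal-approximation mean
CI on the parametric branch. Zero-variance groups skip the assumption
checks and go nonparametric with a warning. The whole decision path is
calibrated: under a simulated null the procedure rejects at 5 % ± 2 %
over 2000 runs (a test enforces this).

## Synthetic data generator

The generator emulates the *structure* the analysis relies on, not cattle
biomechanics. Behavior motion is defined in the world frame — mounting:
4 Hz oscillation bursts of 8 m/s² lasting 1 s at event start and end with
a quiet middle (the climb / hold / dismount envelope); walking: 1.5 Hz,
2 m/s² on x/y; nodding: 1.5 Hz, 3 m/s² on z; grazing: Poisson bursts
(1.5 s⁻¹, 4 m/s², 0.3 s wide, random direction); resting: nothing — plus
gravity, then mapped into the body frame through a uniformly random base
orientation drifting as a 2 °/s random walk, plus BF sensor noise
(0.05–0.3 m/s² sd by class). Stored WF channels are exactly R(q) applied
to the stored BF channels, so the generator and the preprocessing module
agree to machine precision. Gyro channels are band-limited noise scaled
per class (1–60 °/s) and enveloped for mounts; magnetometer channels are
a rotated constant field plus noise, present only for schema
completeness. Event durations are normal (mount 9 ± 1.5 s, walk 14 ± 3,
rest 20 ± 5, nod 8 ± 1, graze 71 ± 15), truncated at 7 s (10 s for
grazing).

What passing tests on this generator show: the pipeline's plumbing,
conventions, pairing and statistics are correct, and the detector behaves
as theory predicts (separable signatures → F1 ≈ 1; mount profile
interpolated into the nodding profile → F1 decays monotonically to ~0.77,
the mount/nodding confusion regime — precision collapses while recall
stays high, because nodding-like negatives trigger the detector). What
they do not show: real-world amplitudes, sensor-fusion error,
magnetometer miscalibration, or label noise — so synthetic F1 levels say
nothing about field F1 levels, only about the machinery. Under the
default (fully separable) profiles both frames saturate, so the BF < WF
gap seen on field data appears here only in degraded-signature settings
where orientation confounding in BF has something to destroy.

## Problem sizes

The analysis drivers and the acceptance script use the field study's
class composition (21/186/83/43/82 events ≈ 3 h of signal), 5×20 CV (100
fits on 42 balanced samples), and SBS on a 28-feature shortlist; the test
suite uses smaller ensembles (8–12 events per class, 3–5 CV repeats)
where the property under test does not need the full size.

## Known limitations

* The 7-s "first window" policy discards most of a long grazing event;
  tiled mode changes the class balance and is deliberately not default.
* Balancing before CV (matching the study's narrative order) lets test
  folds share the undersampling draw; the per-fold option avoids this at
  the cost of differing from the reference procedure.
* Exact Mann–Whitney enumeration is implemented only for the no-tie,
  small-sample case; everything else uses the corrected normal
  approximation (indistinguishable from reference implementations at
  n = 100 in the tests).
* The generator's amplitudes are declared assumptions; none are fitted to
  hardware.
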