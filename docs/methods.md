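# Methods

## Indices

A performance is an ordered sequence of tracked instrument-tip positions
(frame index, x, y) in image coordinates, calibrated to centimetres by an
explicit pixels-per-cm factor. With points p_0 … p_{n−1} and steps
d_i = ‖p_{i+1} − p_i‖₂:

* **Path length** L = Σ d_i (cm). No formula beyond the discrete
  Euclidean arc length is assumed — it is the standard motion-analysis
  definition and the only one computable from tracked points alone.
* **Average movement** A = L / (n − 1) (cm per frame step).
* **Extreme movements** J = #{i : d_i > c}, with threshold c = 1.0 cm by
  default. The comparison is strict: a step of exactly 1.0 cm does not
  count. J is a count of large excursions ("jerk index"), not a
  derivative-based smoothness metric.

A "frame step" is a consecutive *sample* pair. Tracking software drops
frames; by default each surviving pair still counts as one step, and a
`strict_frames` option rejects gapped input instead for users who want
contiguity guaranteed. Indices are computed on the raw track — no
smoothing is applied by default (an optional moving-average filter exists
for exploration but is off, because filtering before the 1.0 cm
threshold changes J's meaning). The indices are invariant to rigid
motions of the image plane and covariant under scaling, which the test
suite checks property-based.

## Normalization and composite score

Each index value v is mapped to a sub-score via the group medians of a
labelled reference cohort (expert: > 200 laparoscopic procedures
performed; novice: < 10):

s = clamp₀¹ ( (v − median_novice) / (median_expert − median_novice) )

so s = 1 at or beyond the expert median on the expert side, s = 0 at or
beyond the novice median, linear between. The map is direction-agnostic:
for tip motion the expert medians are in practice the *smaller* values,
and the signed form handles either orientation without special-casing.
Values exactly at a median receive that median's score, which makes the
map total and continuous. Medians of even-sized groups are the mean of
the two central order statistics. If any index has equal group medians
it cannot discriminate, and threshold construction fails loudly
(`DegenerateIndexError`) rather than producing a divide-by-zero score.

The composite score is the convex combination
ρ = w_L s_L + w_A s_A + w_J s_J with weights on the probability simplex
(validated to sum to 1 within 1e-9). The weights apply to the
*normalized sub-scores*, not the raw indices: that is the only reading
under which ρ is guaranteed to lie in [0, 1]. The default weighting is
(1/2, 1/3, 1/6), the winner of the benchmark weight search.

## Category bands

Two profiles ship:

* `table1` — expert at ρ ≥ 2/3, novice at ρ ≤ 1/3, both inclusive. This
  is the default and the profile under which the weight search counts
  correct identifications.
* `bands` — the proposed operational bands: expert at ρ ≥ 0.65,
  intermediate 0.35–0.65, novice below 0.35. The two published range
  descriptions overlap at exactly 0.35; this package resolves the tie to
  *intermediate*, because that is the only resolution under which both
  profiles assign the same categories to all twelve published validation
  scores (one of which is exactly 0.35). The resolution is encoded as an
  explicit `novice_boundary="exclusive"` field rather than a nudged
  threshold.

## Weight search

Candidates are either the seven benchmark sets — the uniform triple plus
all six permutations of (1/2, 1/3, 1/6), in their published order — or a
regular simplex grid of step 1/m (C(m+2, 2) vectors). Each candidate
scores every cohort record; a record is *correct* when its predicted
band equals its true group, so intermediate predictions are misses for
both groups. The winner is the candidate with the most correct calls,
ties broken by candidate order — determinism without inventing a
secondary criterion. n_total is always the cohort size; the historical
benchmark's out-of-24 denominator on a 29-record cohort reflects
exclusions that were never documented and is not reproduced.

## Validation against assessor ratings

Validation regresses the external assessor's CAT rating on ρ by ordinary
least squares (ρ on x, matching the published plot; R² is symmetric in
simple OLS so the axis choice is immaterial) and reports
R² = 1 − SS_res/SS_tot together with the standard slope p-value. A
constant rating vector is reported as R² = 0 by convention; a constant
predictor is an error. The bundled twelve published validation videos
reproduce R² ≈ 0.844 and the 5/5/2 band split from their printed scores,
computed at run time, never hard-coded as results.

## Synthetic cohorts

The generator emulates the expert/novice contrast with the simplest
process in which L, A and J are independently controllable — a
requirement of the weight-search tests:

* a heading random walk (turn sd 0.25 rad/frame, fixed) with constant
  purposeful step `drift_cm_per_frame`;
* isotropic Gaussian increment noise `tremor_sd_cm`;
* with probability `jerk_rate` per frame, the step is replaced by an
  excursion of exactly `jerk_magnitude_cm` in a random direction
  (required > 1.0 cm so planted jerks are detectable).

Default profiles (chosen once for clear group separation at plausible
laparoscopic tip speeds, and not tuned thereafter): expert
drift 0.25 cm/frame, tremor 0.05 cm, jerk rate 0.005, jerk magnitude
1.5 cm; novice drift 0.6, tremor 0.25, jerk rate 0.08, jerk magnitude
2.0; 300 frames at 30 fps (10 s of motion — enough for medians to
stabilise while keeping simulation cheap). Default cohort sizes mirror
the reference study: 6 experts, 23 novices. All randomness flows from
one explicit seed through `numpy.random.SeedSequence`; identical
(profile, seed) pairs are bit-reproducible.

What the generator does **not** emulate: the trocar fulcrum, the depth
axis, tissue interaction, task structure, camera motion, or tracking
noise of real video. Passing synthetic tests therefore demonstrates the
pipeline's mechanics (index computation, normalization, search,
classification) — not clinical validity, which rests on the bundled
published validation data.

## Experiment sizes and numerical conventions

* The weight-search experiment uses 20 seeds, each with a fresh
  6 + 23 reference cohort and a fresh 12 + 12 test cohort (24
  performances, mirroring the even surgeon/resident split of the
  original twelve validation videos scaled to the benchmark's
  denominator). With the default profiles the (1/2, 1/3, 1/6) weighting
  classifies essentially all test performances correctly; ≥ 90% is the
  documented floor.
* Floating-point tolerances: weight-sum and sub-score identities 1e-9;
  trajectory round-trips 1e-9 cm; rigid-motion invariance 1e-7 (rotation
  round-off).
* Degenerate inputs: trajectories need ≥ 2 points for any index
  (`InsufficientDataError`); single-point files are readable but not
  scorable; empty cohorts, empty candidate lists and out-of-range ρ are
  rejected with `ValueError`s.
* CSV writing uses full `repr` precision so write→read is the identity
  to 1e-9 cm.

## Known limitations

* 2-D image-plane kinematics only; out-of-plane motion is invisible.
* One instrument per trajectory; bimanual aggregation is left to the
  caller.
* The 1.0 cm threshold is frame-rate-naive: at a different native frame
  rate the same physical motion yields different J. The threshold is
  applied at the native sampling rate, the only documented mode.
* The CAT instrument itself (item rubrics, inter-rater reliability) is
  out of scope; its ratings enter only as an external criterion.
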