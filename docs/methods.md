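# Methods

This note documents the models, conventions and numerical choices
behind `vrsearch`, and what the synthetic experiment generator does and
does not emulate.

## Coordinate conventions

Directions are (longitude, latitude) in degrees at every API boundary:
longitude in [−180, 180), positive to the participant's right; latitude
in [−90, 90], positive above the horizon. Internally directions are 3-D
unit vectors (x forward, z up) and head orientations are rotation
matrices. The head is treated as a roll-free rotation of the forward
axis when given as angles; a quaternion column set bypasses that
assumption when an HMD exports full orientation. Gaze (eye-in-space) is
the head rotation applied to the eye-in-head direction. Distances are
orthodromic central angles computed with the arctan2 form (stable near
0° and 180°); velocity divides consecutive distances by the timestamp
difference, one value per inter-sample interval.

## Event detection

Fixations and saccades are classified from the smoothed velocity trace:

* Savitzky–Golay filter, window 7 samples (~58 ms at 120 Hz), order 2,
  applied to velocities (not positions); negative smoothed values are
  clamped to zero. The window/order are exposed in `AnalysisConfig`;
  traces shorter than the window fall back to raw velocities with a
  warning.
* Strict threshold: a sample is a fixation sample iff v < 120 °/s.
  Sample *i* carries the label of the interval *i → i+1*; the final
  sample inherits the last interval's label.
* Segmentation: maximal label runs become candidate events; saccade
  runs shorter than 2 samples dissolve into fixations, fixations
  shorter than 50 ms are absorbed by a flanking saccade, and adjacent
  same-kind runs coalesce, so output alternates kinds. Event spans are
  half-open in sample index and tile the trace exactly (duration
  conservation is asserted in tests).
* Recordings are split at sampling gaps longer than twice the median
  interval; events never span a gap.
* Head movements are not segmented independently — the head channel's
  orthodromic displacement is measured over each gaze-saccade interval,
  matching the joint gaze/head treatment of direction distributions.
  This is an interpretive choice; no separate head-event algorithm is
  claimed.

## Directions, sectors, latitude

Saccade direction is the angle of the onset→offset displacement in the
local tangent plane at onset, with the longitudinal component scaled by
cos(latitude) (a config flag restores raw Δlon for comparison with
equirectangular pipelines). Absolute angles are CCW from rightward;
relative angles subtract the previous saccade's absolute angle, so 0°
is a forward continuation and 180° a return saccade; the first saccade
of a trial has none. Sector binning uses four 90° sectors centered on
the cardinal directions with the lower edge inclusive (left = [135°,
225°)); exhaustiveness and disjointness are brute-force tested on a
0.1° grid. Gaze latitude per trial is the duration-weighted mean
fixation-centroid latitude. Direction proportions pool movements per
participant × condition (not per trial first).

## Search measures

Fixations map to scene objects by angular-disc containment with a
nearest-center tie-break. Accuracy applies the mis-click correction: a
wrong selection counts as correct when the fixation active at the
button press is on the target; timeouts are always incorrect. RT
decomposes additively: initiation = cue offset to first-saccade onset,
scanning = first-saccade onset to the onset of the first post-saccade
target fixation, verification = that onset to the button press.
Defining scanning onset-to-onset (rather than from cue offset) makes
the three phases sum exactly to RT, which is asserted per trial at one
sample interval of slack. Target refixations count maximal runs of
consecutive target fixations minus one. The prior-target-gaze covariate
sums fixation durations on the trial's target over earlier trials of
the same scene, clipped at each trial's response time.

The exclusion cascade labels each trial with at most one cause, in
order: incorrect (kept only for the accuracy model), no saccade
detected, first fixation on target, then a +3 SD cut-off on log
initiation and log verification computed on the surviving trials,
pooled across participants (a config switch selects raw-scale
cut-offs). Mutual exclusivity and completeness are test-asserted.

## Statistical layer

The condition factor is difference-coded (inverted = +0.5, upright =
−0.5) so every reported *b* is the inverted-minus-upright difference.
RT-family measures are log-transformed; gaze latitude stays in degrees.
Families per measure: binomial (accuracy), Poisson (fixation count,
fixated objects, refixations, direction counts), Gamma with log link
(movement amplitudes), Gaussian otherwise. The prior-target-gaze
covariate is z-scored over the modeled trials and omitted from the
direction-count models (those pool over trials). Random-effects
structure: participant intercept, participant condition slope for all
measures except initiation, scanning, verification and fixation
duration (dropped there to avoid singular fits), and a target-object
variance component.

Estimation is delegated to statsmodels: `MixedLM` (REML) for Gaussian
models, the variational Bayesian mixed GLM for binomial/Poisson
families, and GEE (exchangeable, clustered by participant) for the
Gamma family — the environment offers no frequentist GLMM, and these
are the standard substitutes; the module owns only the specification,
coding and result extraction. Crossed participant × target random
effects are approximated by nesting the target component within the
participant grouping, which is harmless at the target-effect magnitudes
the generator produces.

Per-participant memory slopes are OLS slopes of log RT on trial number
(1–10), pooling a participant's scenes within condition. The
slope-difference test is a *paired* JZS Bayes factor across
participants: BF₀₁ integrates the t likelihood over a zero-centered
Cauchy prior of width r = 0.707 on the standardized effect
(g-representation, adaptive quadrature split at g = 2; the test oracle
integrates over effect size with the noncentral-t density instead).
BF₀₁ > 3 is read as evidence for the null, < 0.3 for the alternative.
Within-subject SEs use Cousineau normalization (remove participant
means, add the grand mean) with the Morey factor √(C/(C−1)).

## The synthetic experiment generator

The generator realizes the study design — 20 participants × 10 scenes
(5 upright, 5 inverted, counterbalanced by participant parity and
randomly interleaved) × 10 searches, 15 s timeout, 120 Hz — as an
explicit fixation–saccade chain per trial, then synthesizes the sample
trace from the chain. There is no published generative model for this
behavior; the chain is this package's own construct, built so that the
condition effects of interest are injected exactly where the pipeline
measures them:

* Scanning and verification are lognormal. On the log scale they carry
  the condition effects (defaults δ_scan = 0.41, δ_verif = 0.14,
  inverted − upright), an across-trial slope (−0.02 per trial, applied
  to both phases so the induced log-RT slope is near that value),
  participant and target random intercepts (SD 0.12 / 0.08), a
  participant × condition interaction (SD 0.03), and a negative effect
  of accumulated prior gaze on the target (−0.10 per 2 s) on scanning.
  Initiation is lognormal (median 250 ms) with no condition effect.
* The distractor walk realizes the drawn scanning time exactly: the
  number of intermediate fixations comes from the budget, saccade
  durations follow an amplitude law (20 ms + 2.5 ms/°), and fixation
  durations are gamma-proportioned to fill the remainder (floor 70 ms).
  Object choice is direction-biased (defaults right 0.40, left 0.25,
  up/down 0.175, shifted downward/less rightward for inverted scenes)
  with weights *calibrated to each layout* by a fixed-point adjustment:
  rooms are wider than tall, so uncorrected sector sampling would leak
  vertical probability mass into the horizontal sectors.
* Saccades travel great circles with a raised-cosine velocity profile.
  Ground-truth event boundaries are the 120 °/s threshold crossings of
  that profile (what an ideal detector would report), and the chain
  compensates for the sub-threshold edge times so that the drawn
  initiation/scanning/verification equal the threshold-true phases.
* Verification happens on the target with Poisson-distributed
  refixation excursions (rate 0.30, log-effect +0.37 for inverted).
  Degenerate trial types occur at the configured rates: wrong selection
  with gaze on target 5.7%, incorrect selections/timeouts 7.2% overall
  with a +0.50 log-odds condition effect (yielding ≈94%/91% accuracy),
  saccade-free trials 2.15%, first-fixation-on-target 3.55%.
  Verification outliers can be injected at mean + 5 pooled SD.
* Scenes hold 8 anchors (4–6° radius) and 20 local objects (2–3°),
  separation ≥ sum of radii + 2°, latitudes biased below the horizon
  (−55° to +25°); inversion mirrors latitudes, which is what drives the
  positive gaze-latitude shift in inverted scenes. Fixation jitter is a
  slow AR(1) wander (SD 0.3°, ρ 0.9); the head follows gaze with gain
  0.6 (optionally lagged) and recenters toward gaze during fixations
  (τ = 0.3 s).
* All Gaussian draws (residuals and random effects) are truncated at
  ±2.5 SD. This bounds single-trial variability so that an injected
  outlier is separable from the clean tail by the +3 SD rule; it also
  means the default synthetic world produces far fewer SD-cut-off
  exclusions (~0.3%) than heavy-tailed human data would.
* One seed determines everything; per-participant substreams are
  spawned from a `SeedSequence`, so regeneration is reproducible.

What the generator does **not** emulate: smooth pursuit, blinks and
tracker dropout, vergence/depth, torsion, locomotion through the room,
main-sequence tuning of peak velocity beyond the amplitude-duration
law, and clutter levels of real indoor scenes. Passing tests therefore
demonstrate that the pipeline measures what it claims on well-posed
spherical data with known truth — not that detection parameters are
optimal for any particular eye tracker.

## Problem sizes and determinism in the tests

Unit and property tests run on constructed traces and a shared
6-participant experiment. The end-to-end recovery test uses the full
20-participant design over 20 fixed seeds and checks that the estimated
log-scanning and log-verification condition effects fall within ±0.05
and ±0.03 of the generative values, and that the slope-difference BF₀₁
favors the null, in ≥ 90% of seeds — sampling variability (participant
× condition interactions, target composition, residual noise) makes a
seed near the tolerance boundary expected occasionally, which the 90%
criterion absorbs. Hypothesis-based property tests are derandomized.
`scripts/acceptance.py` runs one full design per invocation (~2 min).

## Known limitations

* Velocity smoothing spreads saccade flanks by roughly a sample, which
  shifts detected fixation onsets late by a few milliseconds; on log
  verification this produces a small (~+0.01) positive bias on the
  condition difference at default noise. It is inherent to
  smooth-then-threshold detection, not corrected for.
* The Bayesian mixed GLM (variational) understates posterior SDs
  somewhat; z statistics for binomial/Poisson models are accordingly
  optimistic. Gaussian (MixedLM) results are unaffected.
* `exclusion_cascade` assumes the +3 SD step operates on at least two
  valid trials per measure; degenerate inputs skip the step silently.
* The gamma-family GEE estimates marginal (population-averaged) rather
  than conditional effects; for the amplitude measures analyzed here
  the distinction is minor.
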