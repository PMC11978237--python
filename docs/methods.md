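# Methods

This note documents the models, conventions and numerical choices behind
`pelvikin`, and what the synthetic-data results do and do not say about real
recordings.

## Conventions

All 3-vectors use one lab frame: axis 0 vertical (up-positive), axis 1
mediolateral (subject's-left-positive), axis 2 anteroposterior
(anterior-positive), matching the smartphone channel semantics (X, Y, Z) so
both branches share one frame.  Pelvic orientation is an intrinsic Euler
sequence transverse → frontal → sagittal about the vertical, anteroposterior
and mediolateral axes.  Signs are fixed for right-leg stance: positive =
forward contralateral (left) rotation, contralateral pelvic drop, anterior
tilt.  Angles are degrees everywhere outside the rotation algebra.  The
simulator and both decoders share the same matrices, which is why noise-free
round trips recover angles to ~1e-9 degree: the decomposition is the exact
inverse of the construction, not an approximation.

All filtering is zero-phase (forward-backward Butterworth via second-order
sections).  Outcomes are defined at time-aligned events, so phase lag would
bias peak timing; the price is that each filter's magnitude response is
squared relative to its design order.

## The simulator as study conditions

Each recording is 5 s quiet standing, five repetitions of a raised-cosine
descent/ascent (4 s each, matching a 60 bpm metronome protocol) separated by
2 s rests, and 5 s trailing quiet standing; everything is sampled at a
500 Hz master rate and decimated exactly to 250 Hz (markers) and 100 Hz
(phone), so no interpolation separates the branches.

Per-task conditions (defaults, chosen once):

| quantity | SLS | SD15 | SD20 | spread |
|---|---|---|---|---|
| transverse peak (deg) | −6.4 | −1.2 | −0.2 | between-subject sd 3.5, task residual 1.0 |
| frontal peak (deg) | −0.9 | +3.4 | +4.5 | same |
| sagittal peak (deg) | +0.9 | −3.2 | −1.3 | same |
| ML sway accel SD (m/s²) | 0.22 | 0.26 | 0.29 | lognormal: subject sd 0.25, task 0.08 (log) |
| squat depth (m) | 0.15 | 0.18 | 0.20 | sd 0.03 |

Angle centers and sway levels sit at the scale reported for healthy adults
performing these tasks; the per-participant random effect is shared across
tasks, making between-task contrasts paired, as in a within-subject design.
Squat depth in metres is an assumption (no published depth exists for this
protocol); it only sets signal scale and is irrelevant to angle-recovery
tests.  Angle channels are the per-plane amplitude times the same normalised
profile as the vertical displacement.  Mediolateral sway is band-limited
noise (0.8–3 Hz) windowed by the activity profile and scaled so that the
within-repetition acceleration SD equals the target.

Sensor imperfections: marker noise 0.5 mm isotropic; phone accelerometer
noise 0.05 m/s²; phone orientation noise 0.3°; constant mounting offset
(45, 2, 3)° in (transverse, frontal, sagittal) — the azimuth offset stands
for the arbitrary compass zero; heading drift 0.02 °/s on the azimuth only
(a magnetometer-fusion artifact, so it does not touch the accelerometer);
gravity expressed in the device frame by default, with
`include_gravity=False` producing "linear acceleration" semantics.

Two features of real data are *not* modelled: tempo variability (every true
repetition lasts exactly 4.0 s) and soft-tissue / attachment artifact.  Both
matter for interpretation — see Limitations.

## Branch processing

**MOCAP.**  The pelvis frame per sample: mediolateral axis from LASIS−RASIS;
anteroposterior axis from mid-PSIS toward mid-ASIS, orthogonalised;
vertical completes the triad.  Orientation is decomposed against the
first-sample (quiet standing) frame, so a participant standing slightly
rotated reads zero; residual offsets cancel in the baseline subtraction.
Displacement is the 4-marker centroid projected on the vertical and
mediolateral axes, 10 Hz low-passed **before** double differentiation —
broadband 0.5 mm marker noise would otherwise contribute ~10 m/s² of noise
to the second derivative, two orders above the ~0.25 m/s² sway signal.
Central differences (second-order one-sided at edges) are exact for the
polynomial test cases and robust at the boundaries.

**Phone.**  Roll → sagittal, pitch → frontal, azimuth → transverse (identity
signs for the reference sacrum mounting: landscape, screen outward, camera
to the left).  Azimuth is unwrapped over the ±180° seam and re-referenced to
its own initial quiet-standing median, so the compass zero never enters the
outcomes.  Vertical displacement is high-pass(0.1 Hz, 2nd order) →
trapezoidal integral → high-pass → integral → high-pass; "a high-pass at
each step" is read as three filter applications (a switch allows two).  The
zero DC response removes gravity exactly; the waveform is used *only* for
event identification.

**Gravity tilt-coupling.**  With gravity-inclusive channels the X channel
carries g·cos(tilt): a pelvic tilt of θ adds a pseudo-acceleration
−g·(1−cos θ) ≈ −g·θ²/2 synchronised with the squat.  A slow 4 s squat has a
true vertical-acceleration fundamental of only ~0.2 m/s², so at tilts ≳9°
the coupling is comparable and can nearly cancel the displacement
fundamental, making the phone waveform unusable for segmentation — the same
mechanism that forces manual event identification on real smartphone data.
The pipeline handles such recordings permissively (flags, missing-outcome
rows); the gravity-free semantics avoid the effect entirely.  Outcomes are
insensitive to gravity at small tilts (≲3°: <1% on duration and
variability), but the insensitivity degrades quadratically with tilt.

## Segmentation

A stability search over the pre-task 5 s finds the 0.5 s window with minimal
summed rolling variance of the three angle channels (error above a 2 deg²
ceiling).  Repetitions are spans where the vertical displacement deviates
more than 10 mm below the reference, extended to the crossings of the 5 mm
exit threshold (hysteresis), with crossings refined by linear interpolation
— duration is an outcome, so sub-sample precision matters.  Spans shorter
than 1 s or shallower than 30 mm are discarded; a bottom flat to within
2 mm for ≥0.2 s reports its temporal midpoint as the peak (the plateau
rule).  Detected start/end are strictly inside the true movement, so
detected durations are systematically shorter than true durations — the
direction of duration bias any displacement threshold produces.

The reference level is, by default, a rolling 80th-percentile of the
displacement itself (8 s window, computed on a 20 Hz decimated copy).  The
drift high-pass removes the DC of the squat-pulse train, which elevates the
phone waveform's between-rep rest level by several centimetres; against the
global quiet-standing baseline the thresholds would fire ~0.7 s inside the
movement.  The rolling percentile is the automated analogue of reading
events against the local pre-repetition rest level — what a visual analyst
does implicitly — and is the identity for undistorted channels, so the
marker branch is unaffected.  Spans that begin before the baseline or end
within 2 s of the recording edge are discarded as filter-transient
artifacts.  Even so, phone-vs-MOCAP event agreement on clean simulations is
~0.15–0.35 s per event, not arbitrarily small: a 5 mm threshold on a
drift-filtered waveform carries an intrinsic crossing wobble of a few
millimetres, which at squat descent speeds is ~0.1 s.

## Outcomes

Orientation at peak squat: mean per plane over all samples within ±100 ms of
the peak time, minus the branch's own baseline values (each branch subtracts
its own baseline, so constant mounting offsets cancel; this is asserted in
both directions in the tests).  Duration: end − start from the interpolated
crossings.  Variability: sample SD (ddof = 1) of the filtered mediolateral
acceleration within the repetition.  Per-task summaries are componentwise
medians (mean of the middle two for even counts).

## Statistics

Bias: Shapiro-Wilk on the paired differences at α = 0.05 gates paired *t*
versus Wilcoxon signed-rank (zero differences dropped); all-equal
differences are degenerate (bias reported, no p).  Differences are oriented
MOCAP − phone throughout.

ICC (average measures, k = 2 systems), from the two-way mean squares:
consistency `(MSR−MSE)/MSR` with exact F bounds on MSR/MSE; absolute
agreement `(MSR−MSE)/(MSR+(MSC−MSE)/n)` with the Satterthwaite-df F
approximation on the single-measures form transformed by Spearman-Brown.
Both forms and their CIs are verified against a brute-force mean-squares
oracle and an independent implementation, and the CI shows 93–97% coverage
over 500 simulated cohorts at a known population ICC.  The bias gate picks
the model: significant bias → consistency (offsets are real but systematic),
otherwise absolute agreement; the chosen model is printed per row so the
gate is auditable, and it can be forced.  Categories come from the lower CI
bound: poor < 0.5 ≤ moderate < 0.75 ≤ good ≤ 0.9 < excellent.

Bland-Altman: bias = mean difference, limits = bias ± 1.96 × sample SD, plus
the slope of difference on pair mean (proportional bias).

Between-task: Shapiro-Wilk per task column gates repeated-measures ANOVA
(Greenhouse-Geisser-corrected df when Mauchly rejects at 0.05) versus
Friedman; a significant overall test triggers the three pairwise gated
comparisons with Bonferroni m = 3.  Between-group (genders, smartphone
data): gated independent *t* versus rank-sum.

Drift QC: transverse-channel medians over the first and last quiet windows;
|difference| > 5° excludes the recording from transverse-plane rows only,
with the exclusion count reported.

## Numerical choices and degenerate inputs

Filter transients: the 0.1 Hz high-pass settles over seconds; amplitude
measurements in tests use central windows, and the segmentation edge guard
(2 s) removes boundary artifacts.  `MSE == 0` (identical raters up to a
constant) yields ICC CI (1, 1) exactly; zero between-participant variance
yields an explicit degenerate ICC.  Empty repetition lists, unstable
baselines, collinear markers, corrupt azimuth, too-short signals and
mismatched repetition counts each raise a named error (strict mode) or flag
the row (permissive mode).  Peak windows truncated by the recording edge
raise in strict mode and are flagged otherwise.

## Problem sizes

The default cohort is 52 participants × 3 tasks × 2 branches.  Cohort-level
test properties use 8–12 participants; the CI-calibration check uses 500
cohorts of 15; the noise-response check averages 10 paired seeds over a
3-point noise grid (×0.5, ×2, ×5 of the default sensor noise, with common
random numbers so the sweep is paired).

## Limitations

* **Duration validity is not informative here.**  Real participants deviate
  from the metronome, giving large true between-participant duration
  variance; the simulator fixes every repetition at 4.0 s, so measured
  duration differences are all threshold/distortion artifact and the
  duration ICC under default conditions is "poor" by construction.  The
  duration *bias* (phone shorter than MOCAP) is meaningful and reproduces
  the expected direction.
* Angle excursions are exactly proportional to the displacement profile;
  real squats decouple them partially, which would *weaken* the gravity
  tilt-coupling cancellation described above.
* No soft-tissue artifact, marker occlusion, attachment slip or balance
  failures; agreement numbers from clean simulations are upper bounds, not
  predictions, for real recordings.
* Passing round-trip tests shows the two branches and the simulator are
  mutually consistent and the statistics are correct — it cannot validate a
  physical phone against a physical laboratory.
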