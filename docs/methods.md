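# Methods note

This note records the quantitative definitions, default parameters, and
numerical choices behind `bradykinet`, and states what the bundled synthetic
experiments do and do not establish.

## 1. Input model

A recording is a stream of 21-keypoint hand landmarks (wrist = 0, fingertip
indices 4/8/12/16/20) at a fixed frame rate (default 30 fps), optionally
preceded by detector post-processing:

- **Box selection**: per frame and side, the highest-probability detection
  wins; frames without a detection are gaps.
- **Temporal correction**: when a detection's probability does not exceed
  the previous frame's, the previous box (and its probability) is carried
  forward. This suppresses detector flicker at the cost of one-frame lag on
  genuine fast motion; the rule is idempotent.
- **Side assignment**: under the default mirror convention a box centered in
  the left image half is the subject's right hand (ties go to "right").

Gaps of fewer than 5 frames in landmark streams are linearly interpolated;
longer gaps are an error rather than silently bridged.

## 2. Kinematic curves and normalization

| Task | Signal | Units |
| --- | --- | --- |
| finger_tapping | ‖thumb tip − index tip‖ | pixels → normalized |
| hand_grasp | ‖wrist − mean(4 non-thumb fingertips)‖ | pixels → normalized |
| pronation_supination | unwrapped polar angle of (pinky tip − thumb tip), referenced to the calibration circular mean | degrees (never normalized) |

The first `calibration_frames` (default `(0, 15)`) hold the maximal
aperture/reference pose. Distance curves are divided by the
calibration-segment maximum; if that maximum is degenerate (< 10⁻⁶ of the
global maximum) the global maximum is the fallback reference. Rotation is
referenced with a *circular* mean so a calibration pose near the ±180° wrap
does not corrupt the zero point, and the unwrapped curve is sign-oriented so
the dominant excursion is positive (the raw sign depends on hand and
mirroring).

## 3. Signal processing chain

All defaults live in `SignalConfig` / `ExtractionConfig`.

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| `filter_order` | 4 | — | standard biomechanics choice; steep enough to separate movement from jitter at 30 fps |
| `cutoff_rule` | `max_magnitude` | — | one-fourth rule reference M = largest spectral peak; `highest_frequency_peak` is the alternative literal reading |
| `cutoff_margin` | 2.0 | — | see below |
| `threshold_mode` | `prominence` | — | topographic prominence rejects ripples riding on large movements; absolute height available |
| thresholds | 0.1 / 0.25 / 0.25 | normalized, normalized, fraction of calibration rotation range | amplitude correction per task |
| `max_cutoff_fraction_of_nyquist` | 0.95 | — | keeps the filter design well-posed |
| spectrum fallback cutoff | fps/6 | Hz | used when the spectrum has no peaks (≈5 Hz at 30 fps, above any plausible tapping cadence) |

**Cutoff selection (one-fourth rule).** Local maxima of the one-sided
magnitude spectrum of the mean-removed analyzed segment are the candidate
peaks; the selected frequency is the highest peak whose magnitude is at
least M/4, M being the largest peak magnitude. The rule is scale-invariant
and is verified against an independent oracle in the tests.

**Why `cutoff_margin = 2.0`.** A Butterworth filter has |H(f_c)|² = ½ at its
corner. Zero-phase (forward–backward) application squares the magnitude
response, so placing the corner *at* the selected frequency would attenuate
the signal's own dominant component to one half. The corner is therefore
placed at 2 × the selected frequency (capped at 0.95 × Nyquist), where a
4th-order zero-phase response passes the selected component with < 1 %
amplitude loss while still rejecting jitter an octave higher.

**Why Gustafsson edge handling.** `filtfilt` with default padding leaves
edge transients that bias the first and last movement peaks by a few parts
per thousand — irrelevant for amplitude means but fatal for `fatigue`, which
is a small difference of envelope extremes. Gustafsson's method (initial
conditions chosen so forward and backward passes agree) removes this bias;
with it, the closed-form decrement is recovered within 1.5 % across the test
grid, versus > 5 % error at the smallest decrement with padding.

**Peaks and envelope.** Local maxima use the leftmost sample of flat
plateaus and never include endpoints. The upper envelope linearly
interpolates between surviving peaks and extends the first/last peak value
constantly to the curve ends.

## 4. Features

- `amplitude_mean`, `amplitude_std`: mean and **population** SD (ddof = 0)
  of peak values — the features describe the observed movement train rather
  than estimate a population parameter, and a single peak then has SD 0.
- `speed`: n_peaks / duration of the analyzed segment. The calibration
  segment is excised first; `duration_s` is the analyzed length.
- `fatigue`: max − min of the upper envelope. This literal definition is
  non-negative by construction; `fatigue_signed` (mean of the envelope's
  first third minus its last third) is reported alongside because decrement
  direction is clinically meaningful and amplitude can also *grow*.
- Undefined features (no surviving peaks) propagate as NaN and drop the
  subject from that feature's classifier. Imputing 0 would mimic extreme
  bradykinesia and is deliberately not done.

At 30 fps a noise-free constant-amplitude train still shows
`amplitude_std` ≈ 1.4 × 10⁻³: peak instants fall between frames, giving
peak-height jitter of order (f/fps)². This sampling floor, ≈0.2 % of the
mean, is the resolution limit of the feature at webcam frame rates.

## 5. Evaluation

Each classifier input is the (left hand, right hand) value pair of one
feature for one task/condition; PD is the positive class. Models: logistic
regression (sklearn defaults), Gaussian naive Bayes, random forest
(100 trees, seeded). Stratified 4-fold CV with per-fold ROC curves
interpolated onto a fixed 101-point FPR grid and averaged vertically; the
reported AUC is the trapezoidal area under the mean curve and
sensitivity/specificity are read at its Youden point. Note the grid ceiling:
the mean curve is pinned to (0, 0), so perfect fold-wise separation yields
0.995, not 1.0. External validation refits nothing and scores accuracy at
the 0.5 probability threshold. Group contrasts are two-sided Mann–Whitney U
tests of PD most-affected-side values against HS dominant-side values, with
medians/IQRs reported for all four side groups.

## 6. Synthetic motion model

The simulator drives a fixed 21-point hand skeleton with a per-frame
activation built from raised-cosine pulses, sin²(πft): exactly one aperture
peak per movement cycle and a single spectral line at the cadence, so
closed-form expectations survive filtering exactly. Impairment knobs:
cadence (Hz), base amplitude (fraction of maximum aperture/rotation), linear
decrement (fraction of A₀ lost per second), per-cycle hesitation probability
(phase freeze of 0.4 s), Gaussian pixel jitter, and a per-subject asymmetry
factor multiplying cadence and amplitude on the worse side. Group presets:
HS cadence 2.8 ± 0.35 Hz, amplitude 0.82 ± 0.07, decrement 0.005 ± 0.004,
asymmetry 0.97 ± 0.02; PD cadence 1.9 ± 0.35 Hz, amplitude 0.60 ± 0.10,
decrement 0.030 ± 0.012, hesitation 0.08, asymmetry 0.75 ± 0.08. The default
cohort is 22 PD + 20 HS with a 6 + 6 held-out validation cohort; the
bilateral condition degrades the worse side by a further 0.85 factor. All
draws flow from `SeedSequence([cohort_seed, subject_seed])`, so every
artifact is reproducible from one integer.

**What the passing experiments show** — and only this: the chain recovers
known kinematic parameters from its own motion model (speed within
1/duration, amplitude within 2 %, decrement-fatigue within 5 %, noise-free);
the evaluation stack is unbiased under an exchangeable null (mean AUC ≈ 0.5,
uniform p-values across 100 seeds); and a strongly separated synthetic
phenotype is recovered with CV-AUC > 0.95. They do **not** validate clinical
accuracy on real patients, the realism of the motion model, or pose-estimator
robustness (occlusion, lighting, landmark dropout beyond short gaps).

## 7. Problem sizes and runtime

Chosen as package defaults to keep everything desk-scale: recordings of
12 s at 30 fps (360 frames), cohorts of 42 + 12 subjects, 100-seed null
sweeps. The full test suite runs in ≈3 minutes on one CPU (the 100-seed null
calibration dominates at ≈2 minutes); `scripts/acceptance.py` takes about
the same.

## 8. Limitations

- 2-D image-plane kinematics only; out-of-plane rotation components are
  projected away, and pronation–supination reads the *projected* angle.
- The one-fourth rule assumes the movement fundamental dominates the
  spectrum; heavily hesitant movement can push the cutoff fallback.
- Fatigue as max − min of the envelope conflates decrement with any
  transient large tap; the signed variant mitigates but does not resolve
  this.
- Two-value classifier inputs discard within-recording dynamics; the
  features are summaries, not time-series models.
- Synthetic validation only — see §6.
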