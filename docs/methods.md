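# Methods

## Recording model

A trial is a T × 229 matrix sampled at 60 frames/second. The 229
channels are fixed and ordered canonically: extended-finger count (1),
palm position (3) and direction (3), wrist extension angle (1), wrist
position (3), forearm direction (3), fingertip speed (5), fingertip
position (15) and direction (15), then distal-end position, center
position and direction for each of the 20 finger bones (3 × 60).
Within a category the order is finger thumb → little, bone tip → palm,
axis x, y, z. Coordinates are right-handed with y vertical (up from the
sensor); positions are in mm, directions are unit vectors, wrist
extension is in degrees, fingertip speed is mm/frame, and the
extended-finger count is an integer-valued real. The units only matter
to the simulator — the downstream pipeline is covariant to per-channel
scaling.

Anatomically the thumb has no middle phalanx; its tracked segments are
distal phalanx, proximal phalanx, metacarpus and carpal. Descriptors
store these anatomical names, and a display alias maps them onto the
uniform distal/middle/proximal/metacarpus grid used when reporting
per-bone results (thumb "middle phalanx" ⇒ anatomical proximal phalanx,
"proximal phalanx" ⇒ metacarpus, "metacarpus" ⇒ carpal). The alias is
applied on input to the per-bone API so a request for the thumb's
"middle phalanx" selects the anatomically correct channels.

Trials have variable length — slower hands need more frames for their
20 grip-release cycles — and are never resampled; T ≥ 64 is required
for featurization. Recordings round-trip exactly through CSV
(17-significant-digit values + JSON metadata sidecar) and JSON-Lines.

## Spectral featurization

Per channel waveform:

1. **Segmentation.** 15 segments of 64 frames with start offsets
   `offsets[i] = round(i · (T − 64) / 14)`, i = 0..14 (round =
   floor(x + 0.5), so the rule is deterministic and platform-independent).
   The first segment starts at frame 0, the last ends at frame T; for
   T < 960 consecutive segments overlap, and at T = 64 all 15 coincide.
2. **Detrending.** The least-squares affine fit a + b·t is subtracted
   per segment. Any affine-in-time contamination of a channel (offsets,
   slow drift) is therefore annihilated exactly, and the DC bin of the
   subsequent transform carries only the window-weighted residual mean.
3. **Windowing.** Symmetric 64-point Hanning window
   w[t] = 0.5 (1 − cos(2πt/63)), applied after detrending.
4. **Transform.** Unnormalized 64-point FFT; the magnitudes of bins
   0–15 are exported. Normalization is irrelevant downstream because
   features are standardized before classification. Two dialect
   switches exist (`FeatureOptions`): export bins 1–16 instead of 0–15,
   and export squared magnitudes; both default off.

This yields 229 × 15 × 16 = 54,960 features per trial regardless of T,
with a bijective (channel, segment, bin) ↔ position index (channel-major,
then segment, then bin).

Sample vectors concatenate trial features in fixed (side: right, left) ×
(trial: 1, 2) order. Concatenation (rather than averaging) was chosen
because it preserves per-trial information; averaging is a sensitivity
variant that can be built from the same `FeatureVector`s. The CM/control
design classifies participants (4 trials, 219,840 features); the
CM/non-CM design classifies hands (2 trials, 109,920 features), because
CTS can be unilateral and the pooled non-CM comparison is naturally
hand-level. In the CM/non-CM "total" variant both hands enter as
separate samples; participant-grouped folds prevent a person's two
hands from straddling a train/test split.

## Classifier

A support-vector machine on standardized features. With n ≈ 10²
samples and p ≈ 10⁵ features a linear kernel is the appropriate
default (RBF is available); regularization C = 1. Probability scores
come from Platt sigmoid calibration fitted on cross-fitted decision
values (`CalibratedClassifierCV(..., ensemble=False)`, cv = min(5,
smallest class count)); the calibrated score is a monotone transform of
one SVM's decision function, so rankings — and hence ROC/AUC — match
the uncalibrated model. Scaling statistics are learned from the
training split only. Classes are not reweighted by default (cohorts are
near-balanced); `class_weight="balanced"` is available.

## Evaluation

Cross-validation is 10-fold, **grouped by participant** and label-
stratified at the participant level: within each class, participants
are shuffled (seeded) and dealt round-robin to folds, so fold sizes
differ by at most one participant per class and no participant's
samples ever appear on both sides of a train/test boundary. Per-sample
(ungrouped) validation would leak within-person correlation and inflate
the AUC.

The ROC curve sweeps all distinct out-of-fold scores (prediction:
score ≥ threshold), giving nondecreasing FPR/TPR from (0,0) to (1,1).
AUC is the trapezoidal area, which on this full sweep equals the
normalized Mann–Whitney statistic with ties counting ½. The optimal
cutoff minimizes the Euclidean distance √(FPR² + (1−TPR)²) to the
upper-left corner; exact ties (within 1e-12) are broken toward higher
sensitivity, the screening-appropriate direction. Sensitivity and
specificity are reported in percent (one decimal in serialized
reports), AUC to two decimals. Degenerate inputs: single-class label
vectors raise an undefined-ROC error; constant scores collapse the
curve to the chance diagonal.

The per-bone ablation reruns the identical CM/control cross-validation
(same folds, same seed) restricted to one bone's 9 channels
(9 × 15 × 16 = 2,160 features per trial block); restricting to the full
feature set reproduces the headline run exactly, which is tested.

## Synthetic cohorts

The simulator emulates the measurement protocol — 20 grip-release
cycles of a pronated hand tracked from below at 60 fps — with a
five-chain planar forward-kinematic hand. Each finger has a fixed
extended direction fanned in the horizontal plane; flexion rotates
successive bones within the finger's sagittal plane, so bone lengths
are conserved exactly and all direction channels are unit vectors.
Flexion follows a raised-cosine open/close profile per cycle (smooth
and band-limited); per-cycle periods are drawn with coefficient of
variation `jitter`. Sensor noise is additive Gaussian on position
channels only; fingertip speed is computed from the noisy fingertip
track, so the speed channel is exactly consistent with the positions.
Recording length is n_cycles / rate seconds — slow hands produce longer
recordings, as observed clinically.

Group profiles (defaults; synthetic stand-ins, not clinical estimates):

| group   | rate (Hz) | rate SD | amplitude | jitter | thumb factor |
|---------|-----------|---------|-----------|--------|--------------|
| CM      | 1.5       | 0.2     | 0.7       | 0.20   | 1.0          |
| control | 2.3       | 0.2     | 1.0       | 0.05   | 1.0          |
| CTS     | 2.3       | 0.2     | 1.0       | 0.05   | 0.6          |

These mirror the clinical picture — myelopathy hand is slow, reduced
and irregular; CTS spares rhythm but impairs the thumb — with a
separation large enough that the pipeline should recover it nearly
perfectly, giving an unambiguous ground truth. Sensor noise defaults to
0.5 mm. Per participant, hand size is scaled uniformly within ±5% and a
personal cycle rate is drawn from the group profile; each participant
contributes 2 sides × 2 trials. CTS impairment applies to one
randomly designated affected side. All randomness flows from a single
seed through spawned generators, so cohorts are bit-reproducible.

What the simulator does **not** emulate: occlusion artifacts of
camera-based tracking (fingers hidden behind the palm), tremor or
fatigue trends within a trial, inter-finger timing asynchrony, or any
empirically calibrated effect sizes. Passing end-to-end tests therefore
demonstrates that the pipeline recovers class structure it is pointed
at — not that real patients are classifiable at any particular
accuracy. Published clinical headline values (e.g. CM/control
sensitivity ≈ 74%, specificity ≈ 90%, AUC ≈ 0.82 on real cohorts) are
context for scale, not targets this package can or does reproduce.

## Problem sizes and numerical choices

End-to-end checks use cohorts of 5–30 participants per group
(signal-recovery: 30/group over 5 seeds; null-calibration: 50/group with
a 200-draw label permutation; ablation-localization: 15/group), sizes
chosen to match the scale of the clinical cohorts while keeping the
suite fast. The acceptance script uses 20 participants per group.
Detrending uses `scipy.signal.detrend`; FFTs use `numpy.fft`; the SVM,
scaler, calibration and ROC sweep use scikit-learn. Feature arrays are
float64 throughout. The segmentation rounding rule, cutoff tie-break
and fold-assignment procedure are specified above precisely so that
results are reproducible across platforms given a seed.

## Known limitations

- Sample vectors are dense float64; cohorts of thousands of
  participants would warrant float32 or chunked standardization.
- The closest-to-corner cutoff is one convention among several
  (Youden's J is a natural alternative and is not implemented).
- No confidence intervals on AUC and no external-validation harness are
  provided.
- The simulator's planar finger chains cannot represent abduction/
  adduction or out-of-plane thumb opposition.
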