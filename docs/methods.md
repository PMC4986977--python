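# Methods

## The task being emulated

Each trial of the modified Posner task shows a 250 ms endogenous cue at one
of four horizontal letter locations (1–2 left of fixation, 3–4 right;
horizontal spacing 0.88°, vertical 2.05°), then after a uniform 450–550 ms
delay flashes a letter at *every* location twice for 33 ms each within a
200 ms window (≥ 17 ms between a letter's two flashes). A session is two
blocks of 300 trials with each location cued exactly 150 times in random
order. EEG is sampled at 512 Hz from three posterior pairs (PO7/PO8, O1/O2,
PO3/PO4) plus HEOG, VEOG and two mastoids.

## Synthetic signal model

The generator writes, per trial, four lateralized components onto the
posterior pairs, each a boxcar with 20 ms half-cosine on/off ramps:

| component | lock | support (ms) | default contra−ipsi amplitude (inner / outer) |
|---|---|---|---|
| early negativity (N2pc-like) | cue | 170–270 | −1.0 / −1.5 μV |
| sustained negativity (SPCN-like) | cue | 300–840 | −2.0 / −3.0 μV |
| early positivity (P1-like) | each flash of the cued letter | 0–100 | +1.5 / +2.25 μV |
| late positivity | each flash of the cued letter | 410–530 | +1.0 / +1.5 μV |

An amplitude *a* (contralateral minus ipsilateral) is split ±a/2 across the
two electrodes of each pair, so the left-minus-right difference equals
−h·a where h = +1 for left-hemifield locations and −1 for right. Attending
left therefore yields a **positive** L−R difference for the negativities,
mirrored on the right — the sign convention the features rely on.

Choices made once, as the study conditions:

- **Eccentricity grading ×1.5 for outer locations.** Outer letters are
  farther from the midline; their lateralized components are scaled by 1.5.
  This is what lets the classifier separate locations *within* a hemifield
  (inner vs outer differ in magnitude; hemifields differ in sign).
- **Background noise: pink (1/f amplitude) Gaussian noise, sd 10 μV** per
  EEG/EOG channel — a realistic scalp-EEG scale, and a spectrum that
  actually stresses the 0.1 Hz high-pass. Mastoids carry 0.5 μV noise so
  re-referencing is exercised without dominating.
- **Between-subject variability: lognormal amplitude scale, σ = 0.3.**
  Subject-level effect sizes in ERP work commonly vary by tens of percent;
  this is what makes leave-one-*subject*-out a real generalization test.
- **Artifacts: Poisson blinks at 0.05/trial (150 μV, 250 ms VEOG bump with
  10% posterior leakage) and saccades at 0.03/trial (60 μV, 400 ms HEOG
  step)**, yielding ~4% epoch rejection — an ordinary rate for a
  well-behaved cohort, while the exclusion rule (≥ 30%) stays testable
  with elevated rates.
- All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning (schedule / synthesis / artifacts
  per subject), so every product is bit-reproducible.

What the generator does **not** emulate: volume-conducted correlations
between channels, non-stationary alpha rhythms, component latency jitter
across trials or subjects, behavioral errors, or any single-trial coupling
between attention and ERP amplitude. Passing tests therefore show the
pipeline recovers the effects it is pointed at under realistic noise — not
that real data would yield any particular accuracy. The original study's
real-data values (57% four-class accuracy, 79% binary, etc.) need the
original recordings and are treated as qualitative reference points only.

## Preprocessing conventions

- Zero-phase forward-backward 4th-order Butterworth band-passes, −3 dB at
  the stated cut-offs: 0.1–30 Hz (EEG, mastoids), 0.1–10 Hz (EOG). Applied
  after mastoid re-referencing ((M1+M2)/2 subtracted from EEG only; EOG
  channels are bipolar derivations and untouched).
- Epochs are half-open [−200, 800) ms windows, t = 0 at the event sample;
  the baseline [−200, 0) ms mean is subtracted per channel. Events whose
  window crosses a recording edge are dropped (never zero-padded).
- "Deflection within a time window" is peak-to-peak (max − min) over a
  sliding window of the stated length, stepped one sample at a time —
  the standard ERP-practice reading. Comparisons are strict (>):
  blink = VEOG p-p > 50 μV in 150 ms; eye movement = HEOG p-p > 35 μV in
  300 ms; the ±100 μV absolute rule applies to EEG channels only (post
  re-reference, post filter). The first matching reason (blink → eye
  movement → absolute limit) is recorded per epoch.
- Subject exclusion is inclusive at the 30% rejection rate (a subject at
  exactly 30% is excluded), matching the study's participant accounting.

## Features

12 per (subject × location): {cue, target} lock × {PO7−PO8, O1−O2,
PO3−PO4} × {early, late} window, with the windows listed above. Window
endpoints use the same half-open convention as epochs. Target-locked
averages pool the cued letter's two flashes (hence the very early P1-like
feature window starting at 0 ms). Features come from *subject-level*
averages — 60 rows of dimension 12 for 15 subjects — since classification
generalizes across subjects. For the binary task, each (cue location ×
letter location) pairing contributes one row of the 6 target-locked
features, labeled attended iff cue = letter (1:3 imbalance by design).

## Classifier

- Tree: Ward linkage on Euclidean distances between class centroids of
  standardized training features. Deterministic; exact ties merge the
  lowest class indices first. With the generator's geometry the recovered
  topology is [1,2] vs [3,4] at the root, then 1 vs 2 and 3 vs 4.
- Node SVMs: "quadratic SVM" is read as an inhomogeneous degree-2
  polynomial kernel — (γ·x·x′ + 1)², γ = 1/n_features — with C = 1.
  An RBF kernel is available via `DSVMConfig`. Standardization is fitted
  on the training fold only (no leakage).
- The tree is rebuilt inside every LOSO fold by default (leakage-safe);
  `EvalConfig(rebuild_tree_per_fold=False, fixed_tree=...)` freezes it.
- Binary task: same kernel, inverse-frequency class weights for the 1:3
  imbalance (subsampling would be the alternative; weights keep all data).

## Evaluation and significance

- LOSO: one fold per subject; 15 subjects → 15 folds → 60 four-class
  predictions. Decoding accuracy equals the mean of the confusion-matrix
  diagonal when every (subject × location) contributes one prediction.
  Because the study's own accounting treats each fold as "correct or
  incorrect", a per-subject majority-correct tally is reported alongside;
  neither accounting is privileged.
- Percent displays truncate toward zero (10/15 → 66%); full precision is
  kept internally.
- D = (1/4) Σ p_ij |i−j| over the row-normalized confusion matrix; rows
  with zero support are reported as undefined (NaN), and D refuses
  non-stochastic input. Degrees = D × 0.88.
- Binomial threshold: smallest k with P(X ≥ k) < α, X ~ Binomial(n, 1/4),
  by exact tail summation. (As α → 1 the threshold falls to the bottom of
  the attainable grid, 1/n — a zero threshold would require P(X ≥ 0) < α,
  which no α ≤ 1 satisfies.)
- Permutation test: location labels permuted within subject (subject
  structure preserved), full LOSO rerun per permutation, add-one estimator
  p = (1 + #{DA* ≥ DA}) / (B + 1), so p ≥ 1/(B+1) and a label-invariant
  classifier yields p = 1. Ties make the estimator conservative
  (super-uniform), which the null-calibration test tolerates.
- HEOG confound split: subjects ranked by |HEOG| at 500 ms post cue
  (mean over kept cue-locked epochs); the ceil(n/3) largest movers form
  group 1 (5 of 15), the rest group 2 (10 of 15); decoding is rerun on
  group 2 alone. Boundary ties resolve by subject id.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the full default study (15 subjects × 600
trials, ~1 minute on one CPU) with 200 permutations. The statistical
property tests use reduced designs chosen for tight Monte-Carlo behavior at
small cost: parameter recovery uses 15 subjects × 40 trials (high SNR:
2 μV noise; null: zero amplitudes at 10 μV noise, accuracy checked against
the exact 95% binomial band around 25%); permutation-null calibration uses
150 replicates of 8 subjects × 19 permutations against the discrete
uniform; the eccentricity-ordering property uses feature-level synthesis
(60 subjects, noise equal to the inner amplitude) where the expected
diagonal gap between outer and inner locations is large relative to
sampling noise. Worked values (66% display, 0.62 × 0.88° = 0.55°,
12/6 feature counts, 150 trials per location, 15 folds, 25% ± 0.5 chance
convergence at 100,000 draws) are exact.

## Known limitations

- The generator's channels are independent; spatial covariance and
  reference-electrode artifacts are not modeled.
- Component latencies are fixed; latency-based features or jitter
  robustness beyond the ±20 ms window shift are untested.
- The dendrogram is built from class centroids; centroid-degenerate
  geometries (identical means, different covariances) produce a valid but
  arbitrary tree.
- Single-feature accuracies on synthetic data depend on which components
  overlap each window (the sustained negativity leaks into target-locked
  windows exactly as real SPCN would); they are not calibrated to any
  empirical feature ranking.
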