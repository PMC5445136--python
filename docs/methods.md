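# Methods notes

## The synthetic protocol generator

The generator emulates a stimulation study in which each subject
receives, per session, one 1-minute trial at each of four states —
baseline (L0) and electrical stimuli at 20/30/40 mA (L1–L3) — in a
seeded random order, 30 sessions per day; six subjects are recorded on
one day and one designated subject on 7 consecutive days. Only the
1-minute stimulus windows are synthesized: the 1.5–2 min recovery
periods carry no analysed signal, and features use in-trial data only.

Waveform models are deliberately simple; the fidelity target is that
the four states are visibly and statistically different, not that
individual beats are physiological:

* **BVP** — three-harmonic pulse wave at the subject's heart rate with
  2% respiratory frequency modulation (0.25 Hz). Level effects: heart
  rate rises by `heart_rate_gain_per_level` (bpm per level rank) and
  pulse amplitude shrinks by `bvp_attenuation_per_level` per rank
  (sympathetic vasoconstriction).
* **ECG** — a PQRST Gaussian-component template train at the same heart
  rate with 3% inter-beat jitter, over a 0.12 Hz, 120 µV baseline
  wander that the preprocessing stage must remove.
* **SCL** — tonic level plus a stimulus-locked phasic ramp
  `g·r·(1 − e^(−t/τ))` with τ = 8 s, gain `g` per level rank `r`.
  At L0 with zero noise the channel equals the tonic level exactly.

Per-subject parameters are drawn uniformly from documented ranges
(heart rate 62–78 bpm, gain 4–7 bpm/level; BVP amplitude 8–12,
attenuation 0.10–0.18/level; tonic SCL 4–10 µS, phasic gain 0.8–1.5
µS/level; channel noise SDs 0.25–0.45, 15–30 µV, 0.02–0.05 µS). Day
drift adds per-(subject, day) offsets to tonic SCL (SD 0.2–0.5 µS),
baseline heart rate and BVP amplitude, so between-day variance of
feature means dominates within-day variance. All three level effects
scale with a single `effect_scale` knob; 0 gives a null world in which
the four labels are exchangeable, used for chance-level leakage
controls. The default effect sizes were fixed once so that the full
processed pipeline separates the four classes well above chance but
below ceiling for the linear classifier; they are not fitted to any
external data.

What the generator does **not** emulate: motion and electrode
artifacts, habituation across sessions, heart-rate variability beyond
jitter, respiratory coupling between channels, and any psychological
confound. Passing tests therefore demonstrate the pipeline's
correctness and its behaviour under the documented statistical
structure, not clinical performance on human recordings.

## Preprocessing

Filtering is a single forward pass (no zero-phase filtering); start-up
transients die out well before the analysed 30-s span. The ECG
high-pass cutoff (0.5 Hz, order 2) and the moving-average spans (50 ms
ECG, 500 ms SCL) are standard practice values and configurable.
"Adaptive" baseline correction is realized as fiducial-anchored
piecewise-linear subtraction: R peaks are detected on the smoothed
signal, the baseline is sampled at the inter-beat envelope minima,
linearly interpolated and subtracted; with fewer than two fiducials the
median is subtracted.

The module's default BVP band is the protocol's printed [30, 200] Hz,
which requires a sampling rate above 400 Hz; `preprocess_bvp` rejects
infeasible bands explicitly rather than silently clamping. Since the
protocol itself samples at 256 Hz, the evaluation pipeline's default
configuration substitutes a pulse-preserving 0.5–12 Hz band with the
same order and gain; the printed band remains available via
configuration for higher-rate data.

## Features and normalization

The analysis span is the second half of each 1-minute trial (pain
reaction lag), cut into ten non-overlapping 3-s windows; each window's
N is its own sample count (768 at 256 Hz, 384 for the decimated SCL).
f9 = min/N and f10 = max/N are implemented literally as printed in the
source formulas, dimensionally odd but harmless; they are exactly
collinear with f7/f8 within a channel, which the reduction stage
removes. Conventions for degenerate inputs: a zero-variance window
yields f4 = f6 = 0; a constant feature column min–max-normalizes to 0.
Normalization bounds are fitted on training rows only and applied to
test rows (which may therefore leave [0, 1]); a `global_norm` switch
reproduces whole-set normalization for comparison.

## Genetic algorithm

Interpretation choices where the procedure was underspecified:

* "Gaussian mutation" on binary genes is undefined; mutation is
  independent per-bit flips at the stated rate 0.01, preserving the
  printed rate semantics.
* Steady-state replacement: the offspring replaces the current worst
  individual iff fitter, making best fitness monotone and the
  "best generation" statistic well defined.
* One generation = `population_size` breeding events, so 30 generations
  of a 100-individual population bound fitness evaluations at ≈3,100;
  evaluations are memoized by bit pattern.
* Fitness is stratified k-fold CV accuracy (5-fold at full budget) of
  the configured classifier, LDA by default; the empty subset scores 0,
  and an all-zero total fitness makes roulette selection uniform.

A reduced budget (population 30 × 10 generations, 3-fold fitness CV)
is provided for desk-scale runs and benchmarks; the full 100 × 30
budget remains the default for the `select` stage.

## PCA rank choice

Eigenvectors are sign-fixed (largest-magnitude entry positive) for
reproducibility, and PCA is fitted on training rows only. The pipeline
default keeps **all non-degenerate components** (cumulative-variance
threshold 1.0): on min–max-scaled statistical features, class-
discriminative structure often lives in low-variance directions, and
truncating at 95% (or even 99%) cumulative variance measurably reduced
held-out accuracy below the raw-feature model on the synthetic cohort,
inverting the expected benefit of feature processing. At threshold 1.0
the projection still decorrelates the features and removes the exactly
redundant directions (the f9/f10 collinearities contribute zero
eigenvalues), which is the stated purpose of the reduction stage.
Aggressive truncation remains available (`pca_variance_threshold`,
`pca_k` / `--pca-k`), and `choose_k`'s own signature default stays at
0.95 for standalone use.

## Classifiers

* LDA one-vs-rest: four binary discriminants, argmax of their outputs.
  The scikit-learn svd solver tolerates the exact collinearities of the
  raw 36-feature set without explicit covariance regularization.
* KNN: k = 3, Euclidean on standardized features, votes weighted 1/d;
  an exact match (d = 0) claims the query. Residual ties resolve by
  label order.
* SVM: "width 2.58" is read as the RBF σ in exp(−‖x−y‖²/(2σ²)), i.e.
  gamma = 1/(2σ²) ≈ 0.0751. Multi-class strategy is one-vs-rest,
  mirroring the LDA design. Grid-search ranges (disabled by default)
  are C ∈ {0.1, 1, 5, 10, 100}, σ ∈ {0.5, 1, 2.58, 5, 10}, 5-fold
  stratified CV, ties toward smaller C then larger σ.

All three standardize features to zero mean and unit variance with
training-set statistics.

## Evaluation scenarios

Run-to-run variance in the repeated-split scenarios comes from fresh
stratified 75/25 splits per repeat (the documented interpretation of
"running n times"). The between-subject scenario repeats the full
leave-one-subject-out rotation per seed; the multi-day scenario leaves
each of the recorded days out once for the multi-day subject. Every
fitted object — normalization, GA chromosome, PCA model, classifier
standardization — is fitted strictly inside the training fold; the
null-setting tests verify the absence of leakage by staying within 3
points of the 25% chance level.

Note that splitting at the *window* level (as the repeated-split
scenarios do) places sibling windows of the same trial on both sides of
the split; nearest-neighbour-style classifiers benefit from the
resulting within-trial correlation. The leave-one-subject-out and
leave-one-day-out scenarios are free of this effect.

## Problem sizes

The test suite and the acceptance script use desk-scale problem sizes
chosen as the package's defaults for quick verification: the benchmark
cohort is 6 subjects × 1 day (720 trials, 7,200 windowed samples) with
the reduced GA budget and 5 split seeds; unit and property tests use
1–2 subjects with 2–30 sessions, 100–1,000-window Monte-Carlo checks,
and 20-seed GA recovery experiments on planted-feature data.

## Known limitations

* Synthetic waveforms only; no artifact model, no habituation, no
  cross-channel physiological coupling.
* The printed BVP band is unusable at the protocol's own sampling rate;
  the pipeline substitutes a pulse-band default (above).
* Single-objective GA without parallel fitness evaluation; determinism
  per seed is the contract.
* No probability calibration or significance testing across
  classifiers; reports are accuracies, per-class rates and confusion
  matrices.
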