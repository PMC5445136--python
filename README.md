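# painsig

Objective pain-intensity recognition from peripheral physiological
signals. For patients who cannot self-report pain — people with severe
cognitive or communicative impairment, ICU patients with disorders of
consciousness — an automatic, physiology-based estimate of pain level is
the alternative to rating scales. `painsig` implements a complete,
tested pipeline for a four-state pain classification problem (baseline
plus three calibrated electrical-stimulation intensities, 20/30/40 mA)
from three wearable-sensor channels: blood volume pulse (BVP,
photoplethysmography), electrocardiogram (ECG, lead I) and skin
conductance level (SCL), all sampled at 256 Hz in 1-minute trials.

Because no public recordings exist for this protocol, the package ships
a first-class synthetic-data module that emulates the stimulation
protocol (6 subjects × 30 sessions × 4 levels per day, 7 consecutive
days for one subject) with level-dependent cardiovascular and
electrodermal responses, subject-to-subject and day-to-day variability,
and configurable effect sizes including a null setting for chance-level
controls.

## Method

1. **Preprocessing** — per channel: Butterworth bandpass on BVP (order
   4, gain 3), high-pass + moving-average + fiducial-anchored baseline
   correction on ECG, moving-average smoothing and ×1/2 decimation on
   SCL.
2. **Feature extraction** — the last 30 s of each trial is cut by a 3-s
   sliding window (step 3 s → 10 windows/trial). Each window of each
   channel is summarized by 12 statistics: mean μ, standard deviation σ,
   mean absolute first difference θ₁ and its standardized form θ̃₁ =
   θ₁/σ, mean absolute second (lag-2) difference θ₂ and θ̃₂ = θ₂/σ,
   min, max, min/N, max/N, range, and median — 36 features per window.
   Features are min–max normalized with bounds fitted on training data.
3. **Feature selection** — a steady-state genetic algorithm over 36-bit
   masks (roulette-wheel selection, two-point crossover at rate 0.8,
   per-bit mutation at rate 0.01, replace-worst survival; population
   100 × 30 generations at full budget). Fitness is the stratified
   k-fold CV accuracy of the downstream classifier on the selected
   subset — wrapper selection that directly optimizes recognition rate.
4. **Feature reduction** — PCA on the selected subset: eigenpairs of the
   sample covariance in descending eigenvalue order; rank-k projection
   with k chosen by cumulative explained variance.
5. **Classification** — one-vs-rest LDA (argmax of four binary
   discriminants), KNN (k = 3, Euclidean, inverse-distance votes), and a
   soft-margin RBF SVM (C = 5, kernel width σ = 2.58, optional CV grid
   search), each on training-standardized features.
6. **Evaluation scenarios** — single-signal, multi-signal raw,
   multi-signal processed, pooled multi-subject, leave-one-subject-out
   and leave-one-day-out, with per-class accuracies, confusion matrices
   and mean ± SD over seeded repeats. All fitting happens inside the
   training fold.

## Worked example

```python
import dataclasses
import painsig as ps
from painsig import evaluation as ev

proto = ps.ProtocolConfig(n_subjects=2, n_days=1, sessions_per_subject=6)
trials = ps.simulate_cohort(proto, master_seed=42)
print(f"{len(trials)} trials")

cfg = dataclasses.replace(ev.PipelineConfig(), n_repeats=3, seed=42).reduced_ga()
report = ev.run_scenario("multi_signal_processed", trials, cfg)
print(ev.summarize(report)[["classifier", "n_runs", "mean_accuracy",
                            "sd_accuracy", "chance"]].to_string(index=False))
```

prints

```
48 trials
classifier  n_runs  mean_accuracy  sd_accuracy  chance
       knn       3       0.963889     0.012729    0.25
       lda       3       0.980556     0.020972    0.25
       svm       3       0.980556     0.012729    0.25
```

Two subjects × 6 sessions give 48 one-minute trials → 480 windowed
samples. Over three stratified 75/25 splits, the processed pipeline
(GA at the reduced 30 × 10 budget, then PCA, then each classifier)
classifies the four pain states with ~96–98% mean accuracy against a
25% chance level; the SD column is the spread over the three splits.
The null setting (`simulate_cohort(..., effect_scale=0.0)`) drops every
classifier to chance, confirming that nothing fitted on training folds
leaks test labels.

The same stages are scriptable from a shell:

```sh
painsig simulate --subjects 6 --sessions 30 --seed 1 --out data/
painsig extract  --data data/ --out features.csv
painsig select   --features features.csv --out chromosome.txt --seed 1
painsig evaluate --scenario multi_subject --data data/ --out report.csv
painsig run      --config pipeline.yaml       # whole pipeline from YAML
```

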