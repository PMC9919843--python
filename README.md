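# freqhar

Frequency-band-enhancement filters and model ensembles for
accelerometer-based human activity recognition.

## The problem

Wearable-sensor activity recognition classifies short windows of
triaxial accelerometer data (walking, jogging, standing still, stair
climbing, ...) with a 1D CNN. Different activities concentrate their
energy at different frequencies — a walking cadence near 1 Hz, jogging
near 3 Hz, standing still almost entirely in the DC component — but
standard pipelines feed the raw window to the model and ignore this
structure. `freqhar` implements a three-phase method that discovers the
frequency each activity depends on and exploits it:

1. **Importance discovery.** Train a classifier M on raw training
   windows. For validation windows `x ∈ ℝ^{3×w}` (subjects disjoint
   from training), occlude one FFT bin `f` at a time,

   `x′ = F_m(x, f) = ifft(P(fft(x), f))`,

   where `P(·)` zeroes bin `f` (never the 0 Hz DC bin), sweeping `f`
   over `(0, f_s/2]`. The bin whose removal most reduces a class's
   recall is that class's *important frequency* `f_c`; a class whose
   recall never drops resolves to 0 Hz. The result is the bank
   `ℱ = {f_c | c ∈ C}`.
2. **Emphasis during training (DA).** For each class `c`, train a model
   `M_c` on training data filtered by a gain profile that keeps the
   amplitude spectrum at `f_c` intact and attenuates other bins toward
   a floor of 0.5 — shaped as a peak, Gaussian (σ = 10 bins),
   triangular, or random window (the uninformed control).
3. **Emphasis during testing (TTA) + ensembling (EL).** Each `M_c`
   predicts on the test window filtered by its own profile; the final
   label is the majority vote of the |C| members, with deterministic
   tie-breaking (highest mean winning score, then lowest class index).

An 8-row ablation harness toggles DA/TTA/EL independently, and a
filter-comparison harness runs the full method with each window shape.

The classifier is a 1D adaptation of VGG16 (13 kernel-3 convolutions in
five pooled blocks) with a global-average-pooling head and a single
fully-connected layer, implemented directly on numpy with explicit
backpropagation and Adam — training is bitwise-reproducible under a
fixed seed. A `tiny` scale (channel widths ÷ 8) keeps desk-scale
experiments fast.

Because the public corpora this method targets cannot be bundled, the
package ships a synthetic benchmark generator: classes with distinct
planted oscillation frequencies (plus one DC-only "static" class),
subject-level frequency/amplitude jitter, and Gaussian noise, so every
phase — including subject-disjoint splitting and end-to-end frequency
recovery — is testable from nothing.

## Worked example

```python
from freqhar.benchmark import run_benchmark_trial

trial = run_benchmark_trial(seed=1)
for label, (k, hz) in trial.recovered.entries.items():
    print(f"{label:10s} {hz:4.1f} Hz (bin {k:2d}; planted bin {trial.planted.bin_of(label)})")
print(f"recovery: {trial.recovery_hits}/{trial.n_classes} classes within one bin")
print(f"plain single model     test accuracy: {trial.acc_single:.3f}")
print(f"full method (gaussian) test accuracy: {trial.acc_full['gaussian']:.3f}")
```

prints

```
osc_bin03   1.5 Hz (bin  3; planted bin 3)
osc_bin06   3.0 Hz (bin  6; planted bin 6)
osc_bin10   5.0 Hz (bin 10; planted bin 10)
static      0.0 Hz (bin  0; planted bin 0)
recovery: 4/4 classes within one bin
plain single model     test accuracy: 0.766
full method (gaussian) test accuracy: 0.875
```

The masking sweep recovered every planted frequency exactly — including
the static class resolving to the DC component — and the full method
(per-class emphasis + test-time filtering + majority vote) beats the
plain single model trained on the same data.

The same pipeline is scriptable from the shell:

```bash
freqhar simulate data/ --seed 3          # write benchmark CSVs + manifest
freqhar discover bank.csv --seed 0       # phase 1: important frequencies
freqhar train-ensemble bank.csv models/  # phase 2: per-class members
freqhar evaluate bank.csv                # phase 3: DA+TTA+EL test accuracy
freqhar ablation ablation.csv            # 8-row DA/TTA/EL ablation table
freqhar compare-filters filters.csv      # peak/gaussian/triangular/random
```

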