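# Methods

## Spectral model

A window is `x ∈ ℝ^{3×w}` (three acceleration axes, `w` samples at
`f_s` Hz). All filtering happens on the one-sided real FFT: bin `k`
maps to `k·f_s/w` Hz, the highest bin is at or below Nyquist, and bin 0
is the DC component (the window mean — posture/gravity orientation).
A *gain profile* is a real per-bin multiplier `g_k ∈ [0, 1]`; applying
it multiplies each complex rFFT coefficient by `g_k` and inverse
transforms, so amplitude scales while phase is untouched and the output
is exactly real. Consequences used as test oracles: unit gains are the
identity, the operation is linear, gains ≤ 1 can only remove energy
(Parseval), masking is idempotent, and a pure tone at bin `k` emerges
with its amplitude scaled by exactly `g_k`.

Masks set one bin (optionally a band) to zero, everything else 1. The
DC bin is never masked and never attenuated by any emphasis filter: for
static activities it is the only informative component, and attenuating
it would confound the sweep's attribution. The transform length is `w`
as-is (no zero padding), so bin frequencies line up with the window
grid.

Emphasis windows have gain 1 at the centre bin `f_c` and a floor of
0.5 elsewhere:

* **peak** — 1 at the centre, 0.5 everywhere else;
* **gaussian** — `0.5 + 0.5·exp(−(k−c)²/(2σ²))`, σ = 10 **bins** by
  default (σ's unit is a genuine design choice; bins keep the shape
  grid-relative and are configurable);
* **triangular** — linear ramp from 1 at the vertex, clamped at 0.5;
  the half-width defaults to the distance from the centre to the
  farther spectrum edge, so the ramp spans the whole band;
* **random** — i.i.d. uniform gains on [0.5, 1] over (0, 7.8] Hz, gain
  1 above the cutoff (configurable to 0.5 for floor-consistency). This
  window carries no class information and serves as the control that
  isolates the value of emphasizing the *right* frequency.

## Importance discovery

The sweep masks exactly one bin per step (step = bin resolution
`f_s/w`); the reported per-class accuracy is recall within the class,
the only per-class accuracy computable from true-label stratification.
Selection takes the argmin of the recall-vs-masked-bin curve, ties
toward the lowest bin; if no mask lowers recall below
`baseline − 0.005` the class resolves to 0 Hz. The 0.005 tolerance
absorbs prediction flutter on finite validation sets without letting a
real dip through; bins where masking *improves* recall never influence
the choice. Both the tolerance and an optional occlusion band width are
configurable.

## Classifier

1D VGG16: 13 kernel-3, stride-1 convolutions in five blocks
(64,64 | 128,128 | 256,256,256 | 512,512,512 | 512,512,512), size-2 max
pooling after each block, global average pooling, one fully-connected
layer. `tiny` scale divides channel widths by 8. With no padding each
convolution removes 2 samples and each pooling halves (floor): a
256-sample window reaches a pre-GAP length of 2, while a 151-sample
window dies in the fifth block — construction fails fast naming the
layer and pointing to `padding='same'`, which short windows require.

The network, backpropagation and Adam are implemented directly on
numpy (float64). This keeps the dependency surface minimal and makes
training bitwise-reproducible under a fixed seed on a given machine —
a property the determinism tests assert exactly, not approximately.
Choices the interface leaves open: optimizer Adam at learning rate
0.001; loss cross-entropy; model selection final epoch (best-validation
checkpointing behind a flag); batch normalisation off by default to
match the classic architecture, with an on-flag. Non-finite loss aborts
with the epoch/batch named.

## Ensembles, voting, ablation

With DA, member `M_c` trains on the *whole* training set filtered by
class `c`'s profile. For the DA-with-single-model ablation rows the one
model trains on the union of all |C| filtered copies — the plain
data-augmentation reading of applying every filter to the training
data. Without DA, ensemble diversity comes only from seed-varied
initialisation. Random-window profiles are drawn once per member under
a recorded seed and reused at test time, so DA and TTA see the same
filter. Votes are argmax labels; ties resolve by the highest mean
winning score among tied labels, then the lowest class index —
deterministic and fully auditable, since every prediction returns the
complete per-member vote record from which any reported accuracy can be
recomputed.

## Synthetic benchmark

Defaults (fixed once, used by every end-to-end test and by
`scripts/acceptance.py`): 4 classes with dominant bins {0, 3, 6, 10}
on a `w=128`, `f_s=64` Hz grid (bin width 0.5 Hz); one static DC-only
class with a distinctive gravity-like offset (0.8, −0.2, 0.4); three
oscillatory classes at 1.5/3/5 Hz with a 2nd harmonic at 0.2 relative
amplitude, *sharing* DC offset and amplitude so frequency is the only
separating feature; noise s.d. 0.3 against unit amplitude (a moderate
consumer-accelerometer noise level); 10 subjects split 6/2/2 with ±2 %
frequency and ±10 % amplitude jitter plus random phases per subject;
16 s recordings, non-overlapping windows (8 per recording). Planted
frequencies sit on exact grid bins and jitter is capped at half a bin,
so recovery has unambiguous ground truth. Desk-scale training uses the
tiny model with `same` padding (128-sample windows cannot survive five
unpadded blocks), batch normalisation on for stable convergence, batch
size 64, 15 epochs.

What the generator does *not* emulate: biomechanical gait waveforms,
non-stationary activity transitions, broadband or autocorrelated noise,
gyroscope channels. Passing tests therefore demonstrate that the
machinery is correct and that the method behaves as designed when
classes genuinely differ by frequency — not that the accuracy levels
transfer to real recordings.

## Observed behaviour of the window shapes

On this benchmark the end-to-end pipeline (recovered bank feeding the
ensembles) gives gaussian-window accuracy equal to random-window
accuracy in the 3-seed mean, and with the ground-truth bank the random
window can come out ahead. The reason is structural: with σ = 10 bins
on a 65-bin spectrum and planted bins all within 10 bins of each other,
the |C| gaussian member filters are nearly identical (gain ≥ 0.88 at
every other class's bin), so the ensemble loses member diversity,
whereas the random window draws a distinct filter per member and leaves
everything above 7.8 Hz untouched. On a wider grid, or with classes
spread further apart relative to σ, the shaped windows regain their
advantage; the benchmark keeps the pinned conditions rather than
tuning them, and the comparison harness reports whatever the run
produces.

## Numerical notes

* Tolerances: identity/linearity/tone-transfer asserted at 1e-9
  absolute; masked-tone residual energy below 1e-12 of input.
* `hz_to_bin` rounds to the nearest bin and rejects frequencies above
  Nyquist; window counts follow `floor((T−w)/stride)+1` with 0-based
  half-open intervals and the trailing remainder dropped.
* Degenerate inputs: recordings shorter than one window yield an empty
  list with a warning (not an error); a class absent from the
  validation split produces an undefined importance curve that
  selection refuses to score; an empty ensemble and a bank missing a
  class are rejected eagerly.
* Seeds: every stochastic step (weight init, batch shuffling, subject
  assignment, jitter, noise, random-window gains) flows from an
  explicit seed; derived seeds stay below 2³¹.
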