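# Methods

## The problem

Voluntary wheel running (VWR) is the standard low-stress exercise paradigm
for mice, but its conventional readout — wheel turns aggregated in 1-min
bins — hides nearly everything about how the animal actually ran.
`pawstrike` implements a video-based alternative: a convolutional network
classifies the hindlimb foot-strike frequency (an integer count of paw
contacts per second, expressed in Hz) for every second of a 2-h wheel
exposure recorded at 30 frames/s.  Mice run at roughly 2.5–10 Hz; a
second in which the animal is off the wheel or stationary is labeled
0 Hz.  Two cohorts are modeled: an aged cohort with 8 frequency classes
(0–7 Hz) and a faster young-adult cohort with 11 (0–10 Hz).

## Network and training

The input to the network is one second of video as a single tensor: 30
grayscale frames stacked on the channel axis of a 2-D convolution
("time as channels"), so the first filter bank has shape 4x4x30x30 and
temporal structure is mixed from the very first layer.  Three blocks of
same-padded 4x4 convolution (stride 1) + leaky-ReLU + 2x2 max pooling
(stride 2) halve the spatial resolution three times; the result is
flattened through three fully connected layers (256, 64, N_freq), and a
softmax over the final activations yields class probabilities.  The
predicted frequency is the argmax, with ties broken toward the lower
frequency (the conservative choice for an activity measure).

Training minimizes multi-class cross-entropy (computed in log space) by
plain mini-batch stochastic gradient descent — no momentum, no
regularization — under a stair-step schedule lr(e) = lr0 · decay^e
updated at each epoch end.  Reference hyperparameters are lr0 = 1e-4,
decay = 0.95, batch 36, 50 epochs (100 for transfer learning).  The
whole forward/backward pass is hand-written NumPy: convolutions are
evaluated as one GEMM per kernel offset, and the analytic gradients are
validated against central finite differences (relative error ≤ 1e-4 on a
float64 instance) in the acceptance suite.

Open architectural details were fixed as follows: the fully connected
widths (256, 64) follow the taper of a six-layer design at desk scale;
the pool window is 2x2; the leaky-ReLU slope is 0.2 (the common
framework default of the TensorFlow-1 era); weights use He (fan-in)
initialization with zero biases.  "Stride alternating between 1,1 and
2,2" is read as conv stride (1,1) + pool stride (2,2) per block, the
standard reading that halves resolution three times.  All are
configurable on `ModelConfig`.

### Data handling

Because roughly two thirds of labeled seconds are 0 Hz, train/test
splitting is stratified by class, with largest-remainder rounding so the
overall test count equals round(n · fraction) exactly (4800 clips at 10%
give exactly 4320/480; 1000 give 900/100).  Training data may be
augmented eight-fold — {identity, horizontal, vertical, both flips} x
{clean, +Gaussian pixel noise} — applied statically once before the
first epoch, and only to the training side; test clips are always raw.
Flips and pixel noise cannot change a strike count, so labels are
preserved by construction.  The noise magnitude is not specified by the
reference recipe; the default is sigma = 0.02 on [0,1] intensities,
visible but label-preserving.

### Transfer learning

A model trained on one cohort is adapted to another by copying all
layers and continuing training.  The aged-to-young transfer changes the
class count (8 → 11), which makes a verbatim copy of the final layer
shape-impossible; that layer is re-initialized at the new width and
everything remains trainable (no layer freezing).  This is the
minimal-deviation reading of "parameters for all layers were first
initialized" from the pretrained model.

## The synthetic ground-truth generator

No videos were deposited with the study, so the package ships a
generator that produces data with *known* labels, emulating the
statistical structure of the real datasets:

- **Label distributions.** Clip labels are drawn i.i.d. from the
  published class fractions of the two human-labeled datasets (aged:
  68.6% at 0 Hz, mass concentrated at 3–6 Hz; young: 49.2% at 0 Hz with
  a fast 6–8 Hz mode).  The printed, rounded percentages are
  renormalized to sum to one.
- **Clips.** A rendered clip contains a static textured background, a
  bright "wheel surface" row at 88% of frame height, an elliptical body
  whose hindquarters bob with the gait cycle, and a limb marker that
  descends to the surface row exactly f times in the second.  Strike
  instants are (i + u_i)/f with u_i uniform in ±`strike_jitter`
  (default 0.2) of the inter-strike interval; contact frames are forced
  at least two frames apart so events never merge at 30 frames/s (this
  caps renderable frequencies well above the 10 Hz the young cohort
  needs).  Between contacts the limb follows a sine arc with a lift
  floor of 0.4, so it is several pixels clear of the surface except at
  the strike instant — the event is unambiguous at any resolution.
  A 0-Hz clip is, with seeded probability 0.5, an empty cage or a
  present-but-motionless mouse, matching the two real meanings of the
  0-Hz label.  Geometry is parameterized by fractions of frame size, so
  the same scene renders at 64x64 (the default, chosen for CPU-scale
  training) or at the full 240x320.
- **Bouts.** A 2-h bout (7200 s) has episodic running: episode onsets
  are a Poisson process (default 6 starts/h), episode lengths are
  exponential (mean 120 s), and within-episode seconds draw their
  frequency i.i.d. from the running-conditional class distribution.
  Per-minute wheel turns are `turns_per_strike` x strikes that minute
  (default 0.25 — a stride advances roughly a quarter wheel turn) plus
  Gaussian noise (default SD 5 turns/min), floored at zero and rounded.
  The noise term is the model's only stand-in for wheel free-spin after
  the mouse jumps off.

An independent brute-force oracle in the test suite counts strike events
as rising edges of limb presence in the surface band (checking the
mirrored band too, so the count is flip-invariant) and recovers the
commanded frequency for 100% of noiseless clips across classes 0–10 and
several resolutions.

**What the generator does not emulate:** photorealistic appearance, coat
and lighting variability, camera jitter, partial occlusion, gait-phase
irregularity beyond per-strike jitter, and any temporal correlation of
frequency within an episode (per-second draws are i.i.d.; the real
correlation structure is unknown).  Accuracies obtained on synthetic
data therefore validate the *pipeline* — rendering, splitting,
optimization, gradients, metrics — not performance on real near-IR
video, which is substantially harder.

## Scaled-down experiments

The published accuracies were obtained from ~2000 h of video that is not
available, so the test suite validates behaviour with scaled-down
synthetic analogues sized for a single CPU:

- **Recovery.** 1200 aged-distribution clips at 64x64 split 1080/120;
  the network is trained for 9 epochs at lr0 = 0.015, decay 0.93 (a
  schedule chosen by a small convergence study on this task scale — the
  reference 1e-4/50-epoch setting is matched to the much larger real
  dataset) and must reach ≥ 0.90 exact held-out accuracy (median over
  3 seeds), with within-1-Hz accuracy at least as high.
- **Transfer ordering.** A model pretrained on aged-style clips and
  fine-tuned on 270 young-style clips must match or beat an identically
  budgeted from-scratch model on the same clips (median over 5 seeds) —
  the qualitative transfer-learning claim, tested as an ordering rather
  than as the irreproducible +28 points.
- **Correlation pipeline.** Over 50 simulated bouts with noiseless
  strike-to-turn coupling and perfect predictions, the bout-total
  regression gives r² = 1 to 1e-9; with default noise it stays > 0.9.

## Numerical choices and degenerate inputs

Softmax and cross-entropy subtract the row maximum / use log-sum-exp, so
arbitrary finite logits neither overflow nor produce NaNs.  Training
aborts with a diagnostic naming the epoch and batch if the loss goes
non-finite.  Max pooling uses ceil-mode (ragged edges padded with -inf),
so spatial sizes follow ceil(dim/2) per block and any input ≥ 8 px
works.  Ties in pooling route the gradient to the first maximal element.
Prediction ties go to the lower frequency.  Empty prediction series,
zero-variance regressions, non-normalized distributions, labels outside
the class range, duplicate clip ids and negative turn counts all raise
typed errors rather than propagating garbage.

## Known limitations

- AVI/MP4 decoding requires an ffmpeg-capable imageio plugin; without
  one, lossless containers (multi-page TIFF, NPZ) are the supported
  interchange format and video files raise a typed error.
- Training is single-threaded NumPy; it is sized for thousands of
  64x64 clips, not for the full 240x320 corpus.
- The 0-Hz class dominance means overall accuracy is a lenient metric;
  class-balanced accuracy is reported alongside it in evaluation
  output for transparency.
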