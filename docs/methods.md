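# Methods

## Problem setting

A subject performs standardized FOG-provoking tasks — timed-up-and-go (TUG:
stand, walk 2.5 m, turn, return, sit) and one-minute alternating 360°
turning in place (360Turn) — in Off- and On-medication states, with and
without a cognitive dual task, and in a second arm with volitional
(self-generated) or researcher-imposed stops.  Five inertial sensors
(pelvis, both tibiae, both tali) record 6 channels each (triaxial
accelerometer, triaxial gyroscope) at 64 Hz, giving a `T x 30` signal per
trial.  Expert annotation yields a per-sample tier with four classes:
non-FOG (0), FOG (1), FOG-related non-paroxysmal shuffling/festination (2),
and stop (3).  For training and evaluation the tier is collapsed to binary
with only class 1 positive — FOG-related movement and stops are negatives —
while the full tier is kept for error attribution.

## Detector

The model is a fully convolutional two-block sequence labeler.

**Initial prediction block.**  A 1x1 convolution lifts the 30 channels to
`F` filters, followed by `L` dilated residual layers (kernel 3, dilation
`2^l` in layer `l`, ReLU, 1x1 convolution, inverted dropout, residual
addition), and a 1x1 convolution to 2 logits per sample.  Softmax over the
two classes gives the initial `T x 2` probability sequence.  The receptive
field is `1 + 2 * sum_l 2^l`; configurations below 2 s (128 samples) are
rejected, since FOG episodes average ~3 s and the stop-vs-akinesia cue
(below) spans about a second of context.

**Refinement block.**  `S >= 1` further stages with the same layer
structure, each consuming the previous stage's `T x 2` probabilities and
emitting a refined `T x 2` sequence.  Refinement suppresses
over-segmentation — long episodes predicted as several short ones.

**Loss.**  Summed over stages: per-sample cross-entropy (optionally
inverse-frequency class-weighted, the default, since FOG is the minority
class) plus `lambda *` a smoothing penalty — the mean of squared differences
of consecutive log-probabilities, truncated at 16 (i.e. clamping
`|log p_t − log p_{t−1}|` at 4).  Defaults: `lambda = 0.15`, truncation 16.
Unlike the detached variant common in multi-stage action segmentation, the
penalty here is differentiated through both frames of each pair, so the
implemented gradient is exactly the gradient of the reported loss (verified
against finite differences in the test suite).

**Training and inference.**  The engine is written in NumPy (dilated conv1d
via an im2col GEMM, hand-written backward passes, Adam), float32, one whole
trial per optimization step — the model is length-agnostic, so no windowing
is used at train or test time.  Per-channel z-score normalization statistics
are computed from the training fold only and stored with the model,
preventing leakage under leave-one-subject-out (LOSO) evaluation.  Labels at
inference are the argmax of the final stage; a tie at probability 0.5
resolves to non-FOG (conservative toward the majority class).  Given a seed,
initialization, dropout, and shuffling are all driven by explicit
generators, so training is bit-reproducible.

**Default hyperparameters** (exposed via `DetectorConfig`, chosen as
package defaults, not as claims about any clinical system): initial block
8 layers x 64 filters, kernel 3, dilations 1..128 (receptive field 511
samples ≈ 8 s), dropout 0.1; refinement 3 stages x 8 layers x 64 filters;
Adam at 5e-4.  The experiment and test runs in this repository use a reduced
configuration — 7 layers x 16 filters with a single refinement stage
(receptive field 255 samples ≈ 4 s), 12 epochs at 5e-3 — which is ample for
the synthetic class structure and keeps a full LOSO run on a 10-subject
cohort in the minutes range on one CPU core.

## Rule-based post-processing

An alternative to the learned refinement: extract maximal predicted-FOG
runs, merge consecutive episodes whose gap is ≤ `gap_max` samples
(transitively, left to right), then remove episodes strictly shorter than
`min_len` samples.  Defaults are 21 samples each (0.33 s at 64 Hz),
reflecting that the large majority of true episodes exceed a third of a
second.  Merging precedes removal so fragments of a fragmented long episode
are reunited rather than deleted.  The boundary readings (gap ≤ threshold
merged; length < threshold removed) are configurable.  The pipeline is
idempotent, and with `gap_max = 0` and `min_len <= 1` it is the identity.

## Metrics

* **%TF** — `100 * (#FOG samples) / T`; the pooled, per-subject variant sums
  numerators and denominators over trials (equivalently a duration-weighted
  mean of per-trial %TF).
* **#FOG** — number of maximal FOG runs.
* **Sample-F1** — `F1 = TP / (TP + (FP + FN)/2)` on per-sample confusion
  counts of the positive class.
* **Segment-F1@k** — predicted episodes are assigned one-to-one to
  ground-truth episodes; a pair with IoU strictly greater than `k`
  (default 0.5) is a TP, other predictions are FP, and ground-truth episodes
  claimed by no prediction are FN.  The assignment is the optimal one:
  it first maximizes the TP count and then the number of additional
  overlapping (sub-threshold) claims, computed with a weighted linear-sum
  assignment.  A below-threshold prediction therefore still claims its
  episode — it is penalized once as FP, not twice as FP plus FN.  The test
  suite checks this equals an exhaustive search over all one-to-one
  matchings.
* **Degenerate F1** (no positives in either annotation): scored 1.0 by
  default — perfect absence-agreement counts as perfect agreement — and
  configurable to NaN to exclude such trials from averages.
* **Per-subject scores** are unweighted means over the subject's trials;
  overall scores are unweighted means over subjects.
* **ICC(2,1)** — two-way random-effects, absolute-agreement, single-rater
  intraclass correlation from ANOVA mean squares, with the standard
  F-distribution 95% CI.  With identical non-constant rater columns the
  coefficient is exactly 1 and the CI is undefined (returned as NaN); a
  table with no variance at all raises.  Verified in tests against an
  independent mean-squares computation and a reference implementation.
* **Bland–Altman** — bias = mean difference, limits of agreement
  bias ± 1.96 sd, normal-theory CIs for bias and both limits.
* **Strength bands** — ICC ≥ 0.80 strong, 0.60–0.79 moderately strong,
  0.30–0.59 fair, < 0.30 poor.

## Experiments

Training subsets follow the condition design: Model_TUG / Model_360Turn /
Model_Off / Model_On restrict the no-stopping trials by task or medication;
Model_Clinical takes all no-stopping trials; Model_Stop only stopping
trials.  Evaluation is LOSO: one model per fold, trained on the subset
trials of the remaining subjects, evaluated on the held-out subject.  Folds
without positive training labels are skipped with a warning.  Model
comparisons use a two-sided paired t-test over per-subject values with
Levene and Shapiro–Wilk diagnostics (α = 0.05 reported, not enforced);
zero-variance nonzero differences are flagged degenerate rather than coerced.
A stop counts as a false positive if **any** predicted-FOG sample falls
inside it — the strictest reading.  Error attribution reports the percentage
of false-positive samples lying in FOG-related (tier-2) intervals.

## Simulator

The generator is phenomenological: sums of gait harmonics plus
manifestation-specific templates plus Gaussian noise.  It aims to give the
detector learnable class structure with the documented spectral and variance
signatures, not biomechanical fidelity.

* **Gait** — quasi-periodic oscillation at the configured cadence
  (default 1.8 steps/s) with a second harmonic, fixed per-channel gains and
  phases (lower limbs strong, pelvis attenuated), gravity offset on
  accelerometer z channels, and an alternating yaw rate on the pelvis gyro
  during 360Turn trials.
* **Trembling FOG** — locomotor content replaced by an oscillation at a
  per-episode frequency drawn uniformly from 8.5–12.5 Hz (so the measured
  spectral peak stays within the nominal 8–13 Hz band), strongest on
  tibia/talus gyro channels.
* **Shuffling FOG** — cadence x 1.6 at amplitude x 0.25.  FOG-related
  (tier-2) events use a deliberately similar template (cadence x 1.4,
  amplitude x 0.4) so that models confuse them with FOG — mirroring the
  known clinical failure mode — while remaining negatives in training.
  No quantitative description of shuffling kinematics was available; these
  factors are a repository convention.
* **Akinetic FOG** — near-zero lower-limb signal preceded by an abrupt
  0.3 s trembling burst at onset.
* **Stops** — near-zero lower-limb signal preceded by a smooth cadence
  decay of 0.6–1.2 s (and a 0.5 s resumption ramp).  The abrupt-vs-smooth
  onset is the learnable cue separating akinetic FOG from stopping; without
  some such cue the two regimes would be indistinguishable from lower-limb
  quiescence alone and the stop-training effect would be untestable.  The
  quiescence guarantee (lower-limb variance < 5% of walking variance) holds
  for stop intervals and for akinetic intervals outside the onset burst.
* **Episode durations** — log-normal with mu = 0.2596, sigma = 1.298,
  clipped to [0.05 s, 63.62 s]; the parameters solve mean = 3.01 s with
  ~42% of episodes shorter than 1 s (a deliberately hard, short-episode
  regime).
* **Protocol** — per subject and medication state: 2 TUG + 1 360Turn, with
  and without dual task (12 clinical trials), plus 4 stop-TUG + 1
  stop-360Turn for each of self-generated and imposed stopping (20 stopping
  trials): 32 trials total.  TUG durations are uniform 15–60 s; 360Turn is
  60 s.  Episode onsets follow a Poisson process at `fog_rate_per_min`
  (default 2.2/min, giving a cohort %TF around 15%), scaled by a per-subject
  log-normal severity multiplier (sd 0.8 on the log scale, spreading
  subject %TF from near 0 to tens of percent) and by 1.5 under dual task.
  Events are placed with 1 s clearance and never overlap stops.
* **Determinism** — cohorts are generated from a seed tree
  (`SeedSequence` spawning per subject and per trial), so identical
  configurations are bit-identical and any trial can be regenerated
  independently.

**What passing tests do and do not show.**  The synthetic classes are far
more separable than clinical data: real FOG has gradual onsets, annotator
disagreement, sensor artifacts, and manifestation mixtures within one
episode, none of which are modeled.  High LOSO F1 on synthetic cohorts
demonstrates that the pipeline is implemented correctly end to end (the
architecture can represent and recover the labels, the evaluation machinery
measures what it claims), not that comparable accuracy would be obtained on
patients.  Directional findings — e.g. that a stop-naive model mislabels far
more stops as FOG than a stop-trained model — are expected to transfer
qualitatively, since they follow from the training distribution, not from
signal realism.

## Numerical and design choices

* Indices are 0-based; segments are half-open `[start, end)`.
* Label resampling between annotation rates (e.g. 30 fps video to 64 Hz
  IMU) assigns each output sample the label of the temporally nearest source
  frame, ties toward the earlier frame; labels are categorical, so no
  interpolation.
* On-disk trial files store signals to 8 significant digits (read/write
  round trips agree to at least 6).
* The experiment suite evaluates the stop-training contrast on stopping
  trials of held-out subjects via a 7/3 subject split (two model fits)
  rather than a full LOSO sweep (twenty fits); the contrast is between
  training subsets, and a held-out-subject split estimates it at a tenth of
  the cost.
* Problem sizes used by the test suite: capacity checks fit 5 trials;
  recovery and stop-contrast checks use 10-subject cohorts (120 and 320
  trials); oracle-equivalence checks use 500 random instances per rule and
  100 random rating tables.

## Known limitations

* No biomechanical realism: no turning-specific freezing geometry, no
  upper-body model, no festination-to-FOG transitions, no sensor dropout.
* The detector has no GPU path; it is sized for desk-scale experiments.
* ICC confidence intervals assume the standard two-way ANOVA model; with
  n = 2 subjects they are essentially uninformative (and undefined for
  degenerate tables).
* The CLI covers the common workflows; programmatic use is the primary
  interface.
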