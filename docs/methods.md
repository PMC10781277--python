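# Methods

## Problem setting and pipeline

The package classifies annotated upper-limb movement segments of
hemiparetic stroke patients and non-disabled (ND) controls from five
body-worn IMUs. A *segment* is one annotated movement instance (five
repetitions of the movement); segments vary widely in duration, so the
pipeline first equalizes lengths and only then cuts fixed-size windows:

1. zero-center every channel over the segment;
2. keep the 30 accelerometer + gyroscope channels (magnetometer readings
   depend on heading relative to the Earth's field and are discarded);
3. for left-hemiparesis participants, exchange the right/left wrist
   sensor blocks and the right/left upper-arm blocks (axis values are not
   negated), so the dominant activity sits on the same sensor columns for
   every participant;
4. linearly interpolate to the task's fixed length (ROM 1000, ADL 3700
   time points);
5. cut sliding windows (ROM 200/stride 42, ADL 740/stride 150), giving
   exactly 20 windows per segment. Equal window counts per segment are
   the point: they remove the class imbalance that variable durations
   would otherwise create.

### Numerical choices in preprocessing

- **Interpolation abscissa is sample index, not wall-clock time.** The
  recordings' nominal 80 Hz rate is treated as descriptive; resampling on
  index keeps the operation deterministic under irregular sampling.
  Query positions are `linspace(0, n−1, T)`, so endpoints are exact and a
  channel that is affine in sample index is reproduced with zero error.
- **Centering happens once, before interpolation.** Interpolated signals
  are not re-centered; the residual mean after piecewise-linear
  resampling of a zero-mean signal is negligible for the energy score and
  irrelevant to the classifier.
- **Trailing samples** not covered by the final window (ROM rows 998–999,
  ADL rows 3590–3699) are discarded, per the stated stopping rule
  ("advance by the stride until the remainder is shorter than the
  window").
- Segment indices are 0-based half-open `[start, end)`.

## Asymmetry score

For zero-centered values `x_{c,t}`, side energies are mean per-channel
mean squares over the lateralized sensors (right: sensors 1 and 4; left:
2 and 5; accelerometer + gyroscope only, 12 channels per side — the trunk
sensor is unlateralized and magnetometers are excluded, consistent with
the six-channel selection that precedes the score):

    E_R = (1/N_R) Σ_{c∈RC} (1/T) Σ_t x_{c,t}²,   E_L analogous
    S_asym = ln((E_R + ε)/(E_L + ε)),  ε = 0.001

Scores are computed on interpolated segments by default (T constant
across segments, as the definition assumes); a raw-length path exists for
exploratory use. The movement-type summary (AAS = |S_asym|) averages each
movement across participants first and then movements within type, with a
pooled-segments alternative; a single-member group reports sd 0
(population sd convention, ddof = 0).

## Synthetic data generator

The generator emulates the *statistical structure* the analysis depends
on, not limb biomechanics:

- **Class templates.** Each movement class defines, per accelerometer/
  gyroscope channel, a sum of 2–4 sinusoids with frequencies in
  0.5–3 Hz (upper-limb movement band) and fixed phases, normalized to
  unit RMS; templates are a deterministic function of (class, channel).
  Mirrored sensor pairs (1↔2, 4↔5) share templates per (modality, axis),
  so an execution with the other limb is the mirror image of the
  reference execution — this is precisely what makes the preprocessing
  side swap able to align left- and right-dominant executions, as it does
  for real mirrored movements.
- **Asymmetry.** The non-dominant side is rescaled so the pre-noise
  side-energy ratio exactly equals the movement type's target:
  UNI 110, BIA 1.67, BIS 1.25 — chosen so ln(ratio) lands on the
  published AAS ordering (≈ 4.7 / 0.51 / 0.22). The dominant side is the
  right for ND and right-hemiparesis participants and the left for
  left-hemiparesis participants. Measured AAS for UNI comes out below
  ln(110) ≈ 4.7 (≈ 4.0 at default noise) because the additive noise floor
  raises the silent side's energy; the ordering is unaffected.
- **Participant variability** enters only through per-channel amplitude
  factors (log-normal, sd 0.1), per-sinusoid phase offsets (sd 0.2 rad),
  a speed factor (sd 3%), and duration.
- **Stroke distortion** applies per-segment log-normal amplitude jitter
  (sd 0.3) and extra phase jitter (sd 0.5 rad) to the affected-side
  channels, and inflates mean duration by 1.3×. For bimanual-symmetric
  movements the jitter is attenuated (×0.3): the affected limb mirrors
  the intact limb's gross symmetric pattern, so symmetric executions are
  far less abnormal than movements where the affected limb carries the
  dominant or delicate role. This is the mechanism behind both the
  published movement-type F1 ordering and its synthetic counterpart.
- **Durations** are normal draws (ROM mean 1016, sd 492; ADL mean 4229,
  sd 3072 time points) clipped below at the observed minimum-scale floor
  of 240; clipping shifts the mean by ≈ 14 points, well inside sampling
  error at the tested sizes.
- **Magnetometer channels** carry a slow drift plus offset and noise;
  they exist only so the raw 45-channel dialect is complete.

What the generator does *not* emulate: realistic joint kinematics,
within-segment repetition structure (five repetitions are not modeled as
discrete bouts), cross-channel correlation beyond shared sinusoid
families, sensor saturation/drift, or annotation noise. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
its comparative conclusions hold under the assumed structure — not that
the specific F1 levels transfer to real recordings.

## Classifier

Four valid (unpadded) 1-D convolutions, kernel 5, stride 2, features
32/64/128/256 — each layer halves the temporal length
(`L' = ⌊(L−5)/2⌋+1`; 200→98→47→22→9 and 740→368→182→89→43) — followed by
dense layers 800/200/K. ReLU activates every hidden layer; the first two
dense layers use dropout 0.7 (training only, inverted scaling). Training
uses AdamW exactly as published (lr 1e−3, betas (0.9, 0.999), eps 1e−8,
decoupled weight decay 0.01 applied to all parameters), cross-entropy,
batch 256, 40 epochs, no padding/pooling/normalization layers, no
learning-rate schedule or early stopping; final-epoch weights are used.
The implementation is pure NumPy (im2col convolution + explicit backprop)
and is described as such.

### The output-layer activation

Read literally, the architecture applies ReLU to *all* layers including
the last dense layer, then softmax. Implemented that way
(`final_relu=True`), the head is fragile: once every logit of a batch
goes negative the softmax is exactly uniform and the gradient vanishes
identically — at desk scale the head reliably dies mid-training even when
the output biases are initialized positive (which this package does in
that mode, at 1.0, to start units in the active regime). A model whose
training collapses to chance cannot produce the published accuracy, so
the package's default is the conventional head — plain logits into
softmax cross-entropy (`final_relu=False`), standard practice in the
frameworks this architecture targets. The literal mode remains available
as a configuration flag.

Weight initialization (unspecified in the source description) is He
normal with zero biases; weights, shuffling and dropout all derive from
one seed, so training is reproducible on a fixed BLAS/thread
configuration. Inference is deterministic (dropout off); argmax ties
break toward the lowest class index.

## Evaluation protocol

- **ND condition**: train on all ND participants, evaluate every stroke
  participant (plain split — no stroke data in training).
- **Stroke condition**: LOSO over stroke participants.
- **Joint condition**: LOSO over stroke participants with all ND data in
  every training pool.

Per held-out participant, one-vs-rest precision/recall over that
participant's windows give a per-(participant, class) F1
(`2TP/(2TP+FP+FN)`, 0 when the denominator is 0); participant means,
group means ± sd (across participants), and movement-type means are
derived from that table. The default scoring unit is the window; a
segment-level mode (majority vote over a segment's windows, ties toward
the lowest class) is provided because windows of one segment are not
independent. Confusion matrices are row-normalized over pooled held-out
windows per group. Training/evaluation participant disjointness is
asserted on every split, and each split's seed and composition are
logged.

Augmentation, when enabled, applies to training segments only — one
uniformly rotated copy per segment (angle uniform in ±90°, axis uniform
on the sphere), drawn at segment level *before* windowing so all 20
windows of a copy share one rotation (a whole-recording orientation
change); gyroscope triplets rotate identically to accelerometer triplets
since angular rates transform as vectors under frame rotation. A
per-sensor rotation scope is available. The test-time nuisance option
rotates each *evaluation* segment independently, emulating unseen sensor
orientations at deployment.

## Desk-scale scenarios

The full-scale protocol (thousands of full-length segments, 40 epochs) is
impractical for routine testing, so `imuhar.scenarios` fixes two reduced
designs used by the tests and the acceptance script:

- segments of mean 300 (sd 80, floor 120) time points, interpolated to
  290 and cut into the same 20 windows per segment (window 100,
  stride 10);
- training for 10 epochs with batch 64 — the batch is scaled down with
  the ~10× smaller training sets so the number of optimizer updates stays
  proportionate to the full protocol's (batch 256 remains the full-scale
  default);
- *recovery*: 8 ND + 4 stroke participants, 8 unimanual classes, default
  noise and distortion; joint-condition LOSO should reach macro F1 ≥ 0.8
  on held-out stroke participants.
- *trend*: 6 ND + 4 stroke participants, 9 classes cycling
  UNI/BIA/BIS, evaluated under test-time rotation nuisance; used for the
  directional checks (joint > stroke-only; augmentation within 0.02 of,
  and typically above, no-augmentation; BIS > BIA for the stroke group),
  averaged over three seeds because single-seed margins fluctuate.

## Known limitations

- The NumPy network is single-threaded apart from BLAS matmuls; it is
  sized for the desk-scale scenarios, and full-scale runs (ADL windows of
  740×30, tens of thousands of windows, 40 epochs) are possible but slow.
- Reproducibility is exact for a fixed BLAS build; across builds,
  floating-point reduction order may change results at the last few bits.
- The exclusion rule needs the task's expected movement set; when it is
  not supplied it is inferred as the union of annotated movement ids,
  which under-detects movements missing from *every* participant.
- Statistical comparison across conditions is descriptive (means ± sd and
  matched-seed directional checks); mixed-effects modeling of condition
  effects is out of scope.
- The real released dataset's on-disk annotation schema is not fixed by
  its description; the readers accept declared header/column maps for
  that reason, and the CSV dialect written by the generator is the
  reference for the round-trip contract.
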