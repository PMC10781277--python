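# imuhar

Upper-limb activity recognition for hemiparetic stroke rehabilitation from
body-worn inertial sensors.

After a stroke, encouraging use of the more-affected arm in daily life
requires knowing *which* movements a patient performs at home. This package
implements a complete pipeline for classifying upper-limb movements from
five IMUs (right/left wrist, right/left upper arm, trunk; accelerometer +
gyroscope + magnetometer, 45 raw channels at a nominal 80 Hz), aimed at
researchers in wearable-sensor human activity recognition and
rehabilitation engineering. It covers:

- **I/O** for CSV recordings and segment annotations, with the study's
  exclusion rule (a participant missing more than one movement segment is
  dropped);
- **preprocessing**: per-segment zero-centering, selection of the 30
  accelerometer + gyroscope channels, left/right sensor swapping for
  left-hemiparesis participants, linear interpolation of variable-length
  segments to a fixed length, and sliding windows that yield exactly 20
  windows per segment (ROM task: length 1000, window 200, stride 42; ADL
  task: 3700 / 740 / 150) — so every (participant, class) pair contributes
  equally many training examples;
- **movement asymmetry**: the side-energy score
  `S_asym = ln((E_R + ε) / (E_L + ε))` with `ε = 0.001`, where `E_R` and
  `E_L` are the mean per-channel mean-square energies of the zero-centered
  right- and left-side channels (12 per side); its absolute value (AAS)
  ranks movement types as unimanual ≫ bimanual-asymmetric >
  bimanual-symmetric;
- **axis-rotation augmentation**: each sensor's x/y/z vector time series
  rotated by a uniform angle in (−90°, +90°) about a uniformly random
  axis, doubling the training set;
- a **1D-CNN classifier** (NumPy implementation with reverse-mode
  gradients): four valid convolutions, kernel 5, stride 2, features
  32/64/128/256 (feature lengths 200→98→47→22→9 for ROM, 740→368→182→89→43
  for ADL), dense layers 800/200/K with dropout 0.7, trained with AdamW
  (lr 0.001, betas (0.9, 0.999), eps 1e−8, weight decay 0.01) on
  cross-entropy;
- **evaluation**: three training conditions — non-disabled (ND) only,
  stroke only, and joint ND+stroke — with leave-one-subject-out
  cross-validation over stroke participants, per-(participant, class) F1,
  movement-type and group summaries, and row-normalized confusion
  matrices.

A synthetic-data generator reproduces the statistical structure the
analysis relies on (class-specific oscillatory templates, mirrored left/
right execution, movement-type-dependent energy asymmetry, stroke-side
distortion, realistic duration spread), so the entire pipeline is testable
with no data download.

## Worked example

Score movement asymmetry on a generated dataset (`analysis/02_asymmetry.py`):

```
216 segments scored; AAS by movement type:
movement_type  mean_aas  sd_aas  n
          BIA     0.583   0.039  6
          BIS     0.224   0.010  6
          UNI     4.002   0.052  6
ordering UNI > BIA > BIS holds
```

Unimanual movements put nearly all signal energy on one side (mean AAS
≈ 4.0, i.e. an energy ratio of e⁴ ≈ 55 after the sensor-noise floor),
bimanual-asymmetric movements are mildly lateralized (0.58), and
bimanual-symmetric ones nearly balanced (0.22).

Compare training conditions at desk scale (`analysis/04_train_conditions.py`,
one seed; held-out stroke participants evaluated under random test-time
sensor rotations):

```
condition  augmented  stroke_macro_f1
   stroke      False             0.18
    joint      False             0.69
joint_aug       True             0.67

joint-condition F1 by movement type (stroke group):
 group movement_type  mean_f1  sd_f1
Stroke           BIA    0.645  0.194
Stroke           BIS    0.701  0.229
Stroke           UNI    0.724  0.163
```

Joint ND+stroke training greatly outperforms training on the sparse
stroke data alone (+0.51 macro F1 here), and symmetric (BIS) movements
are classified better than asymmetric (BIA) ones in the stroke group —
the distorted affected limb carries the discriminative signal in
asymmetric movements. Single-seed augmentation margins fluctuate; the
three-seed average (see below) is the stable comparison.

The numbered scripts under `analysis/` are thin drivers over the library
(`imuhar.*`) and write their tables to `results/`.

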