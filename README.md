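# insolegait

Gait-type classification from smart-insole sensor arrays: rule-based
unit-step segmentation with swing-phase artifact cleaning, step-length
normalization, and single-/multi-modal 1-D convolutional networks that
distinguish seven gait types — walking, fast walking, running, stair
climbing, stair descending, hill climbing and hill descending.

The package is aimed at researchers in human-movement analysis and
wearable sensing who need a reproducible pipeline from raw insole
time series (plantar pressure quantized to {0, 1, 2}, 3-axis
acceleration and gyro per foot, 100 Hz) to a trained classifier, plus a
synthetic-recording generator with exact ground-truth step boundaries
for validating every stage.

## Method

**Segmentation.** The gait cycle alternates stance and swing. A left-foot
*swing start* is the frame at which the sum of the 8 left-foot pressure
sensors becomes 0; the following *stance start* is the first frame where
≥ 2 sensors are non-zero. A *unit step* spans one swing start to the end
of the following stance phase. Frames inside a swing whose left-foot sum
is exactly 1 are single-sensor artifacts and are zeroed — uncorrected,
they split one swing into two and double-count steps.

**Normalization.** Each step is resampled channel-wise to *t* = 63
frames (linear interpolation; pressure re-quantized to {0, 1, 2}),
removing walking-speed variation. A normalized step flattens time-major
to vectors of 63·16 = 1008 (pressure) and 63·6 = 378 (accel, gyro);
*k* consecutive steps stack into a (63·k) × W classifier input.

**Classifier.** Per sensor array: three valid conv layers (32/64/128
filters, height 20, first-layer filter spanning the full width W, stride
1 for k ≤ 2 and 2 for k ≥ 3), ReLU then batch normalization, flatten,
two fully connected hidden layers, dropout 0.5, softmax over 7 classes;
Adam at 1e-4 on categorical cross-entropy, batch size 32. A multi-modal
classifier concatenates the flattened conv features of independently
trained single-modal networks (stacks frozen) under a fresh fully
connected head. The network engine is a self-contained numpy
implementation — no deep-learning framework required.

**Evaluation.** Repeated random subsampling (disjoint 1000/1000 draws,
20×) and 7-fold cross validation (10×), stratified, with feature
standardization refit on the training portion of every split.

## Worked example

```sh
python examples/01_segment_and_clean.py
```

```
recording: 1195 frames, label = walking
swing artifacts cleaned: 34
unit steps recovered: 12 (simulated: 12)
boundaries match ground truth exactly: True
step lengths (frames): min 92, mean 99.2, max 111
```

A simulated 12-step walking recording carries 34 injected swing-phase
artifact frames; after the sum-1 cleaning rule, segmentation recovers
all 12 step intervals exactly. `examples/02_normalize_and_assemble.py`
shows the 63-frame normalization and the 1008/378/378 flattening;
`examples/03_train_multimodal.py` trains the classifiers on a small
synthetic dataset (60 one-step samples per class):

```
single-modal pressure: test accuracy 0.886 (loss 2.044 -> 0.404)
single-modal accel   : test accuracy 0.986 (loss 2.075 -> 0.250)
single-modal gyro    : test accuracy 0.993 (loss 2.013 -> 0.266)
tri-modal fusion     : test accuracy 1.000
```

Fusing the three frozen feature extractors matches or beats the best
single sensor array, the expected benefit of multi-sensor fusion.

## Command line

```sh
insole-gait simulate --n-per-class 10 --steps 30 --seed 1 --out data/
insole-gait preprocess --input-dir data/ --k 1 --t 63 --out prep/
insole-gait train-eval --samples prep/samples.csv \
    --modalities pressure,accel,gyro --protocol kfold --folds 7 --out run/
insole-gait report --results-dir run/
```

Every output directory contains a `manifest.json` with the resolved
configuration, its hash, the seed and the package version.

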