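# Methods

## Problem and pipeline

`stressrp` classifies short (10 s / 30 s) windows of three autonomic
channels — foot galvanic skin response (FGSR), hand galvanic skin response
(HGSR) and heart rate (HR) — as *stressed* or *relaxed*. Each window
channel is rendered as a **continuous recurrence plot** (Cont-RP): the
unthresholded matrix of pairwise Euclidean distances between (optionally
delay-embedded) samples, min-max scaled to [0, 1] and bilinear-resized to a
square grayscale image. A three-branch convolutional network learns
channel-specific features from these images and fuses them for the binary
decision. Evaluation is leave-one-recording-out (LORO) cross-validation:
every fold holds out one whole recording, so the test subject/session never
influences training, including class rebalancing, which is applied to the
training split only.

## Synthetic cohort

Real stress-monitoring recordings of this kind are not publicly
distributable, so the package ships a seeded generator whose output has the
statistical structure the classifier exploits:

* **GSR channels** — tonic level (`gsr_tonic_base`, default 5 a.u.) with an
  additive stress shift (+3 a.u.), plus phasic skin-conductance responses
  (SCRs): Poisson-arrival events with exponential rise (1.5 s) / decay
  (4 s), amplitude ~ Exp(mean 1.0). Event rates are 1/min relaxed vs
  12/min stressed, inside the range reported for nonspecific SCRs at rest
  versus sympathetic arousal. Hand and foot sites share a fraction
  `hand_foot_correlation` (default 0.7) of events.
* **HR channel** — baseline 70 bpm, +15 bpm under stress, with AR(1)
  variability (decorrelation ~2 s) whose stationary SD is 6 bpm relaxed vs
  2 bpm stressed (reduced variability under load).
* Gaussian sensor noise (SD 0.02 a.u. GSR, 0.3 bpm HR) is added last.

Defaults: 16 Hz sampling, 600 s recordings, alternating 60 s episodes,
nine recordings per cohort (odd-indexed recordings start in the stressed
state so episode phase is not confounded with recording identity).

A design point worth stating explicitly: recurrence-plot distances are
invariant to the signal's mean, and the per-window image min-max scaling
also removes overall amplitude. Level effects (tonic GSR shift, HR baseline
shift) are therefore *invisible by construction* to the Cont-RP channel of
the pipeline — only texture survives (event rate and shape, smoothness,
variability). The generator consequently places the strong class contrast
in those texture properties, while the level shifts are kept because the
classical feature baselines (and any future non-RP front end) do see them.
This is also what the generator does **not** emulate: real ECG/PPG
waveform morphology, respiration coupling, motion artifacts, electrode
drift, or inter-subject physiological diversity. Passing tests show the
pipeline recovers a strong, known texture effect under clean conditions;
they do not certify field performance on real recordings.

## Recurrence images

Defaults: embedding dimension m = 1, delay τ = 1 (a 30 s window at 16 Hz
has 480 samples; higher-dimensional embedding shrinks the matrix and adds
free parameters the data cannot pin down), image size 64×64, polarity
"larger distance = brighter". All are configurable. Input windows are
min-max normalized per window before the distance matrix; together with the
image scaling this makes the rendering invariant to affine rescaling of
the channel, which is the intended behavior for sensors with arbitrary
gain.

## Architecture

Each branch has five convolution blocks with (2, 2, 3, 3, 3) convolution
layers — 13 in total — all 3×3 stride 1 with ReLU, each block ending in
2×2 stride-2 max pooling. Per-block channel counts are (16, 32, 64, 128,
256); global average pooling over the final 256-channel map yields the
256-dim branch vector, so the branch output dimension is exact for any
input size divisible by 2⁵. The three branch vectors concatenate to a
768-dim fused representation, followed by one hidden dense layer (width
128, ReLU) and a 2-unit softmax. Variants: a single-branch unimodal model
per channel; a 1-D variant with the same block layout (kernel 3, pool 2)
over raw normalized sequences; and a frozen-branch baseline whose
convolution weights stay at their seeded random initialization while only
the fusion head trains (the "fixed generic features" control).

The networks are implemented directly in NumPy (im2col + GEMM convolution
with explicit backprop, float32 throughout). This keeps the package
dependency-light and makes training bit-reproducible for a fixed seed and
BLAS thread configuration.

## Training and evaluation

Plain SGD on two-class cross-entropy; defaults: learning rate 0.001, batch
size 4, 15 epochs. Weight initialization is He-scaled and seeded at build
time; shuffling is seeded by the train config; an experiment master seed
fans out deterministically (via seed sequences keyed on stage, fold and
model tag) to simulation, balancing, initialization and shuffling.

Metrics are computed on the percentage scale as accuracy, precision,
recall and F1 from the stressed-positive confusion counts, with
zero-denominator cases defined as 0; AUC is the Mann–Whitney statistic
with ties credited ½. Per-class precision/recall/F1 are reported by taking
each class in turn as positive. Pooled metrics micro-average the summed
fold counts; pooled AUC is computed over the concatenated test scores.
Grid search enumerates a coarse default grid (learning-rate decades 0.1 …
1e-5, batch sizes {1, 2, 4, 8, 16, 20}, epochs {5, 10, 15, 20, 30}) in
lexicographic order with first-wins tie-breaking; the exhaustive 1–20 ×
1–30 grid is available via `GridSearchSpace.full()` but is not the
default, and the default experiment uses the fixed operating point above
rather than searching.

### Problem sizes

The shipped acceptance experiment (scripts/acceptance.py and the
end-to-end test) uses the default nine-recording cohort: 20 non-overlapping
30 s windows per recording (180 total, 160 training windows per fold after
undersampling — the default cohort is balanced by construction). At this
cohort size a full 15-epoch schedule is more optimization than the task
needs; the experiment trains the multimodal model for 5 epochs and the
unimodal baselines for 4, which is where held-out accuracy plateaus on
this generator, and reports pooled LORO metrics. Classical baselines
(XGBoost, random forest, SVM, logistic regression) consume the documented
per-channel time-domain feature vectors (13 statistics × 3 channels).

## Numerical conventions and edge cases

* Min-max normalization of a constant series is defined as all zeros, and
  a constant distance matrix renders as an all-black image.
* Skewness/kurtosis of a zero-variance window are defined as 0; a peak is
  a strict local maximum; the successive-difference feature is the mean
  *absolute* successive difference (the signed mean telescopes to
  (x_N − x_1)/(N − 1) and is uninformative).
* Label intervals are half-open [start, end) in seconds; windows must lie
  entirely inside one interval or they are dropped; default window stride
  equals the window length (non-overlapping).
* Undersampling draws without replacement from the majority class only;
  oversampling duplicates existing windows with replacement; neither ever
  synthesizes values (interpolation-style augmentation is deliberately out
  of scope).
* Resampling is linear interpolation onto the output time grid with
  length round(n · fs_out / fs_in).

## Known limitations

* The NumPy training loop is single-device and unbatched beyond BLAS; it
  is sized for cohorts of hundreds of windows, not thousands.
* The frozen-branch baseline uses seeded random weights; no pretrained
  weights are bundled, and requesting them raises an explicit error.
* AUC is undefined for single-class test folds; such folds report
  accuracy/precision/recall only (the default generator always yields
  both classes per recording).
* With m > 1 embeddings the distance matrix shrinks by (m−1)·τ rows; the
  rendered image size is unchanged but very short windows can become
  unembeddable, which is reported as a validation error.
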