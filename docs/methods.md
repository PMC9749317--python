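# Methods

## Problem

Patients with ventricular premature complexes (VPC) often present with
ordinary sinus-rhythm ECGs; a classifier that flags VPC-prone patients
from a plain 12-lead printout would make screening cheap. The raw
material in that setting is usually a *printed* ECG — a red-grid raster
with a 3x4 lead panel and a long-lead-II rhythm strip — not a digital
signal, so the pipeline has two halves: (1) digitize the printout into a
1250 x 12 sample tensor (2.5 s per lead at 500 Hz), and (2) classify
either the image or the recovered time series with a CNN, evaluated under
a patient-disjoint protocol.

## Digitization

The printout model: four vertical sub-images (time quarters) of 250 pixel
columns each; every column crosses four traces (three leads plus the
rhythm strip). Stages and choices:

1. **Grid removal.** A pixel is grid if `R - max(G, B) > 30`. A
   red-dominance predicate rather than exact color matching tolerates
   anti-aliased or faded grids while never touching near-black ink. The
   remainder is converted to grayscale with standard luma weights
   (0.299, 0.587, 0.114). The operation is idempotent.
2. **Crop.** Tight bounding box of non-background pixels (+ optional
   margin); the crop offset is carried along so layout coordinates stay
   meaningful.
3. **Binarize/invert.** Ink (gray < 128) becomes foreground 255. After
   grid removal the trace is near-black on white, so the threshold is not
   delicate.
4. **Sub-image split.** Fixed quarter boundaries when the layout is
   known; otherwise the deepest ink-density valleys near the quarter
   marks.
5. **Column scan + grouping.** Each column's foreground rows are split
   into runs (a gap > 3 px starts a new run: pen strokes are vertically
   connected). Each run's pixel-weighted centroid is assigned to the
   nearest trace reference — the trace's previously assigned row
   (tracking) falling back to its static baseline — with ties going to
   the upper trace. Tracking lets a large excursion that invades a
   neighbouring band stay with its own trace. The centroid, not the
   topmost pixel, is the sample value, making the estimate symmetric in
   line thickness.
6. **Assembly.** Amplitude = baseline row − assigned row (up is
   positive). Interior gaps are filled by linear interpolation, edge gaps
   hold the nearest value; a lead missing in more than half its columns
   is an error, not a guess. The rhythm strip is extracted but kept out
   of the 12-lead tensor.
7. **Conditioning.** 250 columns are linearly up-sampled to 1250 points,
   low-pass filtered (Butterworth, cutoff 15 Hz, order 3 — Butterworth
   because a maximally flat passband leaves the retained morphology
   untouched), and min-max normalized per lead to [0, 1] (a constant lead
   maps to 0.5). The filter runs forward and backward by default (zero
   phase, squared magnitude): morphology alignment matters for
   classification, phase does not. Edge transients are controlled by
   reflect-padding of one signal length. Filtering precedes
   normalization; up-sampling precedes filtering.

## Classifier families

* **Image model:** backbone → global average pooling → dense(512, ReLU)
  → dropout 0.5 → dense(2, softmax). The backbone registry exposes TINY
  (a 4x average pool followed by three 3x3-conv/batch-norm/ReLU/2x2-pool
  stages) and a plain-conv VGG16 stack; both are built on the package's
  own NumPy engine (see below). TINY exists because a ~24k-parameter
  backbone is what CPU-scale experiments and tests can actually train.
* **Single-input 1-D model:** conv blocks (1-D conv stride 3 → batch
  norm → ReLU → max pool size 5 stride 3) over the 1250 x 12 tensor, then
  GAP → dropout 0.5 → dense(2).
* **Multi-input 1-D model:** twelve weight-independent copies of the
  block stack, one per lead (1250 x 1), GAP features concatenated and fed
  directly to dense(2) — no dropout in this head. Branch weights are
  deliberately independent (merging shared features is the head's job).

Block-stack depth: with stride-3 convs and stride-3 pools each full block
shrinks the sequence about nine-fold, so from 1250 samples only two
pooled blocks plus one unpooled block fit. The default stack is three
blocks with filters (32, 64, 128), pooling on the first two; the
`tiny_ts_spec` used in tests keeps two pooled blocks (16, 32). Kernel
sizes {3, 5, 7, 9, 11} are the canonical sweep grid; anything else builds
with a warning. A 1-D residual variant (conv-BN path plus a 1x1 strided
projection) is available behind the `residual` flag.

All convolutions and pools use valid (no) padding, so output lengths obey
`floor((L - k)/s) + 1` exactly — this closed form is tested against the
built models.

## The NumPy engine

No deep-learning framework is part of the dependency set; the layers the
families need (Conv1D/Conv2D, BatchNorm, ReLU, max/average pooling, GAP,
Dense, Dropout) are implemented directly in NumPy with explicit
forward/backward passes, softmax cross-entropy, and Adam (eps 1e-7).
Convolution uses stride-tricks windows plus einsum; backward scatters
through strided slices. All randomness (weight init, dropout, shuffling)
flows through explicit `numpy.random.Generator` seeds, making training
bit-reproducible in single-threaded NumPy. The engine is sized for the
small architectures above, not for ImageNet-scale backbones; the
registry's Inception/ResNet/Xception names therefore raise a clear error
instead of building.

## Training and evaluation protocol

Defaults: Adam at learning rate 0.0011, categorical cross-entropy, batch
32, up to 400 epochs, early stopping on validation loss with patience 250
and best-state restoration (batch-norm running statistics are restored
with the weights). Experiments in this repository use far smaller epoch
budgets (a dozen to a few dozen) because the synthetic cohorts are
strongly separable and the models converge quickly; the defaults remain
the protocol values.

**Split.** Validation (50 records) and test (100 records) are filled by
whole patients via randomized first-fit over patient permutations,
retried until the record counts land exactly; everything else trains.
Patient disjointness is guaranteed by construction, determinism by the
seed.

**Evaluation.** ROC and AUC via scikit-learn; the operating point
maximizes Youden's J (ties resolved toward higher specificity; a record
is positive when its score ≥ threshold). Accuracy, sensitivity,
specificity, PPV and NPV are computed at that point (empty denominators
yield 0.0). 95% CIs are percentile bootstrap over 2000 class-stratified
resamples with the threshold held fixed — re-optimizing the cut-point
inside each resample would bias the intervals optimistically. In
degenerate tiny resamples a percentile interval can exclude the point
estimate; reported intervals are widened to contain it.

## Synthetic data: what it does and does not show

Waveforms are P-QRS-T Gaussian-deflection trains scaled by a fixed
per-lead polarity/amplitude table, with optional baseline wander
(0.2–0.6 Hz sinusoid) and white noise. The VPC class applies a smooth,
deterministic perturbation — a low-frequency hump 100 ms after the R peak
and a 25%-per-unit-effect QRS widening — scaled by `class_effect_size`
(default 1.0, a deliberately large effect so end-to-end learnability is
a pipeline test, not a statistical-power test). With effect size 0 the
class generators are identical, which the suite verifies with a
permutation test.

Cohorts draw waveform parameters once per patient (heart rate 55–95 bpm,
amplitude ranges around the template defaults, noise SD 0.015–0.03,
wander 0.02–0.08) and re-draw only noise per record, emulating multiple
printouts per patient; class labels are allocated deterministically at
the requested balance.

What passing therefore shows: the digitizer recovers rendered waveforms
nearly losslessly; the models can learn a morphology difference through
the full image path; the protocol never leaks patients. What it does not
show: performance on real scanned ECGs (no skew, perspective, ink
fading, or lead-label OCR — all out of scope) or on the subtle real-world
VPC signature, whose effect size nobody knows.

## Numerical details and edge policies

* Rendering quantizes amplitudes to pixel rows (25 px per unit); pen
  strokes connect consecutive samples with a midpoint-split convention so
  the per-column centroid stays close to the true row. Excursions beyond
  a trace's band are clipped and flagged.
* `upsample` refuses to downsample; endpoints are preserved exactly.
* Min–max normalization is affine-invariant and idempotent; constant
  leads map to 0.5.
* The digitize chain re-raises stage failures with the stage name
  attached.
* Problem sizes in the checked experiments: 50 rendered records for
  round-trip fidelity, 10,000 random rosters for split safety, and a
  700-patient (one record each) cohort for end-to-end learnability of
  all three families — sizes chosen so the whole suite runs comfortably
  on one CPU core.

## Known limitations

* The renderer is an emulation of a printout, not a reconstruction of
  any vendor's exact geometry or calibration pulse.
* Trace overlap handling relies on tracking; pathological crossings
  (two traces riding each other for many columns) will corrupt both.
* The rhythm strip is digitized but unused by the classifiers.
* ImageNet-scale backbones and pretrained weights are out of reach of
  the CPU engine; TINY results say nothing about what a large pretrained
  backbone would achieve on real data.
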