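# Methods

## Model

The recognizer is modular. The **short-term (ST) module** is a 3D
convolutional encoder `f: (W, H, TS, C) -> R^D` over 8-frame volumes.
Two heads share it:

* *Supervised (ST model 2)*: a fully connected layer with softmax over the
  G task gestures; the volume label is the argmax (ties broken by lowest
  index everywhere in the package).
* *Self-supervised (ST model 1)*: a decoder of six transposed 2D
  convolutions that upsample a linear projection of the embedding back to
  (W, H); every layer but the last applies ReLU then batch normalisation,
  the last a sigmoid, so predictions live in (0, 1). The training target is
  the frame immediately following the volume (next-frame pretext task, MSE
  loss), which requires no annotations. Pixels are kept in [0, 1]
  throughout the package so the sigmoid output is on the target scale. The
  predicted next frame is full RGB; the alternative (grayscale target) is a
  known open choice.

The **long-term (LT) module** projects each of a clip's NS = 8 volume
embeddings to `d_model`, applies three transformer blocks and classifies
from the flattened token matrix with a one-hidden-layer MLP softmax head.
Attention is single-head scaled dot-product *self*-attention,
`A = softmax(QKᵀ/√d_k) V`, with Q, K, V projected from the same tokens and
`d_k = d_model` (required by the residual). Block wiring is post-norm:
`LN(t + FFN(LN(t + Attn(t))))`. No positional encoding is added; the block
stack is therefore permutation-equivariant and order information enters
only through the flatten — a property the tests assert explicitly. We use
√d_k in the attention denominator, the standard scaled form.

### Encoders

* `inception3d_reference`: an Inception-style 3D network (7×7×7 stem,
  channel-concatenated mixing blocks with 1×1×1 and 3×3×3 towers, average
  pooling between stages) ending in a 1×1×1 convolution and global average
  pooling to a 1024-d embedding at 224×224×8 input. Pretrained weights are
  optional and loaded from an `.npz` matching the package's parameter
  names; no download is required anywhere.
* `tiny`: four conv3d+ReLU blocks (spatial stride 2 each; temporal extent
  8→1) with global average pooling to 64 dimensions. It accepts any
  spatial size that is a multiple of 8 and is the workhorse for CPU-scale
  experiments.

### Training protocol

Training is two-phase for both ST models: a warm-up in which only the head
(decoder or FC) is optimised while the encoder is bitwise frozen, then
end-to-end fine-tuning; the LT model is trained separately on frozen
embeddings (cross-entropy). All phases use Adam. The reference defaults —
15 warm-up epochs at lr 1e-4, 30 fine-tune epochs at lr 1e-5, 30 LT epochs
at lr 1e-5, batch size 10 — are the `TrainConfig` defaults. The desk-scale
schedule actually used on the synthetic benchmark (`experiments.
desk_schedule`) is 2 warm-up + 10 fine-tune epochs at lr 1e-3 and 25 LT
epochs at lr 3e-4: the tiny encoder trains from scratch on small images,
where the reference rates are needlessly conservative. Epoch counts and
rates are configurable everywhere.

## Numerical engine

No deep-learning framework is used: `surgest.nn` is a small float32 layer
library (conv3d via im2col+GEMM, stride-matched transposed conv, batch/
layer norm, single-head attention) with hand-derived backward passes and a
plain Adam. Every layer's gradient is validated against central finite
differences of a random linear functional, and the attention forward pass
against an explicit double-loop oracle. Because everything is numpy,
seeded runs are bitwise reproducible on a given machine; the only
train/eval asymmetry is batch normalisation, which uses batch statistics
in training and running averages at inference (momentum 0.1, eps 1e-5).
A consequence worth noting: with learning rate 0 the *parameters* are
exactly unchanged, but decoder losses can still vary across epochs because
train-mode batch-norm statistics follow the shuffled batch composition.

## Synthetic data

The generator emulates the structure of annotated box-trainer recordings:
trials follow a fixed gesture grammar (10 elements over 5 classes for the
peg-transfer-like task; 4 over 4 for the knot-tying-like task), each
gesture instance draws its duration uniformly from 15–45 frames (roughly
the 3–24 s annotated range at 5 fps, scaled for desk runtime), and every
class is a motion primitive — directed sweeps, a circular orbit, vertical/
horizontal oscillation, grow–shrink pulsation — applied to an identical
bright disc on a dark background with additive Gaussian pixel noise
(σ = 0.02, clipped to [0, 1]). Default frames are 64×64 (224×224 is
supported for reference-config parity). Transcripts tile each trial
exactly and are emitted in the package's CSV format (subsampled timeline,
0-based, half-open intervals). A dedicated `make_motion_only_pair` task
renders one class as a left-to-right sweep and the second as the *same
frames in reverse order*, so no single frame carries class information.

What passing on this data shows — and does not. The generator provides
temporal-only class structure, exact labels and stationary appearance; it
has none of the photometric variability, occlusions, annotation noise or
inter-subject variation of real laparoscopic video. Results on it validate
the machinery (decomposition, training dynamics, temporal feature capture,
evaluation protocol), not clinical performance.

## Experiments (desk-scale study conditions)

`surgest.experiments` fixes the problem sizes used by the acceptance
script and end-to-end tests, chosen once for single-CPU runtimes:

* *Label recovery*: 20 trials, 64×64, 5 classes; trial-disjoint 5-fold
  split with one fold held out; tiny C3DTrans; training thinned to every
  2nd clip and every 4th volume per clip (the heavy overlap makes
  neighbouring samples near-duplicates, so thinning trades little
  information for a large speedup).
* *Motion-only pair*: 8 trials, 32×32; C3Dargmx vs a logistic-regression
  baseline on each clip's centre frame.
* *Annotation-budget robustness*: 8 trials, 32×32; budgets 100% vs 60% of
  annotated segments (segment-level seeded subsampling, mimicking partial
  annotation); three model seeds on a fixed split. The self-supervised
  encoder is trained once per seed on all video — by construction the
  budget touches only its transformer — while the supervised encoder is
  retrained per budget.

## Design choices where the design was open

* Coordinates are 0-based frame indices with half-open intervals on the
  subsampled timeline; subsampling always starts at raw index 0.
* Labeled clips restart at each annotated segment's start and never cross
  segment boundaries; segments shorter than TL yield nothing (logged, and
  counted during gesture-level evaluation).
* The annotation budget subsamples *segments*, not clips, with a seeded
  draw, and rounds to the nearest count (minimum 1).
* Gesture-level prediction tiles the interval from its start at step
  TL·(1−0.8) = 3 and discards a trailing partial window; summed clip
  probabilities are renormalised (argmax-invariant).
* Online per-frame prediction back-fills the first TL−1 frames with the
  first window's label so the output covers the whole trial.
* F1 is macro-averaged; classes absent from both truth and prediction in a
  fold are excluded (and logged).
* The decoder seed map and stride plan for non-reference sizes factor the
  output size into at most five 2× upsamplings plus an integer seed size.

## Limitations

* The reference encoder is Inception-*style*; it does not reproduce the
  exact published Inception-v1 channel plan, and pooling uses average
  pooling (also in mixing-block branches), so third-party pretrained
  weights cannot be loaded unchanged.
* Training is CPU-bound numpy: fine for the synthetic benchmark, far too
  slow for real 224×224 video corpora.
* Bitwise determinism is guaranteed within one BLAS configuration; across
  different BLAS builds or thread counts, floating-point reduction order
  may differ.
* No temporal smoothing or segmentation post-processing is applied to the
  per-frame output; the package evaluates classification only.
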