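# Methods

## Problem and model

The task is two-class semantic segmentation of breast-ultrasound (BUS)
images: every pixel is assigned a label from φ = {0 background,
1 lesion}, and the network output has the same spatial size as its
input. Three encoder–decoder architectures are compared. CNN1 is a
series network — one path from input to output:

```
(Conv64–BN–ReLU ×2 – MaxPool 2×2/s2) ×3
Conv64–BN–ReLU ×2                          # bottleneck (side/8)
Deconv64–BN–ReLU – Conv64–BN–ReLU – Dropout(0.5)
(Deconv64–BN–ReLU – Conv64–BN–ReLU) ×2
MaxPool 2×2/s1 (same)                      # size-preserving
Conv2(1×1)–BN–ReLU – Softmax – PixelClassification
```

All 3×3 convolutions use stride 1, padding 1; deconvolutions
(transposed convolutions) use 4×4 kernels with padding (4−s)/2 so a
stride-s deconv multiplies the spatial size exactly by s. Weights are
initialized N(0, 0.01²), biases zero, batch-norm scale 1/offset 0. A
160×160 input is reduced to 20×20 at the bottleneck and restored by the
decoder.

CNN2 and CNN3 are DAG variants of the same main path. CNN2 taps the
first encoder module after its second ReLU (full resolution) and
reduces it through two MaxPool–Conv–BN–ReLU stages to the resolution of
the first deconv output, where it is depth-concatenated into the
decoder. CNN3 extends CNN2 with three more skip paths, one per encoder
module (tapped after each module's second ReLU), brought to full
resolution — identity for the first, a single stride-2 Deconv–BN–ReLU
for the second, a single stride-4 Deconv–BN–ReLU for the third — and
depth-concatenated immediately before the 1×1 classification conv.
Processing-layer totals (the data input layer is not counted) are 52,
61 and 68.

Design choices where the architecture description left room:

- **Final pool is size-preserving** (2×2, stride 1, same padding): a
  stride-2 pool at that position would halve the output and contradict
  the same-size pixel-labeling contract.
- **Aggregation is depth concatenation**, with the following conv
  absorbing the widened channel count. Concatenation preserves both
  information streams; it is isolated in the graph builder so an
  additive merge could be swapped in.
- **CNN3 contains CNN2's skip** and uses one deconv per skip branch
  regardless of the up-sampling factor (stride 2 or 4). Among the
  compositions consistent with the stated tap points, this is the one
  whose realized layer totals are 61 and 68.
- **The conv-layer count**: the main path as enumerated contains twelve
  convolutional layers (the 1×1 head included), which is what the
  52-layer total requires.

## Numerical engine

No GPU framework is used: the graphs are interpreted by a NumPy engine
with explicit forward and backward passes. Convolutions are lowered to
im2col + matrix multiplication (BLAS); the transposed convolution and
the input-gradient of a convolution are the same operation, implemented
by zero-stuffing by the stride and correlating with the spatially
flipped, channel-transposed kernel. Max-pool backward routes gradients
to the per-window argmax (first index on exact ties). Batch-norm uses
batch statistics during training (ε = 1e−5), exponentially updated
running statistics (momentum 0.1) at inference, so prediction is
deterministic; dropout (ratio 0.5) is inverted and disabled at
inference. The softmax and the multinomial logistic loss are fused: the
gradient at the softmax input is (p − onehot)/N over the pixel count.
Backprop was validated against central finite differences (step 1e−6,
float64) to ~1e−9 relative error away from ReLU/argmax kinks.

Parameters default to float32 for speed; float64 is available for
gradient checks. `predict_mask` takes the per-pixel argmax of the two
softmax channels and resolves exact ties to background.

## Training protocol

SGDM in its two-point form,
θ_{l+1} = θ_l − α∇E(θ_l) + γ(θ_l − θ_{l−1}), with α = 0.001, γ = 0.9,
batch size 5, a fixed stop at 150 epochs, no schedule and no early
stopping; the first step uses θ_{l−1} = θ_l, reducing it to a plain
gradient step.

Splitting is stratified 60/20/20: validation and test each take
round(0.2 n) items (the unique simple rule giving 233/77/77 at n = 387
and 97/33/33 at n = 163), the remainder trains; per-class allocation
uses largest-remainder rounding, keeping every class within one item of
its global proportion in every subset. After model selection the train
and test pools are merged and evaluated by stratified 5-fold
cross-validation; mini-batch order is reshuffled each epoch with a seed
derived from the run seed, so identical seeds give identical traces.

## Metrics

From per-pixel confusion counts (lesion = positive): global accuracy
(TP+TN)/total; mean accuracy (lesion recall + background recall)/2;
per-class IoU TP/(TP+FN+FP) and TN/(TN+FN+FP); mean IoU; weighted IoU
with class weights taken from the gold mask — not the prediction — so
the two weights always sum to 1; Dice 2TP/(2TP+FN+FP); and the BF
score, the harmonic mean 2PR/(P+R) of boundary precision and recall.
Boundaries use 4-connectivity with the image border
counting as background; the default match tolerance is
ceil(0.0075 × image diagonal). Metrics whose denominator class is empty
are reported as NaN (flagged missing), never silently 0 or 1, and are
skipped by set-level means; set summaries are per-image means and
sample standard deviations (not pixel-pooled — the aggregation
convention is stated in the report header because the alternative is
equally defensible). The error overlay paints FP pink, FN green, TP
white, TN black.

## Synthetic phantoms

Clinical BUS collections with expert contours are generally private, so
the end-to-end tests run on a seeded simulator that reproduces the two
properties the method depends on:

- **Morphology.** A lesion is a star-convex region with radial contour
  r(θ) = base radius + harmonic perturbations (+ spicules). Benign:
  order-2/3 harmonics capped at 0.08·r₀ — smooth, near-elliptical.
  Malignant: order-3/5/7 harmonics plus 4–8 narrow Gaussian radial
  spikes (width 0.06–0.14 rad, height 0.35–0.6·r₀) — spiculated,
  angulated. Over seeded pairs the mean mask solidity (area/convex-hull
  area) of benign exceeds malignant by ≥ 0.05, which is the separation
  the DAG-vs-series question needs.
- **Echotexture.** The image is a two-level echogenicity map (lesion =
  contrast × background, contrast drawn from 0.35–0.60 so lesions are
  hypoechoic), modulated by a slowly varying texture field, multiplied
  by unit-mean gamma speckle (shape 1/s², the fully-developed-speckle
  approximation, s = 0.3 by default), blurred (σ = 1 px) and clipped to
  [0, 1]. With s = 0 the output is exactly the two-level map, the
  noise-free limit used by tests.

Per-item seeds are derived from the master seed with a SplitMix64-style
mix, so item i is reproducible regardless of generation order. The
default class mix 179:208 malignant:benign mirrors a typical clinical
collection. Lesion size (base radius 0.13–0.24 of the image side) and
contrast ranges are the package's own choices — no quantitative size or
contrast statistics are available for the clinical collections the
generator emulates — and are exposed as configuration.

What the phantoms do **not** model: attenuation and acoustic shadowing,
ribs/pectoral muscle and other anatomy, scanner-dependent point-spread
anisotropy, and operator variability. Passing the end-to-end tests
therefore shows the pipeline can learn and score hypoechoic-lesion
segmentation under speckle; it does not certify clinical performance.

## Model comparison

Architectures are compared on per-image global accuracies (validation)
or per-fold means (cross-validation) with the pooled-variance
two-sample t-test, df = n₁+n₂−2, two-tailed at confidence c: reject
when |t| ≥ t_c, the Student quantile at 1 − (1−c)/2 — e.g. t_c = 4.032
at 99% with df 5, and df = 152 for two 77-image validation sets. The
pooled (not Welch) form is used because the df convention identifies
it. Zero pooled variance yields t = 0 for equal means and a flagged
infinite statistic otherwise. Critical values are computed as exact
Student quantiles rather than read from rounded tables.

## Scaled-down end-to-end study

Full-scale training (width 64, 160×160, 150 epochs) is a multi-hour GPU
job per run and the clinical data are private, so the recovery study
that the acceptance checks and `scripts/acceptance.py` run is scaled to
CPU: CNN3 at width 8 on 48×48 phantoms, 60 training / 20 held-out
images, 12 epochs, batch 5, default optimizer settings, three seeds.
The bar — mean held-out Dice ≥ 0.80, required in at least 2 of 3
seeds — is kept at full strength; typical runs reach 0.88–0.92. The
series/DAG boundary comparison (BF score of CNN1 vs CNN3 at matched
budget) is exploratory and reported, not gated: at this reduced scale
the DAG advantage is usually, but not always, visible.

## Known limitations

- The engine is single-threaded NumPy; it is meant for correctness and
  desk-scale experiments, not production training speed.
- Batch-norm statistics are not frozen between epochs for evaluation;
  inference always uses running statistics.
- The simulator's spicules are radial (star-convex contours); real
  malignant margins can fold back on themselves.
- No data augmentation and no class weighting in the loss, matching the
  protocol being reproduced rather than best practice.
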