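# Methods

## Problem setting

An image-level count annotation is a single nonnegative integer per image:
the number of objects of interest it contains.  `countreg` treats counting
as direct regression from pixels to that integer (predicted as a continuous
scalar), which lets archives annotated only with counts — aerial wildlife
surveys, otolith ring readings — be used as training data without any
per-object annotation.

## Model

The regressor is a convolutional trunk ending in global average pooling,
followed by a two-layer fully-connected head: pooled features → 512 hidden
neurons (ReLU) → 1 output.  The output is raw and unclamped; negative
predictions are possible and are only rounded/clamped by an explicit
reporting option, never inside the model.  The output layer is
zero-initialised, so an untrained model predicts exactly 0 — a useful
baseline contract for tests and for "0-epoch" control runs.

Two backbones ship with the package, both plain NumPy (`countreg.nn`
implements 3×3 same-padding convolution via im2col, ReLU, 2×2 max pooling,
global average pooling, dense layers, reverse-mode gradients and Adam):

| name    | blocks (channels)   | input  | pooled features |
|---------|---------------------|--------|-----------------|
| `tiny`  | 8, 16, 32, 64       | 64×64  | 64              |
| `micro` | 16, 32, 64          | 32×32  | 64              |

`tiny` is the reference configuration: with ~25k trunk parameters it trains
in well under a minute per experiment on one CPU core at 64×64, which is
what makes the end-to-end pipeline (including ten-seed stochastic checks)
routinely testable.  Deeper pretrained backbones would raise accuracy on
real imagery but are out of scope here: no pretrained weights ship with the
package, and `pretrained=True` is rejected with an explanatory error.

The network is partitioned into three learning-rate sections: the trunk is
split at the midpoint of its convolutional blocks (sections 1 and 2), and
the head is section 3.  Phase specifications require section LRs to be
nondecreasing from early to late — the discriminative-LR convention that
protects generic early features while letting the head move fast.

## Loss

The Huber loss with threshold δ = 1 in count units:
quadratic (0.5 r²) for residuals |r| < 1, linear (|r| − 0.5) beyond, averaged
over the batch.  Its gradient per element is bounded by 1/n, so a single
grossly mislabelled or mispredicted image cannot dominate an update — the
property that matters when labels are noisy.  The threshold stays at 1
throughout; the loss helper accepts other thresholds but nothing in the
package changes it.

## Training protocol

Two phases, each with best-epoch checkpointing (minimum validation loss,
validation always un-augmented):

1. **Head phase** — trunk frozen, only the head trains.
2. **Fine-tune phase** — everything unfrozen, discriminative LRs
   (early, geometric-mean middle, head).

Within a phase the LR follows a one-cycle trajectory: cosine warm-up from
`base/start_dampening` to `base × max_lr_multiplier` over the first 30% of
steps (the peak is attained exactly once, at the warm-up boundary), then
cosine annealing to `base/end_dampening`.  Defaults: multiplier 10, start
dampening 10, end dampening 100.

The optimiser is Adam (β₁ = 0.9, β₂ = 0.99, ε = 1e-5) with decoupled weight
decay 1e-2 on weights only; these values are recorded in every run
manifest.  Before the head phase, `run_protocol` sets the (zero) output
bias to the training-label mean: with a bounded Huber gradient the bias
would otherwise spend most of the phase walking from 0 to the label scale.

Preset configurations: the ring-style preset uses a 25-epoch head phase at
LR 5e-2 and a 50-epoch fine-tune at 9e-7…9e-5 with batch size 84; the
dot-style preset uses 50 epochs at 3e-2, then 50 at 3e-4…3e-2, batch 100.
These presets describe full-scale configurations.  The **desk protocol** —
the package's reference for CPU experiments — uses 10 head epochs at 3e-3
and 12 fine-tune epochs at 3e-4…3e-3, batch 50, with flip + mild lighting
augmentation.  Its epoch counts and LRs were chosen on validation loss for
the tiny backbone trained from random initialisation (a from-scratch net
needs a larger LR and fewer epochs than fine-tuning a pretrained one).

## Synthetic data

The generators are pure functions of (spec, count, seed) — bit-identical
across runs — and every image carries its exact ground-truth label plus
provenance metadata (object/distractor masks, scene scale).

**Dot scenes** (aerial-survey style, default 64×64 greyscale, counts 0–30):
anti-aliased ellipses with per-object rotation, elongation (axis ratio
1–1.8) and intensity 0.75–1.0, on a background with smooth texture
(amplitude 0.05) under scene-level multiplicative lighting 0.8–1.2.  The
scene-level object diameter is drawn from 5–11% of image width, emulating
variable camera distance; when overlap is disallowed, crowded scenes cap
the effective diameter so that random sequential placement stays feasible
(~28% coverage), i.e. crowded scenes read as photographed from farther
away.  0–3 distractor marks (smaller, dimmer, strongly elongated — the
"birds" of aerial imagery) are rendered and masked but never counted.
A placement margin of 14% of width keeps all objects clear of the border,
which is what makes ≤10% zoom and small warps label-safe.

**Ring images** (otolith style, default 256×256, counts 1–63): Gaussian
ridge rings at radii `agc + spacing·(i+1)`, strictly outside a smooth
bright accessory-growth-centre disc whose profile is monotone (it
contributes no countable maxima).  Discrete zoom levels emulate microscope
magnifications; a spec whose maximal ring pattern cannot fit inside the
image half-width is rejected at construction.

**Label noise** emulates deduplication across overlapping survey images,
which only ever *removes* counts: with probability 0.7 an image's label
becomes `floor(true × f)`, f ~ Uniform(0.4, 0.95).  The true label is kept
in metadata, and images whose scene scale falls below a configurable
threshold are flagged unidentifiable.  The noise magnitudes are
configurable conventions, not estimates from any survey.

**Recount oracle**: returns the stored true label, or an unidentifiable
signal for flagged images — a deterministic stand-in for the human
re-annotator in the refinement loop.

What the generators do *not* emulate: photorealistic texture, perspective,
object occlusion/overlap (off by default), correlated noise between nearby
images, annotator disagreement.  Passing tests on this data demonstrates
that the machinery (splits, protocol, refinement selection, CAM) behaves as
specified, not that any particular accuracy transfers to real imagery.

## Splits and evaluation

Equal-width label bins over the observed integer range with width
`(max − min + 1)/n_bins`; the maximum label lands in the last bin.  The
stratified test set draws a fixed number per bin uniformly without
replacement; train/validation is a seeded uniform split with
`floor(fraction·n)` training items.  Whether real archives used equal-width
or quantile bins is generally unknowable; equal-width is the reproducible
choice here.

R² is the coefficient of determination 1 − SS_res/SS_tot (SS_tot about the
label mean) — exactly 0 for the constant mean-label predictor, negative for
worse — not squared Pearson correlation, which would hide systematic bias.
Zero label variance flags R² as missing rather than raising.  Totals
accounting reports `100 · Σŷ / Σy` and its complementary underestimate
percentage, the quantity a survey ultimately propagates into population
estimates.  Metrics use raw continuous predictions by default; rounding +
clamping at 0 is an explicit reporting option.

## Two-step refinement

Residuals are computed against the *noisy* label (ŷ − y_noisy): a large
positive residual marks an image whose label likely undercounts — exactly
where relabelling pays.  Records are sorted by residual descending with
ties broken by id, on raw unrounded predictions (rounding would create mass
ties).  Selection walks both tails; an unidentifiable image is discarded
and replaced by the next record in the same tail, preserving the over/under
balance.  If the combined quota covers the pool, the selection is every
identifiable image; a tail that genuinely runs out is an error naming the
tail and shortfall.  Relabelled images join the clean subset with oracle
labels (noisy flag cleared), the merged set is re-split 80/20 uniformly at
random, and the whole network fine-tunes with best-epoch checkpointing.
The loop runs once; iterating it is deliberately out of scope.

## Class-activation maps

The two-layer head breaks the plain-CAM assumption of a single linear
layer over pooled features, so the gradient-weighted variant is used:
channel weights are the spatially averaged gradients of the scalar output
with respect to the last convolutional block's ReLU activations; the
weighted activation sum is rectified (keeping regions that push the count
*up*), bilinearly upsampled to image size, then min–max normalised, so a
non-constant map attains both 0 and 1 exactly.  A constant raw map (e.g.
zero gradients under a zero-initialised head) yields an all-zero map by
convention.  Heatmaps are qualitative: per-object localisation is not
evaluated, and the mask-contrast check (heat inside object masks vs
outside) is a sanity property, not a localisation metric.

## Reference experiments and problem sizes

The desk-scale **counting experiment**: 1200 dot scenes, counts 0–30 with
geometric-decay weights (factor 0.93 — skewed, but leaving every one of the
8 stratified bins fillable with 15 test images at this pool size),
600/150/120 train/validation/test, tiny backbone, desk protocol.  The
desk-scale **refinement experiment**: counts 0–49 (decay 0.95), 1200
images, 10 bins × 6 test images, a 320-image clean subset restricted to
the lower 40% of the count range, the rest as a noisy pool (70% corruption,
retained fraction 0.4–0.95), k_over = k_under = 25, then a 12-epoch
full fine-tune at 3e-4…3e-3.  These sizes are the package's reference
conditions for CPU-scale experimentation; `scripts/acceptance.py` runs both
and reports their metrics.

## Numerical and design notes

- All tensors are float32; runs are single-threaded NumPy and
  bit-deterministic for fixed seeds (identical histories across reruns).
- Max-pool gradients split evenly among tied maxima, keeping the backward
  pass exact rather than argmax-order-dependent.
- Stage seeds derive from one global seed by fixed offsets, so an
  experiment config is a single reproducibility knob.
- Equality at the Huber branch point belongs to the linear branch
  (`|r| < 1` is strict), matching the piecewise definition; both branches
  agree at 0.5 there, so the choice is invisible numerically.
- Bin assignment of the maximum label is closed (clamped into the last
  bin), avoiding an empty overflow bin.
- Datasets are held in memory; PNG + CSV round-trips quantise pixels to
  8 bits (images are rendered in [0, 1]).

## Known limitations

- The NumPy engine targets small inputs; at megapixel scale a GPU framework
  and a pretrained backbone are the right tools, and results here do not
  predict performance there.
- Counts are learned, not computed: a trained regressor can respond to
  distractors or lighting (the CAM distractor probe occasionally shows
  this), which is faithful to the method's real failure modes.
- The refinement loop assumes the oracle is exact; annotator disagreement
  is not modelled.
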