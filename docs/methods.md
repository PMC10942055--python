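# Methods

## Model

The classifier stacks three *texton-dense capsule* levels. Level *l* applies,
in order: a texton selection layer, a densely connected convolution block,
and a convolutional primary-capsule layer. The squashed primary-capsule
activations of level *l*, re-laid-out as an H×W×96 feature map, are the input
to level *l*+1. On a 32×32×3 input the shape chain is

    32×32×3 → (texton) → (dense) 32×32×259 → (PC, k5 s2) 14×14×96
            → (texton) → (dense) 14×14×352 → (PC, k5 s2) 5×5×96
            → (texton) → (dense) 5×5×352  → (PC, k3 s2) 2×2×96

giving 2352, 300 and 48 primary capsules (12 types × grid cells, 8-D each).
Four class-capsule heads are routed by agreement: heads 1–3 from the three
primary-capsule sets (16-D, 12-D, 10-D per class), head 0 (16-D) from the
concatenation of all 2700 capsules, so the model can read out integrated
features across scales. Per class the four output capsules concatenate to a
54-D capsule; its Euclidean length is the class score and the argmax is the
prediction (ties break to the lowest class index).

### Texton selection

A texton here is a 2×2 window in which one designated pixel pair is equal;
six pair geometries are tested in a fixed first-match order (the last two —
vertical-right and horizontal-bottom — extend the classical four-texton set).
Windows are anchored every `step` pixels (default 1; the classical descriptor
scans with step 2, available via config) with anchors clamped so the window
stays in bounds; the whole 2×2 grid is kept on a hit and overlapping hits
combine by OR; uncovered pixels become zero. Because a whole grid is kept
whenever *any* selected pair matches, first-match order does not affect the
mask — a property the test oracle exploits. A `keep="pair"` variant retains
only the two matching pixels of the first matching texton.

Exact equality is meaningful on integer images but almost never fires on
continuous activations, so the in-network layer quantizes each channel of
each sample independently to 256 uniform bins over its own min–max range
(a constant channel maps to bin 0 everywhere and is therefore fully kept),
detects textons on the quantized grid, and multiplies the *original* values
by the boolean mask. A tolerance mode (|a−b| ≤ ε on raw values) is provided
as an alternative. The operator is a selection, not a smooth function: the
mask is treated as a constant of the forward pass (straight-through), so
downstream gradients are exactly zero at masked-out positions and unchanged
elsewhere.

### Dense blocks

Eight layers (configurable), each batch-norm → ReLU → 3×3 same-padded
convolution adding `growth` channels; layer *t* consumes the concatenation of
the block input and all previous outputs, and the block output is that full
concatenation (its first C channels are the untouched input). Growth 32 is
forced by the published channel arithmetic (3 + 8·32 = 259, 96 + 8·32 = 352);
kernel 3 with no bottleneck/compression follows the dense-convolution
lineage the design cites. Pre-activation ordering was chosen for the same
reason; the source describes only "batch normalization and ReLU activation".

### Routing

Logits start at zero; per iteration c_i = softmax over upper capsules of
b_i, s_j = Σ_i c_ij û_j|i, v_j = squash(s_j), then b_ij += v_j·û_j|i. The
default applies the agreement update inside each of the r = 3 iterations
(the conventional reading); a verbatim mode (`routing_update="after"`) keeps
the printed control flow, in which the update happens once after the loop —
observationally that variant equals single-iteration routing plus a logit
update, and it is exposed for comparison only. Gradients flow through all
iterations. Note a consequence of the softmax direction: with a single lower
capsule the couplings still spread 1/J across upper capsules, so the outputs
are squashed *coupling-scaled* votes (exactly squashed votes only when
J = 1).

squash divides by √(‖s‖² + 1e−9) so the zero vector maps to zero; lengths
are strictly increasing in ‖s‖ and bounded in [0, 1).

### Loss and training

Each head contributes the per-class hinge-squared margin loss with m⁺ = 0.9,
m⁻ = 0.1, λ = 0.5 — the conventional values of the capsule-network baseline;
the source states only that they are set during learning. The four losses are
summed: the heads' gradient paths are disjoint above their primary capsules,
so the unweighted sum back-propagates each head independently (no
alternating per-head steps). The decoder reconstructs the flattened input
from the 54-D capsule of the true class during training (argmax class at
inference; the one-hot mask zeroes all other classes' capsules) through
FC(54→512) → FC(512→512), the two outputs concatenated → FC(1024→1024) →
FC(1024→H·W·C) with sigmoid, adding α·SSE with α = 0.0005. Optimization is
Adam (lr 0.001, β₁ 0.9, β₂ 0.999); batch size defaults to 64 within the
50–100 range used by the reference setup; epochs are config-driven (no
schedule, weight decay or early stopping). Capsule transformation matrices
W_ij initialize from N(0, 0.01²); convolutions and decoder layers use
He-normal initialization. All randomness (init, shuffling, splits) flows
from explicit seeds; runs are bit-reproducible at a fixed thread count.

Weight checkpoints embed the model config and are written whenever
validation accuracy improves; training aborts with a diagnostic on a
non-finite loss.

### Parameter count

The full four-class configuration holds 10,209,904 trainable scalars
(≈10.21 M; the published count for that setup is 10.29 M — the residual gap
depends on unstated choices such as normalization parameters and decoder
sharing, so the count is reported, not asserted).

## Metrics

Per class, from one-vs-rest confusion counts: accuracy (TP+TN)/(TP+FP+TN+FN),
precision TP/(TP+FP), sensitivity TP/(TP+FN), specificity TN/(TN+FP). A
zero-denominator metric is *undefined* (None), never 0. Table-style output
rounds half-up to 4 decimals (accuracy as a percentage to 2), matching how
such tables are printed. ROC/PR curves are one-vs-rest on the 54-D
concatenated capsule lengths (the natural score; per-head lengths would also
be defensible), with trapezoidal ROC area and step-interpolated
(average-precision) PR area; macro averages accompany the per-class values.
In the binary case, sensitivity of one class equals specificity of the other
and both classes share one accuracy — identities the tests assert.

## Synthetic data

`synth_textured_dataset` emulates the study setting — small multi-class
32×32×3 images whose classes are *texture* families — without any downloads.
Classes (in order): horizontal, vertical and diagonal stripes, checkerboard;
for 10 classes additionally blob, ring, gradient, speckle, anti-diagonal
stripes and grid. Every archetype is built from flat same-valued pixel runs,
so the texton operator fires densely on clean samples (a noise-free stripe
image is 100% covered); per-sample random dark/light colors, stripe widths
(2–4 px) and phases provide within-class variation, and `noise_frac` (default
0.05, i.e. 5% of pixels replaced by uniform noise) controls degradation.
Classes are balanced to within one sample and generation is fully seeded.

What this does *not* emulate: natural-image statistics, staining/contrast
variation, class imbalance, label noise, or any anatomical structure of real
histopathology/MRI data. Passing tests therefore demonstrate that the
architecture, losses, routing and training loop are implemented correctly
and can learn texture-defined classes — not that the model attains its
published accuracy on the real datasets, which would require the external
downloads and GPU-scale training that are out of scope here.

## Problem sizes and numerical choices

The package trains through a small numpy autodiff engine (float32,
im2col+BLAS convolution), so desk-scale runs use `ModelConfig.compact()`:
4 primary-capsule types, 2 dense layers of growth 8, 32-level texton
quantization, a 128/128/256 decoder, same head dimensions (54-D concatenated
capsule) and routing. On the synthetic 4-class set (n = 400, 80:20 split)
this configuration reaches ≥95% training accuracy within a handful of epochs
and ~1 min on one CPU core; the tests and the acceptance script use 6-epoch
budgets. The full configuration is exercised forward (shape chain, parameter
count, checkpoint round-trips) in seconds.

Other numerics: softmax is max-shifted; batch-norm uses ε = 1e−5 and
momentum 0.9 running statistics (training statistics are batch statistics);
images smaller than 2×2 yield an all-zero texton mask with a warning;
capsule-length computation adds 1e−9 inside the square root to keep the
gradient finite at zero.

## Data handling choices

The 80:20 hold-out split is stratified per class: floor(0.2·count) samples
(at least 1) per class go to validation (the source says only "80:20
leave-out"; patient-aware splitting is not claimed and not implemented).
Folder datasets take class order from sorted subdirectory names and resize
bilinearly; grayscale sources stay single-channel with a matching decoder
width. Augmentation draws an integer shift uniformly from [−t, t] per axis
and an angle uniformly from [−θ, θ], applies the rotation (inverse-map
bilinear about the image center, zero fill, pixels leaving the canvas are
cropped) and then the shift; the tuple notation (t, θ) names those bounds,
and (0, 0) is the exact identity.

## Known limitations

- No GPU path and no framework interop; throughput is BLAS-bound.
- The texton layer's 256-bin quantization of continuous activations is one
  defensible reading of applying an integer-equality operator to real
  features; near-equal float equality (the tolerance mode) is the other.
  Which one the original training used is unknowable from the source.
- Printed parameter counts are matched approximately (see above).
- The reconstruction decoder is shared across heads via the concatenated
  capsule; per-head decoders would be an alternative reading.
- `update="after"` (verbatim routing) is provided for study but effectively
  disables iterative re-weighting; use the default for real training.
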