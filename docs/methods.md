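# Methods

## Problem and models

Fetal ultrasound screening relies on *standard planes* — canonical 2-D
views (trans-ventricular, trans-thalamic, trans-cerebellum, abdominal,
femur, thorax, maternal cervix) on which biometric measurements are
defined. This package implements two fully convolutional classifiers for
detecting those planes in grayscale images, plus the data pipeline,
training recipe, and GradCAM attribution around them.

**SonoNet64 baseline.** A VGG-style ladder of bias-free 3×3 convolutions
(64,64 | 128,128 | 256×3 | 512×3 | 512×3), each followed by batch
normalization and a ReLU, with 2×2 max pooling after the first four
blocks. The *adaptation head* is a 1×1 convolution 512→256 (norm + ReLU),
a 1×1 convolution 256→K (norm), and a global spatial max pool to K logits.
Because every layer is convolutional and the head pools globally, any
input with both spatial dimensions ≥ 2^(#pools) is accepted, and the max
pool implicitly localizes the most discriminative region. Total trainable
parameters at K = 6: 14,850,892 (14.9 M).

**LPC-SonoNet.** The light pyramid convolution (LPC) block computes
y₁ = Conv3×3(x) (in→hidden), y₂ = Conv3×3(y₁) (hidden→hidden),
concatenates (x, y₁, y₂) — three receptive-field scales, width
in + 2·hidden — and fuses with a 1×1 convolution to the output width. All
convolutions are bias-free with batch norm and ReLU. The network stacks
four LPC blocks with output ladder (64, 256, 512, 512) and hidden width
half the output width, pools after blocks 1–3, and reuses the same
adaptation head. Total at K = 6: 4,321,900 (4.3 M), a ratio of 0.29 to the
baseline.

The LPC ladder and hidden widths are not uniquely determined by the
published description ("one block fewer, the rest replaced"); the shipped
configuration was calibrated by enumerating candidate ladders and hidden
ratios against the published 4.3 M budget (see the ladder-calibration test
in `tests/test_architectures.py`). Dropping the 128-wide block with
hidden = out/2 is the unique natural candidate that reproduces the budget;
neighbouring candidates miss it. This is a calibration, not a claim about
the original authors' exact choice.

Parameter accounting: 3×3 conv = 9·in·out, 1×1 conv = in·out (no biases —
each conv is followed by batch norm, which absorbs the bias), batch
norm = 2·channels. `total_millions` rounds half-up to one decimal. The
closed-form count is verified against brute-force enumeration of the
instantiated model's tensors in the tests and the acceptance script.

`channel_load` (mean input-channel count over all convolutions) is a
diagnostic with no canonical definition; under this package's definition
the concatenation widths make the pyramid network's mean *higher* than
the baseline's, so it is reported for inspection only and nothing depends
on it.

## Numerical engine

There is no deep-learning framework dependency: `lpc_sononet.nn` is a
compact NumPy engine providing exactly the layers these networks need.
Convolutions run as im2col + single-BLAS-matmul over the whole batch;
backward passes are analytic and are verified against central finite
differences in float64 in the test suite. Arithmetic is float32;
initialization is fan-in-scaled normal from a per-run `numpy` generator,
so instantiation and training are bit-reproducible given a seed (on a
fixed BLAS). Max pooling is 2×2 stride 2 with trailing odd rows/columns
dropped; gradient routing follows the argmax (first occurrence on ties).

## Data pipeline

Splits are per-category 8:1:1: train = ⌊0.8·n⌋, then the remainder goes
⌈rem/2⌉ to validation and the rest to test, shuffled by a seeded
generator. One published per-category row (the six-class brain row,
3092 → 2472/310/310) deviates from any simple rounding rule by one image;
an explicit-counts mode takes a per-category (train, val, test) table
verbatim for exact table fidelity. The shipped count and target tables
for the six- and nine-class schemes of the public Burgos-Artizzu
fetal-plane dataset are configuration defaults, not derived quantities:
the published after-augmentation counts follow no single multiplication
rule.

Augmentation applies only to training originals. Per category the deficit
d = target − n is distributed round-robin over the sources in seeded
order (⌊d/n⌋ each, the first d mod n sources one extra), so executed
counts equal targets *exactly*. Each job carries one transform drawn from
{horizontal flip, rotation, brightness, contrast, Gaussian blur} with
parameters from pinned label-preserving ranges: angle ±15° (counter-clockwise,
zero-filled corners, bilinear), brightness/contrast factors 0.7–1.3
(contrast pivots on the image mean), blur σ 0.5–1.5 px (normalized
kernel, so constants are preserved). Identity parameters are excluded and
no source receives the same transform twice (a flip can occur at most
once per source). Vertical flips are excluded as anatomically implausible
(they invert the fan orientation). Images are 8-bit grayscale PNG;
pipeline math is float in [0, 1] with clipping.

## Training recipe

Adam on softmax cross-entropy; learning rate
lr(e) = initial_lr / decay_factor^⌊e/decay_every⌋ with defaults 0.001,
×10 decay every 50 epochs, 200 epochs — i.e. 0.001 → 1e-4 → 1e-5 → 1e-6.
Batch size defaults to 32; inputs are resized to the configured size
(default 224×288) and standardized per image to zero mean / unit
variance. The retained checkpoint is the epoch with best validation
accuracy, earliest epoch on ties. Argmax predictions break ties toward
the lowest class index.

Metrics reduce the K×K confusion matrix one-vs-rest per class:
accuracy = trace/total, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), with **macro** averaging (equal weight per
class — the natural summary for an imbalanced plane distribution, and the
aggregation consistent with specificity sitting near 1 while sensitivity
tracks the rare classes). A class with no true samples has undefined
sensitivity; it is excluded from the macro mean and flagged in the
report.

## GradCAM

For stage activations A (C×h×w) and target logit y_c, channel weights are
the spatial means of ∂y_c/∂A; the map is ReLU(Σ w_c A_c), upsampled
bilinearly to the input size and max-normalized (an identically zero map
stays zero). The default stage is the output of the last feature block
(`block4`), the deepest spatial layer. Accumulation is float64 so channel
permutation invariance holds to 1e-12. The overlay renderer blends warm
colormap colors in proportion to the heatmap value over the dimmed
grayscale image.

## Synthetic phantoms

The generator renders nine category-discriminative geometries (ellipse
rims, discs, bars, wedges — see `synthetic_data.py`'s table) over a dark
background, with seeded jitter of center (±6 % of size), scale (±12 %),
and rotation (±20°), then multiplicative Gaussian speckle
p ← clip(p·(1 + s·η), 0, 1). Multiplicative Gaussian noise preserves the
defining statistical property of ultrasound speckle (signal-dependent
variance) without a physical Rayleigh-scattering model. The four brain
categories share one rim construction and consume the random stream
identically, so at zero speckle they differ only inside the rim — a
property the tests rely on. Per-image seeds derive from
`numpy.random.SeedSequence(entropy=seed, spawn_key=(category, index))`,
making datasets pure functions of their arguments.

What the phantoms do *not* emulate: acoustic shadowing, probe-fan
geometry, device-dependent contrast, intra-class anatomical variability,
or ambiguous planes. Tests passing on phantoms therefore demonstrate that
the architectures, pipeline, optimizer, and attribution are implemented
correctly and can fit a genuinely separable 9-class imaging task — not
that the networks reach any particular accuracy on clinical images.

## Study sizes in the test suite

The convergence check trains the full 4.3 M-parameter LPC-SonoNet on the
nine-class phantom task at 64 training / 16 validation images per class,
32×32 pixels, speckle 0.1, batch 32, for 8 epochs with decay_every 3 —
a deliberately scaled-down study sized for a single CPU core (roughly
3 minutes per seed on commodity hardware; a step on the full net costs
about 1.4 GFLOP per image at this resolution). The ≥ 0.90
validation-accuracy bar is evaluated over three seeds, at least two of
which must pass; seeds run lazily and stop once two have passed. A linear
baseline on 16×16 downsampled pixels reaches well above 70 % on the same
task, so convergence of the CNN is a meaningful but not vacuous check.

## Known limitations

- The engine is single-threaded NumPy: fine for the bundled studies,
  roughly two orders of magnitude slower than a GPU framework at the
  published training scale (200 epochs on ~16k images at 224×288).
- Published real-dataset accuracies require the external clinical dataset
  and are out of scope here; nothing in this repository claims them.
- Batch norm uses per-batch statistics with momentum 0.1; very small
  final batches can add noise to running statistics. The training loop
  does not drop the last partial batch.
- `channel_load` is a diagnostic only (see above).
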