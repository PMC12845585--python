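# Methods

This note records the model as implemented, the conventions that were
genuinely open, and what the synthetic experiments demonstrate.

## Backbone and block placement

The backbone is the canonical five-stage UNet: each stage is two 3×3
convolutions, each followed by batch normalisation and ReLU; stage widths
double 64→1024; four downsampling steps; transposed 2×2 stride-2
convolutions for upsampling; skips concatenate the encoder feature onto the
upsampled decoder feature; a final 1×1 convolution emits logits for two
classes (background, aphid cluster). Input spatial dimensions must be
divisible by 16 (four halvings); the forward pass rejects anything else with
an explicit error rather than padding silently.

Block placement: SimAM directly after each of the four encoder double-conv
stages; EMA once, on the 1024-channel bottleneck map; HWD replacing all four
max-pools when enabled; FEAM on the deepest `feam_count` (0–4) skips,
deepest first, applied to the encoder feature *before* concatenation. Any
subset of blocks can be enabled independently, which is what the ablation
grid in `ablation_configs()` enumerates.

### Bias conventions and the parameter budget

Convolutions immediately followed by batch norm carry no bias (the BN shift
absorbs it); transposed convolutions, the classifier head, the HWD 1×1
heads and the EMA convolutions carry biases. Under these conventions the
baseline counts 31,037,698 parameters (31.038 M) — within 0.03 % of the
31.031 M commonly quoted for this architecture; the residual is bias
bookkeeping, and both the HWD-head bias and the BN-conv bias are exposed as
flags (`hwd_conv_bias`, `conv_bias_with_bn`) so alternative conventions can
be reproduced exactly. The per-block increments are closed forms asserted in
tests: EMA +164,352, HWD +1,395,520, SimAM +0.

## SimAM: variance convention

With plane statistics μ (mean) and σ² (variance) over all M = H·W neurons,
the per-neuron minimum energy is e*(t) = 4(σ²+λ) / ((t−μ)² + 2σ² + 2λ) and
the output is `sigmoid(1/E) ⊙ X`. We use the *population* variance (divisor
M). This is deliberate: with divisor M, the closed form is the exact
minimiser — to machine precision — of the underlying energy objective in
which every neuron of the plane serves as a neighbour, and the test suite
verifies this against a brute-force Nelder–Mead minimiser. A Bessel-corrected
(divisor M−1) variant agrees only up to O(1/M) and would fail an exactness
test on small planes; on feature maps of realistic size the two are
numerically indistinguishable. λ defaults to 1e-4 and is config-exposed
(`simam_lambda`); the constant-plane energy is exactly 2 for any λ, giving
the characteristic `sigmoid(0.5) ≈ 0.622` attenuation of featureless
channels.

## EMA: group count and normalisation

The group count g is not dictated by the architecture; g = 8 is the default
because at the 1024-channel bottleneck it gives per-group width c = 128 and
a block cost of (c²+c) + (9c²+c) + 2c = 164,352 — the +0.165 M increment the
budget tests pin. The group normalisation inside the block is affine (2c
parameters), included in that closed form. The cross-spatial aggregation
follows the published EMA design: softmaxed global descriptors of each
branch weight the flattened response of the other, and the summed map passes
through a sigmoid, so the final modulation is strictly inside (0, 1).

## HWD: transform conventions

The Haar stage uses the orthonormal (1/√2) filter pair, making the analysis
an isometry: energy is conserved exactly and the adjoint is the inverse
(which is also how its gradient is implemented). Per 2×2 block
[[a,b],[c,d]]: A=(a+b+c+d)/2, horizontal=(a−b+c−d)/2, vertical=(a+b−c−d)/2,
diagonal=(a−b−c+d)/2. "Horizontal detail" means the response of the
high-pass filter along the *width* axis (this is the opposite of the
PyWavelets naming, which labels detail bands by the edge orientation they
detect; the test suite maps between the two explicitly). Subbands stack in
the fixed order (A, horizontal, vertical, diagonal). Spatial dims must be
even — no implicit padding; all working resolutions (480, 1024, and the
divisible-by-16 rule generally) satisfy this. The head maps 4C→C with conv
bias on, so each stage costs 4C²+3C parameters.

## FEAM: spectral conventions and the cost of multi-scale grids

The FFT is the full complex 2-D transform with "ortho" normalisation, so
Parseval holds exactly and a 0/1 real mask can only remove energy. Frequency
bins follow NumPy ordering (zero frequency at the index origin, no
fftshift); the weight grids are defined in that ordering. After the inverse
transform the real part is taken explicitly — the stored grids are full
(not Hermitian-symmetric half-spectra), so the product is not guaranteed
real. Bilinear projection of the weight grids is corner-aligned: it is the
identity when sizes match and preserves constants, which makes the identity
initialisation (α≡1, β≡0) give a pre-gate output of exactly 2X at any
hosting resolution — the initial state is a benign residual-style pass, and
the property is tested literally. `feam_init="random"` draws near-identity
perturbations instead.

The channel gate applies one shared two-layer bottleneck (C → C/r → C,
biases on, ReLU between) to the average-pooled and max-pooled channel
descriptors, sums, and squashes with a sigmoid. r = 4 by default
(config-exposed): the gate then costs 2C²/4 + C/4 + C parameters, e.g.
131,712 at C=512.

One structural property deserves emphasis: the spectral grids cost
2·Σs² parameters and the nominal scales are tied to the hosting skip's
resolution ([30,60] on the deepest skip up to [240,480] on the shallowest at
480×480 input). A FEAM-count sweep therefore adds *growing* spectral cost
(×4 per shallower level: 9,000 → 36,000 → 144,000 → 576,000) while the
channel gates *shrink* (×4 per level: 131,712 → 33,088 → 8,352 → 2,128).
Totals grow strictly with the count, but the per-block increment is
dominated by the spectral grids from the third block on. Any accounting in
which the increments shrink monotonically implies the spectral grids were
not being counted as (or were not) trainable parameters; here they are
trainable — gradients reaching α and β is a tested property — and they are
counted.

## Metrics

All quality metrics derive from an additive per-class confusion accumulator,
so streaming evaluation equals single-shot evaluation and batch order is
irrelevant. mIoU, mPA and mF1 are macro means over the two classes; Accuracy
is pooled pixel accuracy (trace of the confusion table over total pixels) —
for the per-class 4-way decomposition this equals the literal summed-counts
form, and the pooled reading is the one consistent with Accuracy sitting far
above mPA on imbalanced data. Zero-division rule: a class absent from both
prediction and ground truth contributes a vacuously perfect 1.0 (default) or
is skipped (`absent_class="skip"`). The FPS harness times only single-image
forward passes after configurable warm-up (10 by default) and is reported,
never asserted: it is a hardware property.

## Training

Loss = (1−w)·cross-entropy + w·soft-Dice with w = 0.5; the Dice term (with
+1 smoothing) protects the small foreground class from the ~90 % background
majority. Optimiser Adam, default learning rate 1e-4 (constant), batch size
8, 100 epochs — all config-exposed. Every run is seeded end to end: weight
initialisation, batch order and scene synthesis derive from one integer, and
two runs with the same seed produce bit-identical first-step losses.
Checkpoints embed the full model configuration, so loading reconstructs the
exact architecture without external context.

## Synthetic scenes: what they show and what they do not

`synth_scene` composes a base green tone, sinusoidal vein striping at a
random orientation, a linear illumination gradient, an optional Gaussian
shadow band, and per-pixel speckle; foreground is a union of overlapping
rotated ellipses per cluster, rendered ~35 intensity units darker than the
leaf (low contrast), with the exact rasterised union as mask. Magnitudes
(vein amplitude 12, illumination 25, speckle sd 4 on the 8-bit scale,
3 clusters of 3–8 ellipses with semi-axes 3–6 px) were chosen once to give
visually plausible scenes with 5–15 % foreground, and are all
parameters of `SceneParams`. The augmentation protocol doubles a dataset by
partitioning it into four equal random subsets and applying exactly one of
{horizontal flip, vertical flip, brightness ×U[0.7,1.3], Gaussian noise
sd 5 % of range} per subset — flips move image and mask jointly; photometric
transforms leave the mask bit-identical.

Passing tests on these scenes demonstrate that the architecture is
assembled correctly, optimisable end to end, and able to fit genuinely
(the full model reaches training mIoU > 0.9 on eight 64×64 scenes within
200 Adam steps at lr 1e-3, batch 2 — usually in well under 100). They do
*not* demonstrate field accuracy: real aphid imagery has occlusion,
defocus, specularities and annotation noise the generator does not emulate,
and competitive scores on real datasets require GPU-scale training on
thousands of images. The smoke-test problem sizes (64×64, narrow-width
variants in the unit tests) were chosen so the whole suite runs on a single
CPU core; they are capacity sanity checks, not benchmarks.

## Known limitations

* Binary segmentation only (background vs aphid cluster); the metric layer
  is N-class but the pipeline defaults assume two.
* The NumPy engine is single-device and eager; at 480×480 a forward pass
  costs tens of seconds on one CPU core, so the package is a reference and
  research implementation, not a deployment runtime.
* FEAM scales must not exceed the hosting skip's spatial size; small-input
  configurations must supply scaled-down menus (e.g. [4,8]/[8,16] at 64×64).
* The exact learning-rate/loss schedule for field-scale training is not
  prescribed; the defaults are sensible starting points, not tuned values.
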